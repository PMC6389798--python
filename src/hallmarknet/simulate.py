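"""Synthetic multi-cohort datasets with planted co-expression structure.

The generator emulates the statistical structure the hallmark-mining
analysis assumes, with known ground truth so every downstream stage can be
scored:

* several cohorts share a set of *planted modules* — blocks of genes built
  from a one-factor model, gene_jk = sqrt(rho) * f_k + sqrt(1 - rho) * eps,
  where f_k is a per-sample latent factor of module k and eps is
  independent standard normal noise.  Under this construction the expected
  pairwise correlation of two genes in the same module is exactly rho;
* each cohort may additionally carry *cohort-specific* modules, present in
  that cohort only (their genes are pure noise elsewhere);
* all remaining genes are independent standard normal background;
* survival follows an exponential proportional-hazards model whose log
  hazard is beta times the standardized mean expression of one designated
  shared module (the risk module).  Censoring times are independent
  Uniform(0, c_max) with c_max calibrated by root finding so the expected
  censored fraction hits the configured target;
* companion annotation fixtures provide one GO-like term per planted
  module (plus random decoy terms) and a drug table whose target sets
  overlap the planted modules at controlled rates, with cancer-indication
  flags enriched among module-targeting drugs at a configured odds ratio.

Everything is reproducible bit-for-bit from the configuration seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import GeneSetCollection
from .util import derive_seed

__all__ = ["SyntheticConfig", "AnnotationConfig", "SyntheticDataset",
           "generate_cohorts", "generate_annotation_fixtures"]


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic multi-cohort dataset.

    ``shared_modules`` and ``cohort_specific_modules`` are (size, rho)
    pairs; rho in (0, 1) is the within-module pairwise correlation.
    Cohort-specific modules are assigned to cohorts round-robin.
    ``risk_module_index`` selects the shared module that drives survival
    with log-hazard coefficient ``beta``.
    """

    n_cohorts: int = 3
    n_genes: int = 300
    samples_per_cohort: tuple[int, ...] = (100, 100, 100)
    shared_modules: tuple[tuple[int, float], ...] = ((8, 0.8), (6, 0.8))
    cohort_specific_modules: tuple[tuple[int, float], ...] = ((6, 0.8),)
    risk_module_index: int = 0
    beta: float = 1.0
    censoring_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ValueError("samples_per_cohort must list one size per cohort")
        if any(s < 4 for s in self.samples_per_cohort):
            raise ValueError("every cohort needs at least 4 samples")
        total = sum(s for s, _ in self.shared_modules) + sum(
            s for s, _ in self.cohort_specific_modules)
        if total > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for _, rho in list(self.shared_modules) + list(self.cohort_specific_modules):
            if not 0 < rho < 1:
                raise ValueError("module correlation rho must lie in (0, 1)")
        if not 0 < self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must lie strictly in (0, 1)")
        if self.shared_modules and not (
                0 <= self.risk_module_index < len(self.shared_modules)):
            raise ValueError("risk_module_index out of range")


@dataclasses.dataclass(frozen=True)
class AnnotationConfig:
    """Parameters of the toy GO-term and drug-table fixtures."""

    n_decoy_terms: int = 20
    decoy_term_size: int = 8
    n_drugs: int = 200
    targets_per_drug: int = 5
    module_targeting_fraction: float = 0.25
    module_overlap: int = 4  # hallmark-module targets per module-targeting drug
    baseline_indication_rate: float = 0.3
    indication_odds_ratio: float = 4.0


@dataclasses.dataclass(frozen=True)
class SyntheticDataset:
    """Cohorts plus the machine-readable ground-truth manifest."""

    cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]]  # id -> (expr, clinical)
    ground_truth: dict[str, dict]
    config: SyntheticConfig

    def module_genes(self, module_id: str) -> tuple[str, ...]:
        return tuple(self.ground_truth[module_id]["genes"])


def _calibrate_censoring(times: np.ndarray, target: float) -> float:
    """Uniform(0, c) upper bound such that the expected censored fraction is ``target``.

    A subject with survival time t and independent C ~ U(0, c) is censored
    with probability min(t/c, 1); the expectation over subjects is monotone
    decreasing in c, so the root is found by Brent's method.
    """
    def frac(c: float) -> float:
        return float(np.minimum(times / c, 1.0).mean()) - target

    lo = float(times.min()) * 1e-6 + 1e-300
    hi = float(times.max()) / target * 10 + 1.0
    return float(brentq(frac, lo, hi, xtol=1e-12, rtol=1e-12))


def generate_cohorts(config: SyntheticConfig) -> SyntheticDataset:
    """Generate every cohort's expression matrix and clinical table.

    Gene ids are ``g0000``...; planted modules occupy the leading id
    blocks (shared first, then cohort-specific), the rest is background.
    The ground-truth manifest maps module ids to their genes, correlation
    strength and carrier cohorts.
    """
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    cursor = 0
    ground_truth: dict[str, dict] = {}
    placements: list[tuple[str, list[str], float, list[int]]] = []
    for k, (size, rho) in enumerate(config.shared_modules):
        members = genes[cursor:cursor + size]
        cursor += size
        module_id = f"shared{k}"
        cohorts_with = list(range(config.n_cohorts))
        placements.append((module_id, members, rho, cohorts_with))
        ground_truth[module_id] = {
            "genes": members, "rho": rho, "type": "shared",
            "cohorts": [f"cohort{c}" for c in cohorts_with],
            "is_risk_module": k == config.risk_module_index,
        }
    for k, (size, rho) in enumerate(config.cohort_specific_modules):
        members = genes[cursor:cursor + size]
        cursor += size
        module_id = f"specific{k}"
        carrier = k % config.n_cohorts
        placements.append((module_id, members, rho, [carrier]))
        ground_truth[module_id] = {
            "genes": members, "rho": rho, "type": "cohort_specific",
            "cohorts": [f"cohort{carrier}"], "is_risk_module": False,
        }
    ground_truth["background"] = {
        "genes": genes[cursor:], "rho": 0.0, "type": "background",
        "cohorts": [f"cohort{c}" for c in range(config.n_cohorts)],
        "is_risk_module": False,
    }

    risk_genes: list[str] = []
    if config.shared_modules:
        # shared modules come first in `placements`, so this indexes the risk module
        risk_genes = list(placements[config.risk_module_index][1])

    cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for c, n_samples in enumerate(config.samples_per_cohort):
        cohort_id = f"cohort{c}"
        rng = np.random.default_rng(derive_seed(config.seed, "cohort", cohort_id))
        values = rng.standard_normal((config.n_genes, n_samples))
        for module_id, members, rho, carriers in placements:
            if c not in carriers:
                continue
            factor = rng.standard_normal(n_samples)
            rows = [gene_pos[g] for g in members]
            values[rows] = (np.sqrt(rho) * factor
                            + np.sqrt(1.0 - rho) * values[rows])
        sample_ids = [f"{cohort_id}_s{j:03d}" for j in range(n_samples)]
        expr = pd.DataFrame(values, index=genes, columns=sample_ids)

        if risk_genes:
            signal = expr.loc[risk_genes].mean(axis=0).to_numpy()
            z = (signal - signal.mean()) / signal.std(ddof=0)
        else:
            z = np.zeros(n_samples)
        hazard = np.exp(config.beta * z)
        survival = rng.exponential(1.0 / hazard)
        c_max = _calibrate_censoring(survival, config.censoring_fraction)
        censor = rng.uniform(0.0, c_max, size=n_samples)
        clinical = pd.DataFrame({
            "sample_id": sample_ids,
            "time": np.minimum(survival, censor),
            "event": (survival <= censor).astype(int),
        })
        cohorts[cohort_id] = (expr, clinical)
    return SyntheticDataset(cohorts=cohorts, ground_truth=ground_truth, config=config)


def generate_annotation_fixtures(dataset: SyntheticDataset,
                                 annot: AnnotationConfig | None = None,
                                 seed: int | None = None,
                                 ) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Toy GO-term and drug fixtures aligned to the planted modules.

    Each planted module gets one term containing exactly its genes;
    ``n_decoy_terms`` decoys hold uniformly random gene sets.  A
    ``module_targeting_fraction`` of the drugs draw ``module_overlap`` of
    their targets from a planted module (cycling over modules) and the rest
    at random; the others target random genes.  Cancer-indication flags are
    Bernoulli with the baseline rate for random drugs and with odds
    multiplied by ``indication_odds_ratio`` for module-targeting drugs
    (odds ratio 1 makes indication independent of targeting — the null).
    ``seed`` overrides the dataset seed, to redraw fixtures over the same
    cohorts.
    """
    annot = annot or AnnotationConfig()
    config = dataset.config
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(derive_seed(seed, "annotation"))
    all_genes = sorted(
        {g for module in dataset.ground_truth.values() for g in module["genes"]})
    modules = [(mid, list(info["genes"])) for mid, info in dataset.ground_truth.items()
               if info["type"] != "background"]

    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for module_id, members in modules:
        term = f"TERM:{module_id}"
        sets[term] = frozenset(members)
        names[term] = f"planted module {module_id}"
    for d in range(annot.n_decoy_terms):
        term = f"TERM:decoy{d:03d}"
        members = rng.choice(all_genes, size=annot.decoy_term_size, replace=False)
        sets[term] = frozenset(members)
        names[term] = "decoy term"
    genesets = GeneSetCollection(sets=sets, names=names)

    p0 = annot.baseline_indication_rate
    odds1 = annot.indication_odds_ratio * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    rows = []
    n_targeting = int(round(annot.module_targeting_fraction * annot.n_drugs))
    for d in range(annot.n_drugs):
        drug_id = f"D{d:04d}"
        targeting = d < n_targeting and bool(modules)
        if targeting:
            module_id, members = modules[d % len(modules)]
            k = min(annot.module_overlap, len(members), annot.targets_per_drug)
            from_module = list(rng.choice(members, size=k, replace=False))
            pool = [g for g in all_genes if g not in from_module]
            filler = list(rng.choice(pool, size=annot.targets_per_drug - k, replace=False))
            targets = frozenset(from_module + filler)
        else:
            targets = frozenset(rng.choice(all_genes, size=annot.targets_per_drug,
                                           replace=False))
        is_cancer = int(rng.random() < (p1 if targeting else p0))
        rows.append({"drug_id": drug_id, "targets": targets, "is_cancer": is_cancer})
    drugs = pd.DataFrame(rows).set_index("drug_id")
    return genesets, drugs
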