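"""End-to-end hallmark mining as a model/results pair.

:class:`HallmarkMiner` holds the data (one expression matrix and clinical
table per cohort) and the analysis parameters; :meth:`HallmarkMiner.fit`
runs the full pipeline and returns a :class:`HallmarkResults` carrying
every stage's output:

    networks  ->  communities (seed cohort)  ->  conservation test
              ->  survival validation        ->  annotation / drug screen

A *hallmark* is operationalized as a conserved community (>= ``min_size``
genes, permutation p < alpha in every non-seed cohort) whose gene set also
stratifies patient survival (log-rank p < alpha on the held-out test half)
in at least ``hallmark_min_cohorts`` cohorts.

All stage randomness is derived from the single ``seed`` passed to
``fit``, so a fit is bit-for-bit reproducible; ``HallmarkResults.save``
writes a deterministic manifest plus per-stage artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from . import io as hio
from .conservation import ConservationResult, find_conserved
from .enrichment import (DrugScreenResult, EnrichmentResult,
                         annotate_communities, goterm_overlap_test, screen_drugs)
from .mcode import Community, McodeParams, find_complexes
from .network import NetworkConfig, PowerLawFit, build_network, fit_power_law
from .survival import (SurvivalStratification, fit_risk_model, stratified_split,
                       stratify_and_test)
from .util import derive_seed

__all__ = ["HallmarkMiner", "HallmarkResults", "PipelineError"]

logger = logging.getLogger("hallmarknet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclasses.dataclass
class HallmarkResults:
    """Everything one pipeline fit produced.

    ``survival`` maps community id -> cohort -> stratification (or ``None``
    where the test was not estimable, e.g. too few samples); ``hallmarks``
    lists the community ids passing the prognostic rule.
    """

    model: "HallmarkMiner"
    seed: int
    networks: dict[str, nx.Graph]
    power_law: dict[str, PowerLawFit | None]
    communities: list[Community]
    conservation: list[ConservationResult]
    survival: dict[str, dict[str, SurvivalStratification | None]]
    hallmarks: list[str]
    annotations: dict[str, EnrichmentResult]
    drug_screens: dict[str, DrugScreenResult]

    @property
    def conserved(self) -> list[ConservationResult]:
        return [r for r in self.conservation if r.is_conserved]

    def community_by_id(self, community_id: str) -> Community:
        return self.communities[int(community_id.lstrip("C"))]

    def conserved_terms(self) -> set[str]:
        """Distinct annotation terms of the conserved communities."""
        conserved_ids = {r.community_id for r in self.conserved}
        return {a.term_id for cid, a in self.annotations.items()
                if cid in conserved_ids and a.term_id is not None and a.significant}

    def summary(self) -> str:
        lines = ["Hallmark mining results", "=" * 60]
        lines.append(f"cohorts: {', '.join(sorted(self.networks))}"
                     f" (seed cohort: {self.model.seed_cohort})")
        for cohort in sorted(self.networks):
            net = self.networks[cohort]
            fit = self.power_law.get(cohort)
            fit_txt = (f"power-law r={fit.correlation:+.3f} R2={fit.r_squared:.3f}"
                       if fit else "power-law fit: n/a")
            lines.append(f"  {cohort}: {net.number_of_nodes()} nodes,"
                         f" {net.number_of_edges()} edges; {fit_txt}")
        lines.append(f"communities detected in {self.model.seed_cohort}:"
                     f" {len(self.communities)}")
        lines.append(f"conserved communities: {len(self.conserved)}")
        for res in self.conserved:
            worst = max(e.p_value for c, e in res.per_cohort.items()
                        if c != self.model.seed_cohort)
            ann = self.annotations.get(res.community_id)
            term = ann.term_id if ann and ann.term_id else "-"
            n_prog = sum(1 for s in self.survival.get(res.community_id, {}).values()
                         if s is not None and s.p_value < self.model.survival_alpha)
            mark = " *hallmark*" if res.community_id in self.hallmarks else ""
            lines.append(f"  {res.community_id}: {len(res.genes)} genes,"
                         f" max p={worst:.3f}, prognostic in {n_prog} cohort(s),"
                         f" term={term}{mark}")
        lines.append(f"hallmarks (prognostic in >= {self.model.hallmark_min_cohorts}"
                     f" cohorts): {', '.join(self.hallmarks) or 'none'}")
        for hid, screen in self.drug_screens.items():
            lines.append(f"  drug screen {hid}: {len(screen.selected)} selected,"
                         f" {screen.cancer_selected} cancer-indicated,"
                         f" indication p={screen.indication_p_value:.3g}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict:
        """Write all stage artifacts and a deterministic JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {
            "seed": self.seed,
            "seed_cohort": self.model.seed_cohort,
            "parameters": {
                "network": dataclasses.asdict(self.model.network_config),
                "mcode": dataclasses.asdict(self.model.mcode_params),
                "conservation": {
                    "n_permutations": self.model.n_permutations,
                    "alpha": self.model.conservation_alpha,
                    "min_size": self.model.min_size,
                },
                "survival": {"alpha": self.model.survival_alpha},
                "hallmark_min_cohorts": self.model.hallmark_min_cohorts,
            },
            "stages": {},
        }
        net_files = {}
        for cohort, net in self.networks.items():
            path = outdir / f"network_{cohort}.tsv"
            hio.write_network(net, path)
            net_files[cohort] = path.name
        manifest["stages"]["networks"] = net_files

        comm_rows = [
            {"community_id": f"C{i:03d}", "score": c.score, "seed_gene": c.seed,
             "genes": ",".join(c.genes)}
            for i, c in enumerate(self.communities)
        ]
        pd.DataFrame(comm_rows, columns=["community_id", "score", "seed_gene", "genes"]
                     ).to_csv(outdir / "communities.tsv", sep="\t", index=False)
        manifest["stages"]["communities"] = "communities.tsv"

        cons_rows = []
        for res in self.conservation:
            for cohort, entry in res.per_cohort.items():
                cons_rows.append({
                    "community_id": res.community_id, "cohort": cohort,
                    "observed_edges": entry.observed_edges,
                    "exceed_count": entry.exceed_count,
                    "p_value": entry.p_value,
                    "is_conserved": res.is_conserved,
                })
        pd.DataFrame(cons_rows).to_csv(outdir / "conservation.tsv", sep="\t", index=False)
        manifest["stages"]["conservation"] = "conservation.tsv"

        surv = {
            cid: {
                cohort: (None if strat is None else {
                    "statistic": strat.statistic, "p_value": strat.p_value,
                    "hazard_ratio": strat.hazard_ratio,
                    "n_high": int((strat.groups == "high").sum()),
                    "n_low": int((strat.groups == "low").sum()),
                })
                for cohort, strat in per_cohort.items()
            }
            for cid, per_cohort in self.survival.items()
        }
        hio.write_results(surv, outdir / "survival.json")
        manifest["stages"]["survival"] = "survival.json"
        manifest["hallmarks"] = self.hallmarks

        if self.annotations:
            hio.write_results(self.annotations, outdir / "annotations.json")
            manifest["stages"]["annotations"] = "annotations.json"
        if self.drug_screens:
            hio.write_results(self.drug_screens, outdir / "drug_screens.json")
            manifest["stages"]["drug_screens"] = "drug_screens.json"

        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest


class HallmarkMiner:
    """Pan-cancer hallmark-mining model over a set of cohorts.

    Parameters
    ----------
    cohorts
        Mapping cohort id -> (expression DataFrame genes x samples,
        clinical DataFrame with sample_id/time/event).  At least two.
    seed_cohort
        The cohort whose network is mined for communities (by default the
        cohort with the most clinical samples, mirroring the usual choice
        of the largest cohort).
    genesets, drugs
        Optional annotation sources for the enrichment stages.
    """

    def __init__(self, cohorts, seed_cohort: str | None = None, *,
                 network_config: NetworkConfig | None = None,
                 mcode_params: McodeParams | None = None,
                 n_permutations: int = 1000,
                 conservation_alpha: float = 0.05,
                 min_size: int = 5,
                 survival_alpha: float = 0.05,
                 hallmark_min_cohorts: int = 4,
                 genesets: hio.GeneSetCollection | None = None,
                 drugs: pd.DataFrame | None = None,
                 enrichment_alpha: float = 0.05,
                 universe: set[str] | None = None):
        if len(cohorts) < 2:
            raise ValueError("need at least 2 cohorts")
        self.cohorts = dict(cohorts)
        if seed_cohort is None:
            seed_cohort = max(sorted(self.cohorts),
                              key=lambda c: len(self.cohorts[c][1]))
        if seed_cohort not in self.cohorts:
            raise ValueError(f"seed cohort {seed_cohort!r} not among cohorts")
        self.seed_cohort = seed_cohort
        self.network_config = network_config or NetworkConfig()
        self.mcode_params = mcode_params or McodeParams()
        self.n_permutations = n_permutations
        self.conservation_alpha = conservation_alpha
        self.min_size = min_size
        self.survival_alpha = survival_alpha
        self.hallmark_min_cohorts = hallmark_min_cohorts
        self.genesets = genesets
        self.drugs = drugs
        self.enrichment_alpha = enrichment_alpha
        self.universe = universe

    @classmethod
    def from_files(cls, config: dict | str | Path, **kwargs) -> "HallmarkMiner":
        """Build a miner from a JSON config (or dict) of file paths.

        The config maps cohort ids to ``{"expression": path, "clinical":
        path}`` under a ``"cohorts"`` key, with optional ``"seed_cohort"``,
        ``"gmt"``, ``"drug_targets"`` and ``"drug_indications"`` entries.
        """
        if not isinstance(config, dict):
            with open(config) as fh:
                config = json.load(fh)
        cohorts = {}
        for cohort_id, paths in config["cohorts"].items():
            expr = hio.read_expression(paths["expression"])
            clinical = hio.read_clinical(paths["clinical"])
            cohorts[cohort_id] = (expr, clinical)
        if "gmt" in config:
            kwargs.setdefault("genesets", hio.read_gmt(config["gmt"]))
        if "drug_targets" in config:
            kwargs.setdefault("drugs", hio.read_drugs(config["drug_targets"],
                                                      config["drug_indications"]))
        return cls(cohorts, seed_cohort=config.get("seed_cohort"), **kwargs)

    def _stage(self, name: str, fn, *args, **kwargs):
        logger.info("stage %s ...", name)
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # abort with the stage name attached
            raise PipelineError(name, str(exc)) from exc

    def fit(self, seed: int = 0) -> HallmarkResults:
        """Run the full pipeline; deterministic given ``seed``."""
        networks: dict[str, nx.Graph] = {}
        power_law: dict[str, PowerLawFit | None] = {}
        for cohort in sorted(self.cohorts):
            expr, _ = self.cohorts[cohort]
            networks[cohort] = self._stage(
                f"network[{cohort}]", build_network, expr, self.network_config,
                cohort=cohort)
            try:
                power_law[cohort] = fit_power_law(networks[cohort])
            except ValueError:
                power_law[cohort] = None

        communities = self._stage(
            "communities", find_complexes, networks[self.seed_cohort],
            self.mcode_params, cohort=self.seed_cohort)

        conservation = self._stage(
            "conservation", find_conserved, communities, networks,
            seed_cohort=self.seed_cohort, alpha=self.conservation_alpha,
            min_size=self.min_size, n_permutations=self.n_permutations,
            seed=derive_seed(seed, "conservation"))

        survival: dict[str, dict[str, SurvivalStratification | None]] = {}
        hallmarks: list[str] = []
        for res in conservation:
            if not res.is_conserved:
                continue
            per_cohort: dict[str, SurvivalStratification | None] = {}
            n_prognostic = 0
            for cohort in sorted(self.cohorts):
                expr, clinical = self.cohorts[cohort]
                try:
                    train, test = stratified_split(
                        clinical, derive_seed(seed, "split", res.community_id, cohort))
                    risk = fit_risk_model(expr[train], clinical[clinical["sample_id"].isin(train)],
                                          res.genes, cohort=cohort)
                    strat = stratify_and_test(
                        risk, expr[test], clinical[clinical["sample_id"].isin(test)])
                    per_cohort[cohort] = strat
                    if strat.p_value < self.survival_alpha:
                        n_prognostic += 1
                except ValueError as exc:
                    logger.info("survival[%s, %s] not estimable: %s",
                                res.community_id, cohort, exc)
                    per_cohort[cohort] = None
            survival[res.community_id] = per_cohort
            if n_prognostic >= self.hallmark_min_cohorts:
                hallmarks.append(res.community_id)

        annotations: dict[str, EnrichmentResult] = {}
        if self.genesets is not None:
            universe = self.universe
            if universe is None:
                universe = set()
                for expr, _ in self.cohorts.values():
                    universe |= set(expr.index)
            ann_all = self._stage(
                "annotation", annotate_communities, communities, self.genesets,
                universe, alpha=self.enrichment_alpha)
            conserved_ids = {r.community_id for r in conservation if r.is_conserved}
            annotations = {cid: a for cid, a in ann_all.items() if cid in conserved_ids}

        drug_screens: dict[str, DrugScreenResult] = {}
        if self.drugs is not None:
            universe_size = len(self.universe) if self.universe is not None else len(
                set().union(*(set(expr.index) for expr, _ in self.cohorts.values())))
            for hid in hallmarks:
                comm = communities[int(hid.lstrip("C"))]
                drug_screens[hid] = self._stage(
                    f"drug_screen[{hid}]", screen_drugs, comm.genes, self.drugs,
                    universe_size, alpha=self.enrichment_alpha, hallmark_id=hid)

        return HallmarkResults(
            model=self, seed=seed, networks=networks, power_law=power_law,
            communities=communities, conservation=conservation, survival=survival,
            hallmarks=hallmarks, annotations=annotations, drug_screens=drug_screens,
        )

    def robustness(self, seed: int = 0, *,
                   n_neighbors_variants: tuple[int, ...] = (),
                   seed_cohort_variants: tuple[str, ...] = (),
                   term_universe_size: int | None = None) -> dict:
        """Re-run the pipeline under parameter variants and compare annotations.

        For every variant (an alternate neighbour count and/or an alternate
        seed cohort) the pipeline is re-fitted and the GO-term sets of the
        conserved communities are compared with the baseline's by the
        hypergeometric overlap test over the term universe (default: all
        terms of the collection).  Requires ``genesets``.
        """
        if self.genesets is None:
            raise ValueError("robustness comparison needs gene set annotations")
        if term_universe_size is None:
            term_universe_size = len(self.genesets)
        baseline = self.fit(seed=seed)
        base_terms = baseline.conserved_terms()
        report = {"baseline": {"n_conserved": len(baseline.conserved),
                               "terms": sorted(base_terms)},
                  "variants": {}}
        variants: list[tuple[str, dict]] = []
        for n in n_neighbors_variants:
            variants.append((f"n_neighbors={n}",
                             {"network_config": NetworkConfig(
                                 n_neighbors=n,
                                 absolute_ranking=self.network_config.absolute_ranking)}))
        for cohort in seed_cohort_variants:
            variants.append((f"seed_cohort={cohort}", {"seed_cohort": cohort}))
        for label, override in variants:
            miner = HallmarkMiner(
                self.cohorts,
                seed_cohort=override.get("seed_cohort", self.seed_cohort),
                network_config=override.get("network_config", self.network_config),
                mcode_params=self.mcode_params,
                n_permutations=self.n_permutations,
                conservation_alpha=self.conservation_alpha,
                min_size=self.min_size, survival_alpha=self.survival_alpha,
                hallmark_min_cohorts=self.hallmark_min_cohorts,
                genesets=self.genesets, drugs=self.drugs,
                enrichment_alpha=self.enrichment_alpha, universe=self.universe)
            result = miner.fit(seed=seed)
            terms = result.conserved_terms()
            shared = sorted(base_terms & terms)
            overlap_p = goterm_overlap_test(base_terms, terms, term_universe_size) \
                if base_terms and terms else 1.0
            report["variants"][label] = {
                "n_conserved": len(result.conserved),
                "terms": sorted(terms),
                "shared_terms": shared,
                "overlap_p_value": overlap_p,
            }
        return report
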