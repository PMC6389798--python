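"""Hypergeometric over-representation tests.

One upper-tail statistic serves three screens: GO-style annotation of
communities, drug "appropriateness" (does a drug's target set overlap a
hallmark more than chance), and cancer-indication enrichment among the
drugs a hallmark selects.  For an overlap of x between a set of K and a
sample of N drawn from a universe of M,

    p = P(X >= x) = sum_{i=x}^{min(K,N)} C(K,i) C(M-K,N-i) / C(M,N).

The tail is accumulated in log space (log-gamma binomial coefficients and
log-sum-exp), which keeps p-values far below 1e-100 exact; naive
1 - CDF summation loses all precision below ~1e-12.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gammaln, logsumexp

from .io import GeneSetCollection
from .mcode import Community

__all__ = [
    "EnrichmentResult",
    "DrugScreenResult",
    "hypergeom_tail",
    "annotate_communities",
    "screen_drugs",
    "goterm_overlap_test",
]


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of one term in one query set."""

    query_id: str
    term_id: str | None
    term_name: str | None
    overlap: int  # x
    term_size: int  # K
    query_size: int  # N
    universe_size: int  # M
    p_value: float
    significant: bool


@dataclasses.dataclass(frozen=True)
class DrugScreenResult:
    """Drugs selected by one hallmark and their cancer-indication enrichment."""

    hallmark_id: str
    selected: dict[str, float]  # drug id -> target-overlap p-value
    cancer_selected: int
    cancer_in_db: int
    n_drugs_in_db: int
    indication_p_value: float


def _log_binom(n, k) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(x: int, K: int, N: int, M: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    X counts the overlap between a marked set of K and a sample of N drawn
    without replacement from a universe of M.  Computed in log space;
    symmetric in K and N.  x = 0 returns exactly 1.
    """
    if not (0 <= K <= M and 0 <= N <= M):
        raise ValueError(f"inconsistent counts: K={K}, N={N} must lie in [0, M={M}]")
    if not (0 <= x <= min(K, N)):
        raise ValueError(f"overlap x={x} outside [0, min(K={K}, N={N})]")
    if x == 0:
        return 1.0
    i = np.arange(x, min(K, N) + 1)
    log_pmf = _log_binom(K, i) + _log_binom(M - K, N - i) - _log_binom(M, N)
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def annotate_communities(communities: list[Community], genesets: GeneSetCollection,
                         universe, alpha: float = 0.05) -> dict[str, EnrichmentResult]:
    """Best-term annotation of each community by over-representation.

    For each community, every term with nonzero overlap is tested with
    x = |community ∩ term|, K = |term|, N = |community|, M = |universe|;
    the community's annotation is the minimal-p term (ties broken by larger
    overlap, then term id).  Communities overlapping no term are returned
    unannotated and non-significant.
    """
    if len(genesets) == 0:
        raise ValueError("empty gene set collection")
    universe = set(universe)
    M = len(universe)
    results: dict[str, EnrichmentResult] = {}
    for idx, comm in enumerate(communities):
        query_id = f"C{idx:03d}"
        genes = comm.gene_set & universe
        if not genes <= universe:
            raise ValueError("community genes outside the universe")
        best: EnrichmentResult | None = None
        for term in sorted(genesets.sets):
            members = genesets[term] & universe
            x = len(genes & members)
            if x == 0 or not members:
                continue
            p = hypergeom_tail(x, len(members), len(genes), M)
            cand = EnrichmentResult(
                query_id=query_id, term_id=term, term_name=genesets.names.get(term),
                overlap=x, term_size=len(members), query_size=len(genes),
                universe_size=M, p_value=p, significant=p < alpha,
            )
            if best is None or (cand.p_value, -cand.overlap, cand.term_id) < (
                best.p_value, -best.overlap, best.term_id
            ):
                best = cand
        if best is None:
            best = EnrichmentResult(
                query_id=query_id, term_id=None, term_name=None, overlap=0,
                term_size=0, query_size=len(genes), universe_size=M,
                p_value=1.0, significant=False,
            )
        results[query_id] = best
    return results


def screen_drugs(hallmark_genes, drugs, universe_size: int, alpha: float = 0.05,
                 hallmark_id: str = "hallmark") -> DrugScreenResult:
    """Screen a drug table against one hallmark gene set.

    A drug is selected ("appropriate") when the overlap of its target set
    with the hallmark is larger than chance: hypergeom_tail with
    x = |targets ∩ hallmark|, K = |hallmark|, N = |targets|, M =
    ``universe_size`` gives p < alpha.  Drugs with empty target sets are
    never selected.  The selected drugs are then tested for enrichment of
    cancer indications against the whole database: x = cancer-indicated
    among selected, K = cancer-indicated in the database, N = number
    selected, M = database size.
    """
    hallmark = frozenset(hallmark_genes)
    K = len(hallmark)
    selected: dict[str, float] = {}
    for drug_id in drugs.index:
        targets = drugs.at[drug_id, "targets"]
        if not targets:
            continue
        x = len(targets & hallmark)
        if x == 0:
            continue
        p = hypergeom_tail(x, K, len(targets), universe_size)
        if p < alpha:
            selected[drug_id] = p
    n_db = len(drugs)
    cancer_db = int(drugs["is_cancer"].sum())
    cancer_sel = int(drugs.loc[list(selected), "is_cancer"].sum()) if selected else 0
    if selected:
        indication_p = hypergeom_tail(cancer_sel, cancer_db, len(selected), n_db)
    else:
        indication_p = 1.0
    return DrugScreenResult(
        hallmark_id=hallmark_id, selected=selected, cancer_selected=cancer_sel,
        cancer_in_db=cancer_db, n_drugs_in_db=n_db, indication_p_value=indication_p,
    )


def goterm_overlap_test(terms_a, terms_b, universe_size: int) -> float:
    """Overlap significance of two term sets over a term universe.

    Used to compare the annotation sets produced by two pipeline variants
    (different neighbour counts or a different seed cohort):
    hypergeom_tail with x = |a ∩ b|, K = |a|, N = |b|, M = universe_size.
    """
    a = set(terms_a)
    b = set(terms_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("term set larger than the stated universe")
    return hypergeom_tail(len(a & b), len(a), len(b), universe_size)
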