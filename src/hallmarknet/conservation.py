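"""Permutation test for community conservation across cohort networks.

A community detected in a seed cohort is *conserved* in another cohort when
its gene set induces more edges in that cohort's co-expression network than
expected for a random gene set of the same size.  The test:

1. count the edges induced by the community's genes in the target network;
2. draw R (default 1000) uniform random gene sets of the same size from the
   target network's node set;
3. let X be the number of random sets inducing at least as many edges;
4. report p = X / R.

p is reported exactly as X/R (so p = 0 is possible); an add-one
("pseudo") estimate (X+1)/(R+1) is available for downstream consumers that
cannot tolerate zero.  A community is a candidate hallmark when it has at
least ``min_size`` genes and p < alpha in every non-seed cohort.

Each (community, cohort) pair gets its own RNG stream derived from the
master seed by stable hashing, so adding or reordering communities never
perturbs another community's draws.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from .mcode import Community
from .util import derive_seed

__all__ = [
    "ConservationResult",
    "induced_edge_count",
    "permutation_pvalue",
    "find_conserved",
    "derive_seed",
]


@dataclasses.dataclass(frozen=True)
class CohortConservation:
    """One community's permutation result in one target cohort."""

    observed_edges: int
    exceed_count: int  # X: random sets with >= observed edges
    n_permutations: int  # R
    n_genes_present: int  # |community genes ∩ network nodes|

    @property
    def p_value(self) -> float:
        return self.exceed_count / self.n_permutations

    @property
    def pseudo_p_value(self) -> float:
        return (self.exceed_count + 1) / (self.n_permutations + 1)


@dataclasses.dataclass(frozen=True)
class ConservationResult:
    community_id: str
    genes: tuple[str, ...]
    per_cohort: dict[str, CohortConservation]
    is_conserved: bool


def induced_edge_count(genes, net: nx.Graph) -> int:
    """Number of network edges with both endpoints in ``genes``.

    Genes absent from the network contribute no edges.
    """
    return net.subgraph(set(genes)).number_of_edges()


def permutation_pvalue(genes, net: nx.Graph, n_permutations: int = 1000,
                       seed: int | np.random.Generator = 0,
                       universe: list[str] | None = None,
                       shrink_to_present: bool = False) -> CohortConservation:
    """Permutation conservation test of one gene set against one network.

    Random sets are drawn uniformly without replacement from ``universe``
    (default: the nodes of ``net``).  By default the random sets match the
    *full* community size even when some community genes are absent from the
    network; ``shrink_to_present`` instead matches only the present subset.
    """
    genes = set(genes)
    if universe is None:
        universe = sorted(net.nodes())
    else:
        universe = sorted(universe)
    present = genes & set(net.nodes())
    size = len(present) if shrink_to_present else len(genes)
    if size > len(universe):
        raise ValueError(f"gene set size {size} exceeds sampling universe {len(universe)}")
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    observed = induced_edge_count(present, net)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Dense adjacency over the universe makes the R subgraph counts a
    # vectorized slice-and-sum instead of R networkx subgraph builds.
    index = {g: i for i, g in enumerate(universe)}
    adj = np.zeros((len(universe), len(universe)), dtype=bool)
    for u, v in net.edges():
        if u in index and v in index and u != v:
            adj[index[u], index[v]] = True
            adj[index[v], index[u]] = True
    exceed = 0
    for _ in range(n_permutations):
        pick = rng.choice(len(universe), size=size, replace=False)
        count = int(adj[np.ix_(pick, pick)].sum()) // 2
        if count >= observed:
            exceed += 1
    return CohortConservation(
        observed_edges=observed,
        exceed_count=exceed,
        n_permutations=n_permutations,
        n_genes_present=len(present),
    )


def find_conserved(communities: list[Community], networks: dict[str, nx.Graph],
                   seed_cohort: str | None = None, alpha: float = 0.05,
                   min_size: int = 5, n_permutations: int = 1000,
                   seed: int = 0, include_seed_cohort: bool = False,
                   shrink_to_present: bool = False) -> list[ConservationResult]:
    """Apply the conservation test to every community across all cohorts.

    ``is_conserved`` requires at least ``min_size`` genes and p < alpha in
    every non-seed cohort (the seed cohort, where the community was
    detected, is tested too only when ``include_seed_cohort`` is set).
    Results are returned for all communities, conserved or not.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 cohort networks")
    results = []
    for idx, comm in enumerate(communities):
        community_id = f"C{idx:03d}"
        per_cohort: dict[str, CohortConservation] = {}
        verdict = len(comm) >= min_size
        for cohort in sorted(networks):
            sub_seed = derive_seed(seed, ",".join(comm.genes), cohort)
            entry = permutation_pvalue(
                comm.genes, networks[cohort], n_permutations=n_permutations,
                seed=sub_seed, shrink_to_present=shrink_to_present,
            )
            per_cohort[cohort] = entry
            if cohort == seed_cohort and not include_seed_cohort:
                continue
            if entry.p_value >= alpha:
                verdict = False
        results.append(
            ConservationResult(
                community_id=community_id,
                genes=comm.genes,
                per_cohort=per_cohort,
                is_conserved=verdict,
            )
        )
    return results
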