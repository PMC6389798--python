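"""MCODE dense-cluster detection, reimplemented from the published algorithm.

MCODE finds dense regions ("complexes", here called communities) of a simple
undirected graph in three stages:

1. *Vertex weighting.*  The weight of a vertex v is the core-clustering
   coefficient of its closed neighbourhood: take the subgraph induced on
   v and its neighbours, extract its highest k-core, and multiply that
   core's density by its core number k_max.  Vertices whose neighbourhood
   supports no core of at least ``degree_cutoff`` get weight 0, as do
   isolated vertices.

2. *Complex prediction.*  Vertices are visited as seeds in descending
   weight order.  From an unvisited seed, the complex grows outward
   (breadth-first, up to ``max_depth``) over unvisited neighbours whose
   weight is at least ``(1 - node_score_cutoff)`` times the seed weight.
   Every included vertex is marked visited, so complexes are disjoint.

3. *Post-processing.*  Complexes that do not contain a k-core with
   k >= ``k_core_filter`` are discarded.  ``haircut`` iteratively strips
   vertices with degree 1 inside the complex; ``fluff`` (off by default)
   adds unvisited neighbours whose closed-neighbourhood density exceeds
   ``fluff_density_cutoff`` (fluffed vertices may belong to several
   complexes).

The complex score is density x size of the final complex subgraph.  All
orderings that the original implementation leaves to hash order are fixed
here by lexicographic gene id so results are fully deterministic.
"""

from __future__ import annotations

import dataclasses
from collections import deque

import networkx as nx

__all__ = ["McodeParams", "Community", "vertex_weights", "find_complexes"]


@dataclasses.dataclass(frozen=True)
class McodeParams:
    """MCODE parameters, at the published defaults."""

    include_loops: bool = False
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core_filter: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.node_score_cutoff <= 1:
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if self.degree_cutoff < 1 or self.k_core_filter < 0 or self.max_depth < 1:
            raise ValueError("degree_cutoff, k_core_filter and max_depth must be positive")


@dataclasses.dataclass(frozen=True)
class Community:
    """A detected dense community: its genes, seed, score and provenance."""

    genes: tuple[str, ...]
    seed: str
    score: float
    cohort: str | None = None

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError("community must contain at least one gene")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def _density(graph: nx.Graph, include_loops: bool) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    e = graph.number_of_edges()
    if include_loops:
        return 2.0 * e / (n * (n + 1))
    return 2.0 * e / (n * (n - 1))


def _highest_k_core(graph: nx.Graph) -> tuple[int, nx.Graph]:
    """Return (k_max, subgraph) for the highest non-empty k-core."""
    if graph.number_of_nodes() == 0:
        return 0, graph
    core_numbers = nx.core_number(graph)
    k_max = max(core_numbers.values())
    nodes = [v for v, c in core_numbers.items() if c >= k_max]
    return k_max, graph.subgraph(nodes)


def vertex_weights(net: nx.Graph, params: McodeParams | None = None) -> dict[str, float]:
    """Core-clustering-coefficient weight of every vertex of ``net``."""
    params = params or McodeParams()
    weights: dict[str, float] = {}
    for v in net.nodes():
        neighbours = list(net.neighbors(v))
        if not neighbours:
            weights[v] = 0.0
            continue
        closed = net.subgraph(neighbours + [v])
        k_max, core = _highest_k_core(closed)
        if k_max < params.degree_cutoff:
            weights[v] = 0.0
        else:
            weights[v] = k_max * _density(core, params.include_loops)
    return weights


def _grow_complex(net: nx.Graph, seed: str, weights: dict[str, float],
                  visited: set[str], params: McodeParams) -> list[str]:
    threshold = (1.0 - params.node_score_cutoff) * weights[seed]
    members = [seed]
    visited.add(seed)
    frontier = deque([(seed, 0)])
    while frontier:
        v, depth = frontier.popleft()
        if depth >= params.max_depth:
            continue
        for u in sorted(net.neighbors(v)):
            if u in visited:
                continue
            if weights[u] >= threshold:
                visited.add(u)
                members.append(u)
                frontier.append((u, depth + 1))
    return members


def _haircut(sub: nx.Graph) -> nx.Graph:
    sub = nx.Graph(sub)
    while True:
        leaves = [v for v, d in sub.degree() if d <= 1 and sub.number_of_nodes() > 1]
        if not leaves:
            return sub
        sub.remove_nodes_from(leaves)
        if sub.number_of_nodes() == 0:
            return sub


def _fluff(net: nx.Graph, members: list[str], visited: set[str], params: McodeParams) -> list[str]:
    extra = []
    member_set = set(members)
    candidates = sorted({u for v in members for u in net.neighbors(v)} - member_set - visited)
    for u in candidates:
        closed = net.subgraph(list(net.neighbors(u)) + [u])
        if _density(closed, params.include_loops) > params.fluff_density_cutoff:
            extra.append(u)  # fluffed vertices stay unvisited (may overlap)
    return members + extra


def find_complexes(net: nx.Graph, params: McodeParams | None = None,
                   cohort: str | None = None) -> list[Community]:
    """Run the full MCODE procedure on ``net``.

    Returns communities sorted by score descending, ties by size descending
    then lexicographic seed id.  Every returned community contains a k-core
    with k >= ``params.k_core_filter``.
    """
    params = params or McodeParams()
    if net.number_of_nodes() == 0:
        return []
    weights = vertex_weights(net, params)
    visited: set[str] = set()
    communities: list[Community] = []
    # Seeds in descending weight, ties by lexicographic id.
    for seed in sorted(net.nodes(), key=lambda v: (-weights[v], v)):
        if seed in visited or weights[seed] <= 0:
            continue
        members = _grow_complex(net, seed, weights, visited, params)
        sub = net.subgraph(members)
        core_numbers = nx.core_number(sub)
        if not core_numbers or max(core_numbers.values()) < params.k_core_filter:
            continue
        if params.haircut:
            sub = _haircut(sub)
        if params.fluff:
            members = _fluff(net, list(sub.nodes()), visited, params)
            sub = net.subgraph(members)
        if sub.number_of_nodes() == 0:
            continue
        score = _density(sub, params.include_loops) * sub.number_of_nodes()
        communities.append(
            Community(
                genes=tuple(sorted(sub.nodes())),
                seed=seed,
                score=float(score),
                cohort=cohort,
            )
        )
    communities.sort(key=lambda c: (-c.score, -len(c), c.seed))
    return communities
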