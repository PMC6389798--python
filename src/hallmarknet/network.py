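"""Rank-based gene co-expression networks and power-law degree fits.

A co-expression network is built in two steps.  First the Pearson
correlation r between every pair of gene expression profiles is computed
with the sample (n-1) convention,

    r = 1/(n-1) * sum_i ((X_i - Xbar)/s_X) * ((Y_i - Ybar)/s_Y).

Second, each gene nominates its top ``n_neighbors`` most correlated partner
genes as neighbours, and the network is the union of all nominated pairs as
an undirected simple graph.  Edge inclusion is therefore relative (rank
based) rather than threshold based, which keeps weakly but consistently
co-expressed pathways connected.  The construction guarantees a minimum
degree of ``min(n_neighbors, n_genes - 1)``.

Scale-freeness is assessed by an ordinary least-squares line on
(log10 k, log10 P(k)) over degrees with nonzero frequency.
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["NetworkConfig", "PowerLawFit", "pearson", "build_network", "fit_power_law"]


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    """Parameters of the rank-based construction.

    n_neighbors: how many partners each gene nominates (default 10).
    absolute_ranking: rank candidates by |r| instead of signed r.  The
        default ranks by the signed coefficient, so strong negative
        correlations are *not* treated as relevant.
    """

    n_neighbors: int = 10
    absolute_ranking: bool = False

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")


@dataclasses.dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10 P(k) on log10 k over nonzero-frequency degrees."""

    log_k: np.ndarray
    log_pk: np.ndarray
    slope: float
    intercept: float
    correlation: float
    r_squared: float


def pearson(x, y) -> float:
    """Sample Pearson correlation of two expression vectors.

    Uses the (n-1) denominator convention consistently in the numerator and
    in both standard deviations (the two conventions give the same r; the
    explicit form keeps the estimator auditable).  Raises ``ValueError`` for
    vectors shorter than 3 or with zero variance — such genes cannot be
    ranked and are excluded from network construction upstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    r = float(np.sum((x - x.mean()) / sx * (y - y.mean()) / sy) / (n - 1))
    return min(1.0, max(-1.0, r))


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson correlations of the rows (genes) of ``expr``."""
    values = expr.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def build_network(expr: pd.DataFrame, cfg: NetworkConfig | None = None,
                  cohort: str | None = None) -> nx.Graph:
    """Build the rank-based co-expression network of one cohort.

    Zero-variance genes are excluded entirely (their correlation is
    undefined).  For each remaining gene the ``cfg.n_neighbors`` candidates
    with the highest ranking key (signed r by default) are selected, ties at
    the rank-n boundary broken by lexicographic gene id; the edge set is the
    union over genes of all (gene, neighbour) pairs.
    """
    cfg = cfg or NetworkConfig()
    variances = expr.to_numpy(dtype=float).std(axis=1, ddof=1)
    usable = expr.index[variances > 0]
    if len(usable) < 2:
        raise ValueError("need at least 2 genes with nonzero variance")
    dropped = len(expr) - len(usable)
    if dropped:
        warnings.warn(f"excluded {dropped} zero-variance gene(s) from network construction")
    expr = expr.loc[usable]
    genes = list(expr.index)
    n_genes = len(genes)

    net = nx.Graph()
    net.add_nodes_from(genes)
    net.graph["cohort"] = cohort
    net.graph["n_neighbors"] = cfg.n_neighbors
    net.graph["absolute_ranking"] = cfg.absolute_ranking

    if cfg.n_neighbors >= n_genes:
        warnings.warn(
            f"n_neighbors={cfg.n_neighbors} >= {n_genes} genes: returning the complete graph"
        )
        net.add_edges_from((genes[i], genes[j]) for i in range(n_genes) for j in range(i + 1, n_genes))
        return net

    corr = correlation_matrix(expr).to_numpy()
    key = np.abs(corr) if cfg.absolute_ranking else corr.copy()
    np.fill_diagonal(key, -np.inf)  # self-pairs are never candidates

    # Rank candidates by key descending, ties broken by lexicographic gene id.
    gene_rank = np.argsort(np.argsort(np.array(genes)))
    for i in range(n_genes):
        order = np.lexsort((gene_rank, -key[i]))
        top = order[order != i][: cfg.n_neighbors]  # self sorts last (-inf key)
        for j in top:
            net.add_edge(genes[i], genes[j])
    return net


def fit_power_law(net: nx.Graph) -> PowerLawFit:
    """Least-squares power-law fit to the degree distribution of ``net``.

    P(k) is the raw relative frequency of degree k among nodes with k >= 1
    (no log-binning).  Requires at least 3 distinct positive degrees.
    R^2 equals the squared Pearson correlation of the fitted points by
    construction for a simple linear fit.
    """
    degrees = np.array([d for _, d in net.degree() if d > 0])
    if degrees.size == 0:
        raise ValueError("power-law fit undefined: network has no edges")
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValueError("power-law fit undefined: fewer than 3 distinct degrees")
    pk = counts / counts.sum()
    log_k = np.log10(ks.astype(float))
    log_pk = np.log10(pk)
    fit = stats.linregress(log_k, log_pk)
    return PowerLawFit(
        log_k=log_k,
        log_pk=log_pk,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        correlation=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
    )
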