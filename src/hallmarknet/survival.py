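"""Prognostic validation of a gene set by GGI risk scoring.

The protocol, applied per cohort with the genes of one community as the
signature:

1. split the cohort into two equal halves with matched event (death)
   ratios: a training and a test set;
2. on the training half, fit a univariate Cox proportional-hazards model
   per signature gene; the sign of the coefficient partitions the
   signature into risk genes (positive: higher expression, higher hazard)
   and protective genes (negative);
3. score each test patient with the Gene expression Grade Index,
   GGI = sum(expression of positive-coefficient genes)
       - sum(expression of negative-coefficient genes),
   unweighted by coefficient magnitude;
4. split the test half at the median GGI score (top half = high risk) and
   compare the two survival curves with the two-group log-rank test; the
   hazard ratio comes from a Cox fit on the group indicator.

The Cox partial likelihood is maximized by Newton's method with Efron's
approximation for tied event times.  Genes with zero variance on the
training half, or whose fit does not converge, are flagged and excluded
from both GGI sums.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RiskModel",
    "SurvivalStratification",
    "stratified_split",
    "cox_coefficient",
    "fit_risk_model",
    "ggi_score",
    "logrank_test",
    "stratify_and_test",
]

_MAX_BETA = 50.0  # |beta| beyond this is treated as a non-convergent fit


@dataclasses.dataclass(frozen=True)
class RiskModel:
    """Per-gene Cox coefficients partitioned by sign.

    ``coefficients`` maps gene -> fitted log hazard ratio, or ``None`` for
    flagged genes (zero variance / non-convergence).  Flagged and exactly
    zero coefficients belong to neither partition.
    """

    coefficients: dict[str, float | None]
    cohort: str | None = None

    @property
    def positive_genes(self) -> tuple[str, ...]:
        return tuple(sorted(g for g, b in self.coefficients.items() if b is not None and b > 0))

    @property
    def negative_genes(self) -> tuple[str, ...]:
        return tuple(sorted(g for g, b in self.coefficients.items() if b is not None and b < 0))

    @property
    def flagged_genes(self) -> tuple[str, ...]:
        return tuple(sorted(g for g, b in self.coefficients.items() if b is None))


@dataclasses.dataclass(frozen=True)
class SurvivalStratification:
    """Median-split GGI stratification of a test cohort with its log-rank test."""

    scores: pd.Series
    groups: pd.Series  # 'high' | 'low' per sample
    statistic: float
    p_value: float
    hazard_ratio: float


def stratified_split(clinical: pd.DataFrame, seed: int | np.random.Generator = 0,
                     ) -> tuple[list[str], list[str]]:
    """Split samples into two halves of equal size with matched event counts.

    Returns (train_ids, test_ids); sizes differ by at most 1 (the training
    half gets the extra sample), event counts by at most 1.  Reproducible
    from ``seed``.
    """
    n = len(clinical)
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = sorted(clinical.loc[clinical["event"] == 1, "sample_id"])
    censored = sorted(clinical.loc[clinical["event"] == 0, "sample_id"])
    rng.shuffle(events)
    rng.shuffle(censored)
    n_train = (n + 1) // 2
    e_train = (len(events) + 1) // 2
    c_train = n_train - e_train
    # Clamp to feasible allocations when one stratum is tiny.
    if c_train > len(censored):
        c_train = len(censored)
        e_train = n_train - c_train
    if c_train < 0:
        c_train = 0
        e_train = n_train
    train = sorted(events[:e_train] + censored[:c_train])
    test = sorted(events[e_train:] + censored[c_train:])
    return train, test


def _cox_loglik(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Efron partial log-likelihood of a single covariate (oracle-friendly)."""
    ll = 0.0
    theta = np.exp(beta * x)
    for t in np.unique(time[event == 1]):
        tied = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(tied.sum())
        s_risk = theta[at_risk].sum()
        s_tied = theta[tied].sum()
        ll += beta * x[tied].sum()
        for ell in range(d):
            ll -= np.log(s_risk - (ell / d) * s_tied)
    return float(ll)


def cox_coefficient(x, time, event, max_iter: int = 60, tol: float = 1e-9) -> float | None:
    """Univariate Cox coefficient by Newton's method (Efron ties).

    Returns the maximizer of the partial likelihood with the given gene's
    expression as sole covariate, or ``None`` when the gene is
    uninformative (zero variance, fewer than 2 events) or the maximizer
    diverges (monotone likelihood).
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2 or np.std(x) == 0:
        return None
    event_times = np.unique(time[event == 1])
    tied_masks = [(time == t) & (event == 1) for t in event_times]
    risk_masks = [time >= t for t in event_times]

    beta = 0.0
    for _ in range(max_iter):
        grad = 0.0
        hess = 0.0
        theta = np.exp(beta * x)
        wx = theta * x
        wxx = theta * x * x
        for tied, at_risk in zip(tied_masks, risk_masks):
            d = int(tied.sum())
            s0_r, s1_r, s2_r = theta[at_risk].sum(), wx[at_risk].sum(), wxx[at_risk].sum()
            s0_t, s1_t, s2_t = theta[tied].sum(), wx[tied].sum(), wxx[tied].sum()
            grad += x[tied].sum()
            for ell in range(d):
                f = ell / d
                s0 = s0_r - f * s0_t
                s1 = s1_r - f * s1_t
                s2 = s2_r - f * s2_t
                grad -= s1 / s0
                hess += s2 / s0 - (s1 / s0) ** 2
        if hess <= 0:
            return None
        step = grad / hess
        beta_new = beta + np.clip(step, -5.0, 5.0)
        if abs(beta_new) > _MAX_BETA:
            return None
        if abs(beta_new - beta) < tol:
            return float(beta_new)
        beta = beta_new
    return None


def fit_risk_model(expr: pd.DataFrame, clinical: pd.DataFrame, genes,
                   cohort: str | None = None) -> RiskModel:
    """Fit the per-gene univariate Cox coefficients of a signature.

    ``expr`` is genes x samples; ``clinical`` rows are matched to its
    columns by sample_id.  Signature genes missing from ``expr`` are
    flagged (excluded from both GGI sums) with a warning.
    """
    clinical = clinical.set_index("sample_id").loc[list(expr.columns)]
    time = clinical["time"].to_numpy(float)
    event = clinical["event"].to_numpy(int)
    coefficients: dict[str, float | None] = {}
    missing = [g for g in genes if g not in expr.index]
    if missing:
        warnings.warn(f"{len(missing)} signature gene(s) absent from expression matrix")
    for gene in genes:
        if gene not in expr.index:
            coefficients[gene] = None
            continue
        coefficients[gene] = cox_coefficient(expr.loc[gene].to_numpy(float), time, event)
    return RiskModel(coefficients=coefficients, cohort=cohort)


def ggi_score(model: RiskModel, expr: pd.DataFrame) -> pd.Series:
    """GGI risk score of every sample (column) of ``expr``.

    Sum of expression over positive-coefficient genes minus sum over
    negative-coefficient genes, unweighted.  Model genes missing from
    ``expr`` are dropped from the sums with a warning.
    """
    pos = [g for g in model.positive_genes if g in expr.index]
    neg = [g for g in model.negative_genes if g in expr.index]
    n_missing = len(model.positive_genes) + len(model.negative_genes) - len(pos) - len(neg)
    if n_missing:
        warnings.warn(f"{n_missing} model gene(s) missing from test matrix; dropped from GGI sums")
    scores = pd.Series(0.0, index=expr.columns)
    if pos:
        scores = scores + expr.loc[pos].sum(axis=0)
    if neg:
        scores = scores - expr.loc[neg].sum(axis=0)
    return scores


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test: ((O-E)^2/V, chi-square p-value).

    ``group`` is a boolean array (True = group 1).  O, E and V are the
    observed and expected group-1 event counts and the hypergeometric
    variance accumulated over distinct event times.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_j = int(at_risk.sum())
        n1_j = int((at_risk & group).sum())
        dying = (time == t) & (event == 1)
        d_j = int(dying.sum())
        d1_j = int((dying & group).sum())
        o_minus_e += d1_j - d_j * n1_j / n_j
        if n_j > 1:
            var += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    if var == 0:
        return 0.0, 1.0
    statistic = o_minus_e**2 / var
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def stratify_and_test(model: RiskModel, test_expr: pd.DataFrame,
                      test_clinical: pd.DataFrame) -> SurvivalStratification:
    """Median-split the test cohort by GGI score and test the separation.

    Samples scoring strictly above the median form the high-risk group;
    scores exactly at the median go to the low-risk group (for odd n this
    leaves the high-risk group as the smaller half).  The log-rank p-value
    comes from the chi-square(1) tail; the hazard ratio (high vs low) from
    a one-covariate Cox fit on the group indicator.
    """
    scores = ggi_score(model, test_expr)
    if scores.nunique() == 1:
        raise ValueError("degenerate stratification: all GGI scores identical")
    clinical = test_clinical.set_index("sample_id").loc[list(test_expr.columns)]
    median = float(np.median(scores.to_numpy()))
    high = scores > median
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("degenerate stratification: fewer than 2 samples in a group")
    groups = pd.Series(np.where(high, "high", "low"), index=scores.index)
    time = clinical["time"].to_numpy(float)
    event = clinical["event"].to_numpy(int)
    statistic, p_value = logrank_test(time, event, high.to_numpy())
    beta = cox_coefficient(high.to_numpy(float), time, event)
    if beta is None:
        warnings.warn("hazard ratio not estimable (Cox fit on group indicator diverged)")
        hr = float("nan")
    else:
        hr = float(np.exp(beta))
    return SurvivalStratification(
        scores=scores, groups=groups, statistic=statistic, p_value=p_value, hazard_ratio=hr,
    )
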