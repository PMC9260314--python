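"""Group-level inference for SWA composition studies.

Three procedures cover the study designs this package produces:

* event-count-weighted two-sample Welch t-tests (stage and age contrasts of
  late-fast percentages), with frequency-weight semantics — weights are
  rescaled to sum to the group n, so equal weights reduce exactly to the
  unweighted Welch test;
* negative-binomial GEE count ratios with exchangeable within-cluster
  correlation and robust (sandwich) standard errors, for within-subject
  channel comparisons and between-group bin counts; the NB dispersion is a
  method-of-moments estimate held fixed during the GEE fit;
* repeated-measures (paired, subject as the repeated factor) contrasts of
  ROI power, reported both as a raw difference and as a percent difference
  of the paired mean.

No multiple-testing correction is applied; each comparison is reported at
face value.  Degenerate zero-variance inputs return the exact estimate with
p = 0 (p = 1 when the estimate is 0) and a logged warning instead of
raising, so toy fixtures keep pipelines running.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

log = logging.getLogger(__name__)


@dataclass
class GroupComparisonResult:
    estimate: float
    ci_lo: float
    ci_hi: float
    p_value: float
    n_a: int
    n_b: int
    method: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float, int]:
    n = x.size
    w = w * (n / w.sum())            # frequency semantics: weights sum to n
    m = float(np.sum(w * x) / n)
    v = float(np.sum(w * (x - m) ** 2) / (n - 1))
    return m, v, n


def weighted_ttest(values_a: Sequence[float], weights_a: Sequence[float],
                   values_b: Sequence[float], weights_b: Sequence[float],
                   ) -> GroupComparisonResult:
    """Two-sample two-sided Welch t-test with frequency weights."""
    xa, wa = np.asarray(values_a, float), np.asarray(weights_a, float)
    xb, wb = np.asarray(values_b, float), np.asarray(weights_b, float)
    if xa.size != wa.size or xb.size != wb.size:
        raise ValueError("values and weights lengths must match")
    if xa.size < 2 or xb.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.any(wa <= 0) or np.any(wb <= 0):
        raise ValueError("weights must be positive")
    ma, va, na = _weighted_moments(xa, wa)
    mb, vb, nb = _weighted_moments(xb, wb)
    est = ma - mb
    se2 = va / na + vb / nb
    if se2 <= 0:
        log.warning("degenerate zero-variance t-test input")
        p = 1.0 if est == 0 else 0.0
        return GroupComparisonResult(est, est, est, p, na, nb,
                                     "weighted Welch t-test (degenerate)")
    se = float(np.sqrt(se2))
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = est / se
    p = float(2 * sstats.t.sf(abs(t), df))
    half = float(sstats.t.ppf(0.975, df)) * se
    return GroupComparisonResult(est, est - half, est + half, p, na, nb,
                                 "weighted Welch t-test",
                                 extra={"t": t, "df": float(df)})


def _nb_alpha_mom(counts: np.ndarray, cond: np.ndarray) -> float:
    """Method-of-moments NB dispersion: Var = mu + alpha * mu^2, pooled."""
    num = den = 0.0
    for c in np.unique(cond):
        x = counts[cond == c]
        mu = x.mean()
        if mu > 0 and x.size > 1:
            num += (x.var(ddof=1) - mu) * x.size
            den += mu ** 2 * x.size
    if den == 0:
        return 1e-8
    return float(np.clip(num / den, 1e-8, 10.0))


def clustered_nb_count_ratio(counts: Sequence[int], condition: Sequence[str],
                             cluster_id: Sequence[str]) -> GroupComparisonResult:
    """Negative-binomial GEE ratio of condition b to condition a counts.

    Log-link marginal model with exchangeable within-cluster correlation;
    returns exp(coefficient) with robust 95 % CI.  Conditions are ordered
    lexicographically: the ratio is second condition / first condition.
    """
    import statsmodels.api as sm

    y = np.asarray(counts, float)
    cond = np.asarray(condition)
    grp = np.asarray(cluster_id)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    levels = np.unique(cond)
    if levels.size != 2:
        raise ValueError("exactly two conditions required")
    if y.sum() == 0:
        raise ValueError("all counts are zero")
    ind = (cond == levels[1]).astype(float)
    n_a, n_b = int((ind == 0).sum()), int(ind.sum())
    mu_a, mu_b = y[ind == 0].mean(), y[ind == 1].mean()
    method = "negative-binomial GEE (exchangeable, robust SE)"

    va = y[ind == 0].var(ddof=1) if n_a > 1 else 0.0
    vb = y[ind == 1].var(ddof=1) if n_b > 1 else 0.0
    if va == 0 and vb == 0:
        log.warning("degenerate zero-variance count input")
        ratio = mu_b / mu_a
        p = 1.0 if np.isclose(ratio, 1.0) else 0.0
        return GroupComparisonResult(ratio, ratio, ratio, p, n_a, n_b,
                                     method + " (degenerate)")
    alpha = _nb_alpha_mom(y, cond)
    X = np.column_stack([np.ones_like(y), ind])
    model = sm.GEE(y, X, groups=grp,
                   family=sm.families.NegativeBinomial(alpha=alpha),
                   cov_struct=sm.cov_struct.Exchangeable())
    res = model.fit()
    b1, se = float(res.params[1]), float(res.bse[1])
    z = b1 / se if se > 0 else np.inf
    p = float(2 * sstats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    ratio = float(np.exp(b1))
    return GroupComparisonResult(
        ratio, float(np.exp(b1 - 1.959964 * se)), float(np.exp(b1 + 1.959964 * se)),
        p, n_a, n_b, method,
        extra={"alpha": alpha, "percent_difference": 100 * (ratio - 1),
               "conditions": (str(levels[0]), str(levels[1]))})


def repeated_measures_roi(power_a: Sequence[float], power_b: Sequence[float],
                          subject_id: Sequence[str]) -> GroupComparisonResult:
    """Within-subject contrast of ROI power (paired, subject as the factor).

    Estimate is the mean within-subject difference a − b; a percent-of-mean
    parameterization (100 · mean(a−b) / mean((a+b)/2)) rides along in
    ``extra``.
    """
    a = np.asarray(power_a, float)
    b = np.asarray(power_b, float)
    subj = np.asarray(subject_id)
    if not (a.size == b.size == subj.size):
        raise ValueError("power_a, power_b and subject_id must pair up")
    if np.unique(subj).size != subj.size:
        raise ValueError("duplicate subjects: inputs must be paired by subject")
    n = a.size
    d = a - b
    est = float(d.mean())
    pct = float(100 * est / np.mean((a + b) / 2)) if np.mean((a + b) / 2) != 0 else np.nan
    method = "repeated-measures (paired) contrast"
    if n < 2 or d.std(ddof=1) == 0:
        log.warning("degenerate zero-variance paired input")
        p = 1.0 if est == 0 else 0.0
        return GroupComparisonResult(est, est, est, p, n, n,
                                     method + " (degenerate)",
                                     extra={"percent_difference": pct})
    se = float(d.std(ddof=1) / np.sqrt(n))
    t = est / se
    p = float(2 * sstats.t.sf(abs(t), n - 1))
    half = float(sstats.t.ppf(0.975, n - 1)) * se
    return GroupComparisonResult(est, est - half, est + half, p, n, n, method,
                                 extra={"percent_difference": pct,
                                        "t": t, "df": n - 1})
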