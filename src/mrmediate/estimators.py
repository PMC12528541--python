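"""Causal-effect estimators for two-sample MR.

Given J harmonized SNPs with exposure effects beta_X (se_X) and outcome
effects beta_Y (se_Y), each estimator summarises the per-SNP Wald ratios
r_j = beta_Yj / beta_Xj into one causal effect on the additive scale:

* ``wald_ratio`` — single-SNP ratio with first-order se = se_Y/|beta_X|.
* ``ivw`` — inverse-variance weighted mean of the ratios, equivalent to a
  weighted regression of beta_Y on beta_X through the origin with weights
  1/se_Y^2.  The primary se is multiplicative random-effects: the
  fixed-effect se inflated by max(1, sqrt(Q/(J-1))), which reduces to the
  fixed-effect se under homogeneity; the fixed-effect se is kept in
  ``extra``.
* ``egger`` — the same weighted regression with a free intercept, after
  orienting every SNP to a non-negative exposure effect.  The slope is the
  pleiotropy-robust causal estimate; a non-zero intercept indicates
  directional horizontal pleiotropy.  Inference uses t quantiles with
  J - 2 degrees of freedom and residual inflation floored at 1.
* ``weighted_median`` — the 50th percentile of the weight-ordered ratio
  distribution (consistent when >= 50% of weight comes from valid
  instruments); its se comes from a parametric bootstrap.

Binary outcomes are on the log-odds scale throughout, so estimates are also
reported as odds ratios with 95% confidence bounds exp(beta +/- c*se) where
c is 1.96 for normal-based methods and the t quantile for MR-Egger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import MIN_PVALUE

__all__ = ["MREstimate", "wald_ratio", "ivw", "egger", "weighted_median"]

Z95 = 1.96


@dataclass
class MREstimate:
    """One method's causal-effect estimate with uncertainty.

    ``or_``/``ci_low``/``ci_high`` are exact exp-transforms of
    ``beta +/- crit*se`` where ``crit`` is 1.96 except for MR-Egger terms
    (t quantile, J-2 df).
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    crit: float = Z95
    extra: dict[str, Any] = dc_field(default_factory=dict)
    or_: float = dc_field(init=False)
    ci_low: float = dc_field(init=False)
    ci_high: float = dc_field(init=False)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        self.pvalue = float(min(max(self.pvalue, MIN_PVALUE), 1.0))
        self.or_ = math.exp(self.beta)
        self.ci_low = math.exp(self.beta - self.crit * self.se)
        self.ci_high = math.exp(self.beta + self.crit * self.se)


def _arrays(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = pairs["beta_exp"].to_numpy(dtype=float)
    sx = pairs["se_exp"].to_numpy(dtype=float)
    by = pairs["beta_out"].to_numpy(dtype=float)
    sy = pairs["se_out"].to_numpy(dtype=float)
    if np.isnan(bx).any() or np.isnan(by).any():
        raise ValueError("pairs contain NaN effects; filter to kept actions first")
    return bx, sx, by, sy


def _norm_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wald_ratio(pair: pd.Series | dict) -> MREstimate:
    """Single-SNP causal estimate: beta_Y/beta_X with first-order se."""
    bx = float(pair["beta_exp"])
    by = float(pair["beta_out"])
    sy = float(pair["se_out"])
    if bx == 0.0:
        raise ValueError("wald_ratio undefined for beta_exp = 0")
    beta = by / bx
    se = sy / abs(bx)
    return MREstimate(
        method="wald",
        beta=beta,
        se=se,
        pvalue=_norm_p(beta / se),
        n_snp=1,
    )


def ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effect IVW: (beta, se_fixed, Q). Pure-array kernel."""
    w = (bx * bx) / (sy * sy)
    beta = float(np.sum(bx * by / (sy * sy)) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    r = by / bx
    q = float(np.sum(w * (r - beta) ** 2))
    return beta, se_fixed, q


def ivw(pairs: pd.DataFrame) -> MREstimate:
    """Inverse-variance-weighted estimate over >= 1 harmonized pairs.

    Multiplicative random-effects: se = se_fixed * max(1, sqrt(Q/(J-1)))
    for J >= 2; equals the single-SNP Wald ratio at J = 1.
    """
    if len(pairs) < 1:
        raise ValueError("ivw requires at least one pair")
    bx, _, by, sy = _arrays(pairs)
    if np.any(bx == 0.0):
        raise ValueError("ivw requires all beta_exp != 0")
    beta, se_fixed, q = ivw_core(bx, by, sy)
    j = len(bx)
    if j >= 2:
        inflation = max(1.0, math.sqrt(q / (j - 1)))
    else:
        inflation = 1.0
    se = se_fixed * inflation
    return MREstimate(
        method="ivw",
        beta=beta,
        se=se,
        pvalue=_norm_p(beta / se),
        n_snp=j,
        extra={"se_fixed": se_fixed, "Q": q, "inflation": inflation},
    )


def egger(pairs: pd.DataFrame) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: returns (slope estimate, intercept estimate).

    Each pair is oriented so beta_exp >= 0 (both effects negated if needed),
    then beta_out is regressed on beta_exp with a free intercept and weights
    1/se_out^2.  Standard errors are the weighted-least-squares ones inflated
    by max(1, sqrt(Q_egger/(J-2))); p-values use the t distribution with
    J - 2 df.
    """
    if len(pairs) < 3:
        raise ValueError("egger requires at least 3 pairs")
    bx, _, by, sy = _arrays(pairs)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / (sy * sy)

    sw = float(np.sum(w))
    sx = float(np.sum(w * x))
    sy_ = float(np.sum(w * y))
    sxx = float(np.sum(w * x * x))
    sxy = float(np.sum(w * x * y))
    d = sw * sxx - sx * sx
    if d <= 0:
        raise ValueError("degenerate design: no spread in exposure effects")
    slope = (sw * sxy - sx * sy_) / d
    intercept = (sxx * sy_ - sx * sxy) / d
    j = len(x)
    resid = y - intercept - slope * x
    q_egger = float(np.sum(w * resid * resid))
    inflation = max(1.0, math.sqrt(q_egger / (j - 2)))
    se_slope = math.sqrt(sw / d) * inflation
    se_intercept = math.sqrt(sxx / d) * inflation
    tcrit = float(stats.t.ppf(0.975, j - 2))

    def _t_p(est: float, se: float) -> float:
        return float(min(1.0, 2.0 * stats.t.sf(abs(est / se), j - 2)))

    extra = {"Q_egger": q_egger, "inflation": inflation, "df": j - 2}
    slope_est = MREstimate(
        method="egger_slope", beta=slope, se=se_slope,
        pvalue=_t_p(slope, se_slope), n_snp=j, crit=tcrit, extra=dict(extra),
    )
    intercept_est = MREstimate(
        method="egger_intercept", beta=intercept, se=se_intercept,
        pvalue=_t_p(intercept, se_intercept), n_snp=j, crit=tcrit, extra=dict(extra),
    )
    return slope_est, intercept_est


def _weighted_median_core(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(
    pairs: pd.DataFrame, n_boot: int = 1000, seed: int = 42
) -> MREstimate:
    """Weighted-median causal estimate over >= 3 pairs.

    The point estimate interpolates the sorted Wald ratios across
    standardized cumulative weights at 0.5 with IVW weights
    beta_exp^2/se_out^2.  The se is the standard deviation of the estimate
    over ``n_boot`` parametric-bootstrap draws (effects resampled from
    normal(observed, se)), reproducible from ``seed``.
    """
    if len(pairs) < 3:
        raise ValueError("weighted_median requires at least 3 pairs")
    bx, sx, by, sy = _arrays(pairs)
    if np.any(bx == 0.0):
        raise ValueError("weighted_median requires all beta_exp != 0")
    ratios = by / bx
    weights = (bx * bx) / (sy * sy)
    beta = _weighted_median_core(ratios, weights)

    rng = np.random.default_rng(seed)
    j = len(bx)
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    # guard exact zeros in resampled exposure effects
    bx_star = np.where(bx_star == 0.0, np.finfo(float).tiny, bx_star)
    r_star = by_star / bx_star
    w_star = (bx_star * bx_star) / (sy * sy)
    order = np.argsort(r_star, axis=1, kind="stable")
    r_sorted = np.take_along_axis(r_star, order, axis=1)
    w_sorted = np.take_along_axis(w_star, order, axis=1)
    cum = np.cumsum(w_sorted, axis=1)
    s = (cum - 0.5 * w_sorted) / cum[:, -1:]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.interp(0.5, s[i], r_sorted[i])
    se = float(np.std(boots, ddof=1))
    if se == 0.0:
        se = np.finfo(float).tiny
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se,
        pvalue=_norm_p(beta / se),
        n_snp=j,
        extra={"n_boot": n_boot, "seed": seed},
    )
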