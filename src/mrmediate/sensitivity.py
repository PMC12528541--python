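"""Heterogeneity, pleiotropy, influence and outlier diagnostics.

* Cochran's Q — weighted sum of squared deviations of the per-SNP Wald
  ratios from the fixed-effect IVW estimate; chi-square with J-1 df.  Q also
  feeds the IVW multiplicative random-effects inflation, so
  Q = (J-1) * inflation^2 whenever inflation exceeds its floor.
* Leave-one-out — the IVW estimate recomputed with each SNP omitted in
  turn; a single influential variant shows up as the omission that moves
  the estimate furthest.
* MR-PRESSO — a parametric simulation test on the leave-one-out residual
  sum of squares: a global test for horizontal pleiotropy, per-SNP outlier
  p-values (Bonferroni-adjusted), and a distortion test comparing the
  outlier-corrected estimate shift with shifts from removing equally many
  random SNPs.  Empirical p-values use the add-one estimator and can never
  be exactly zero (minimum 1/(n_sim+1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, ivw, ivw_core, egger, _arrays

__all__ = [
    "SensitivityReport",
    "PressoResult",
    "cochran_q",
    "leave_one_out",
    "mr_presso",
    "sensitivity_report",
]


@dataclass
class PressoResult:
    global_p: float
    outliers: list[str]
    distortion_p: Optional[float]
    corrected: Optional[MREstimate]
    per_snp_p: dict[str, float] = field(default_factory=dict)
    rss_obs: float = float("nan")


@dataclass
class SensitivityReport:
    q: float
    q_df: int
    q_pvalue: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    loo: list[tuple[str, MREstimate]]
    presso_global_p: float
    presso_outliers: list[str]
    presso_distortion_p: Optional[float]


def cochran_q(pairs: pd.DataFrame) -> tuple[float, int, float]:
    """Heterogeneity of the per-SNP Wald ratios around the fixed-effect IVW.

    Returns (Q, df, p) with df = J - 1 and a chi-square upper-tail p.
    """
    if len(pairs) < 2:
        raise ValueError("cochran_q requires at least 2 pairs")
    bx, _, by, sy = _arrays(pairs)
    _, _, q = ivw_core(bx, by, sy)
    df = len(bx) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def leave_one_out(pairs: pd.DataFrame) -> list[tuple[str, MREstimate]]:
    """IVW re-estimated with each SNP omitted in turn, in input order."""
    if len(pairs) < 2:
        raise ValueError("leave_one_out requires at least 2 pairs")
    out = []
    for i in range(len(pairs)):
        rest = pairs.drop(pairs.index[i])
        out.append((str(pairs.iloc[i]["snp_id"]), ivw(rest)))
    return out


def _loo_beta(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW estimate excluding each SNP, vectorized (1-D)."""
    inv_v = 1.0 / (sy * sy)
    num = bx * by * inv_v
    den = bx * bx * inv_v
    return (num.sum() - num) / (den.sum() - den)


def _loo_beta_matrix(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Row-wise leave-one-out fixed-effect IVW for (n_sim, J) matrices."""
    inv_v = 1.0 / (sy * sy)  # (J,) broadcast over rows
    num = bx * by * inv_v
    den = bx * bx * inv_v
    return (num.sum(axis=1, keepdims=True) - num) / (
        den.sum(axis=1, keepdims=True) - den
    )


def mr_presso(
    pairs: pd.DataFrame,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 42,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed residual sum of squares is
    ``RSS = sum_j (beta_out_j - bhat_(-j) * beta_exp_j)^2 / se_out_j^2``
    with ``bhat_(-j)`` the fixed-effect IVW estimate excluding SNP j.  Its
    null distribution comes from ``n_sim`` parametric replicates drawing
    ``beta_out* ~ N(bhat_(-j)*beta_exp_j, se_out_j^2)`` and
    ``beta_exp* ~ N(beta_exp_j, se_exp_j^2)``.  Per-SNP outlier p-values
    compare each observed squared residual with its simulated distribution,
    Bonferroni-adjusted across the J instruments.  When outliers are found,
    the corrected estimate is IVW without them and the distortion p compares
    the observed estimate shift with shifts under removal of equally many
    SNPs chosen at random (exhaustively when there are at most 10,000
    subsets).
    """
    if len(pairs) < 4:
        raise ValueError("mr_presso requires at least 4 pairs")
    if n_sim < 100:
        warnings.warn(
            f"n_sim = {n_sim} is small; empirical p-values will be coarse",
            RuntimeWarning,
            stacklevel=2,
        )
    bx, sx, by, sy = _arrays(pairs)
    snp_ids = [str(s) for s in pairs["snp_id"]]
    j = len(bx)
    inv_v = 1.0 / (sy * sy)

    beta_loo = _loo_beta(bx, by, sy)
    resid_obs = inv_v * (by - beta_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(beta_loo * bx, sy, size=(n_sim, j))
    beta_loo_star = _loo_beta_matrix(bx_star, by_star, sy)
    resid_star = inv_v * (by_star - beta_loo_star * bx_star) ** 2
    rss_star = resid_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))

    per_snp_p = {}
    outliers = []
    for idx, snp in enumerate(snp_ids):
        p_raw = float((1 + np.sum(resid_star[:, idx] >= resid_obs[idx])) / (n_sim + 1))
        p_adj = min(1.0, p_raw * j)
        per_snp_p[snp] = p_adj
        if p_adj < outlier_alpha:
            outliers.append(snp)

    distortion_p: Optional[float] = None
    corrected: Optional[MREstimate] = None
    if outliers and len(outliers) < j:
        keep_mask = ~pairs["snp_id"].astype(str).isin(outliers).to_numpy()
        corrected = ivw(pairs.loc[keep_mask])
        full_beta, _, _ = ivw_core(bx, by, sy)
        shift_obs = corrected.beta - full_beta
        k_out = len(outliers)
        idx_all = np.arange(j)
        if comb(j, k_out) <= 10_000:
            subsets = list(combinations(idx_all, k_out))
        else:
            subsets = [
                tuple(rng.choice(j, size=k_out, replace=False)) for _ in range(n_sim)
            ]
        shifts = np.empty(len(subsets))
        for i, drop in enumerate(subsets):
            mask = np.ones(j, dtype=bool)
            mask[list(drop)] = False
            b_sub, _, _ = ivw_core(bx[mask], by[mask], sy[mask])
            shifts[i] = b_sub - full_beta
        distortion_p = float(
            (1 + np.sum(np.abs(shifts) >= abs(shift_obs))) / (len(subsets) + 1)
        )

    return PressoResult(
        global_p=global_p,
        outliers=outliers,
        distortion_p=distortion_p,
        corrected=corrected,
        per_snp_p=per_snp_p,
        rss_obs=rss_obs,
    )


def sensitivity_report(
    pairs: pd.DataFrame,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 42,
) -> SensitivityReport:
    """Full diagnostics block for one harmonized instrument set."""
    q, q_df, q_p = cochran_q(pairs)
    _, intercept = egger(pairs)
    loo = leave_one_out(pairs)
    presso = mr_presso(pairs, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)
    return SensitivityReport(
        q=q,
        q_df=q_df,
        q_pvalue=q_p,
        egger_intercept=intercept.beta,
        egger_intercept_se=intercept.se,
        egger_intercept_p=intercept.pvalue,
        loo=loo,
        presso_global_p=presso.global_p,
        presso_outliers=presso.outliers,
        presso_distortion_p=presso.distortion_p,
    )
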