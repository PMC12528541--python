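"""Two-step mediation: mediator screening, effect decomposition and FDR.

The mediation model decomposes the total causal effect beta of an exposure
on the outcome into an indirect path through one mediator and a direct
remainder, by the product-of-coefficients rule:

    indirect = beta1 * beta2          (exposure->mediator, mediator->outcome)
    direct   = beta  - beta1 * beta2
    proportion mediated = beta1 * beta2 / beta

All three coefficients are IVW estimates from separate two-sample MRs.  A
candidate mediator is screened in two steps: the exposure must affect it
(step 1) and it must affect the outcome (step 2), both at the nominal alpha;
among the survivors exactly one mediator is selected — the one whose
indirect effect shares the sign of the total effect (congruent) with the
smallest step-2 p-value.  Mediators whose step-2 odds-ratio confidence bound
sits on 1.00 at reporting precision are dropped as unstable.

The proportion is reported even when it falls outside [0, 1] or the signs
are incongruent (flagged, not clamped): hiding pathological decompositions
would mask real violations of the single-mediator model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .estimators import MREstimate

__all__ = ["MediationResult", "ScreenDecision", "decompose", "screen_mediators", "bh_fdr"]

SCREEN_REASONS = (
    "best_p_congruent",
    "dropped_incongruent",
    "dropped_unstable_ci",
    "dropped_nonsig",
    "dropped_not_best",
)


@dataclass
class MediationResult:
    """Effect decomposition for one exposure-mediator-outcome triple.

    ``direct + indirect == beta_total`` holds to full floating-point
    precision by construction, as does ``proportion * beta_total ==
    indirect``.
    """

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_total: float
    beta1: float
    beta2: float
    indirect: float
    direct: float
    proportion: float
    congruent: bool

    @property
    def proportion_pct(self) -> float:
        """Proportion mediated as a percentage, two decimals (table form)."""
        return round(100.0 * self.proportion, 2)


@dataclass
class ScreenDecision:
    mediator_id: str
    step1_p: float
    step2_p: float
    selected: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in SCREEN_REASONS:
            raise ValueError(f"unknown screening reason {self.reason!r}")


def decompose(
    beta_total: float,
    beta1: float,
    beta2: float,
    exposure_id: str = "",
    mediator_id: str = "",
    outcome_id: str = "",
) -> MediationResult:
    """Product-of-coefficients decomposition of a total causal effect."""
    if beta_total == 0.0:
        raise ValueError("beta_total = 0: proportion mediated is undefined")
    indirect = beta1 * beta2
    direct = beta_total - indirect
    proportion = indirect / beta_total
    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta_total=beta_total,
        beta1=beta1,
        beta2=beta2,
        indirect=indirect,
        direct=direct,
        proportion=proportion,
        congruent=bool(np.sign(indirect) == np.sign(beta_total)),
    )


def _ci_on_unity(est: MREstimate, tol: float = 0.005) -> bool:
    """True when an OR confidence bound rounds onto 1.00 at two decimals."""
    return (
        abs(round(est.ci_low, 2) - 1.0) < tol
        or abs(round(est.ci_high, 2) - 1.0) < tol
    )


def screen_mediators(
    step1: Mapping[str, MREstimate],
    step2: Mapping[str, MREstimate],
    total: MREstimate,
    alpha: float = 0.05,
) -> list[ScreenDecision]:
    """Two-step mediator screening with single-winner selection.

    Parameters
    ----------
    step1, step2
        Exposure->mediator and mediator->outcome IVW estimates keyed by
        mediator id.
    total
        The exposure->outcome (total-effect) IVW estimate.
    alpha
        Nominal significance level for both steps.

    Returns decisions in sorted mediator-id order; at most one is
    ``selected`` (the congruent, CI-stable survivor with the smallest
    step-2 p-value).
    """
    ids = sorted(set(step1) & set(step2))
    decisions: dict[str, ScreenDecision] = {}
    survivors: list[str] = []
    for mid in ids:
        p1 = step1[mid].pvalue
        p2 = step2[mid].pvalue
        if p1 >= alpha or p2 >= alpha:
            decisions[mid] = ScreenDecision(mid, p1, p2, False, "dropped_nonsig")
            continue
        indirect = step1[mid].beta * step2[mid].beta
        if np.sign(indirect) != np.sign(total.beta):
            decisions[mid] = ScreenDecision(mid, p1, p2, False, "dropped_incongruent")
            continue
        if _ci_on_unity(step2[mid]):
            decisions[mid] = ScreenDecision(mid, p1, p2, False, "dropped_unstable_ci")
            continue
        survivors.append(mid)
    if survivors:
        best = min(survivors, key=lambda m: (step2[m].pvalue, m))
        for mid in survivors:
            if mid == best:
                decisions[mid] = ScreenDecision(
                    mid, step1[mid].pvalue, step2[mid].pvalue, True, "best_p_congruent"
                )
            else:
                decisions[mid] = ScreenDecision(
                    mid, step1[mid].pvalue, step2[mid].pvalue, False, "dropped_not_best"
                )
    return [decisions[mid] for mid in ids]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values in input order.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p-values, mapped
    back to the original order.  Inputs must lie in (0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
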