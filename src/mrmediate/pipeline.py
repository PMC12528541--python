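"""Orchestration of the full bidirectional MR + mediation study design.

The workflow mirrors a microbiome -> metabolite -> disease mediation study
on GWAS summary statistics:

1. **Forward scan** — for every exposure trait: select candidate
   instruments at the relaxed threshold (default p < 1e-5), clump to
   independence, gate on instrument strength (F >= 10), harmonize against
   the outcome, run IVW / MR-Egger / weighted-median, and attach
   heterogeneity, pleiotropy and outlier diagnostics.  Benjamini-Hochberg
   q-values are computed across the exposure family's IVW p-values; both
   the uncorrected ("suggestive") and corrected tiers are reported.
2. **Reverse scan** — the outcome treated as exposure (default threshold
   p < 5e-5, at least 20 instruments wanted) against each original
   exposure, with identical machinery.
3. **Mediation** — for chosen exposures: exposure->mediator MR per
   candidate mediator, mediator->outcome MR, two-step screening with
   single-winner selection, then product-of-coefficients decomposition of
   the forward (total) effect.  Mediation proceeds on suggestive hits and
   is flagged exploratory.

Every stochastic step (weighted-median bootstrap, MR-PRESSO) derives its
seed deterministically from the run seed and the trait's position in sorted
order, so identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .estimators import MREstimate, egger, ivw, wald_ratio, weighted_median
from .harmonize import harmonize, kept_pairs
from .instruments import InstrumentSet, LDTable, build_instrument_set
from .mediation import MediationResult, ScreenDecision, bh_fdr, decompose, screen_mediators
from .sensitivity import SensitivityReport, sensitivity_report

logger = logging.getLogger("mrmediate")

__all__ = [
    "RunConfig",
    "TraitResult",
    "RunReport",
    "run_forward",
    "run_reverse",
    "run_mediation",
    "write_report",
]


@dataclass
class RunConfig:
    """Thresholds, seeds and simulation sizes for one pipeline run."""

    p_forward: float = 1e-5
    p_strict: float = 5e-8
    p_reverse: float = 5e-5
    alpha: float = 0.05
    r2_max: float = 0.001
    window_bp: int = 10_000_000
    f_min: float = 10.0
    reverse_min_snps: int = 20
    seed: int = 42
    n_boot: int = 1000
    n_sim: int = 1000

    def __post_init__(self) -> None:
        for name in ("p_forward", "p_strict", "p_reverse", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.f_min <= 0:
            raise ValueError("f_min must be positive")


def _child_seed(seed: int, index: int) -> int:
    """Deterministic per-trait seed below 2**31."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


@dataclass
class TraitResult:
    """All outputs for one exposure-outcome trait pair."""

    exposure_id: str
    outcome_id: str
    instruments: Optional[InstrumentSet] = None
    harmonization_tally: dict = field(default_factory=dict)
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: Optional[SensitivityReport] = None
    skipped: bool = False
    skip_reason: Optional[str] = None
    qvalue: Optional[float] = None


@dataclass
class RunReport:
    """Aggregated pipeline outputs plus provenance."""

    forward: dict[str, TraitResult] = field(default_factory=dict)
    reverse: dict[str, TraitResult] = field(default_factory=dict)
    screens: dict[str, list[ScreenDecision]] = field(default_factory=dict)
    mediations: list[MediationResult] = field(default_factory=list)
    exploratory: bool = True
    seed: int = 42
    software: str = f"mrmediate {__version__}"


def _split_by_trait(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {
        str(tid): sub.reset_index(drop=True)
        for tid, sub in records.groupby("trait_id", sort=True)
    }


def analyze_pair(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    config: RunConfig,
    p_threshold: float,
    ld: LDTable | None = None,
    seed: int | None = None,
    min_snps_warn: int | None = None,
) -> TraitResult:
    """One exposure-against-outcome MR with diagnostics.

    ``exposure`` must hold a single trait.  Skips (never raises) when no
    instrument survives selection, strength gating or harmonization.
    """
    exposure_id = str(exposure["trait_id"].iloc[0])
    outcome_id = str(outcome["trait_id"].iloc[0])
    seed = config.seed if seed is None else seed
    result = TraitResult(exposure_id=exposure_id, outcome_id=outcome_id)

    iset = build_instrument_set(
        exposure,
        p_threshold,
        ld=ld,
        r2_max=config.r2_max,
        window_bp=config.window_bp,
        min_snps_warn=min_snps_warn,
    )
    if iset is None:
        result.skipped = True
        result.skip_reason = "no_instruments"
        logger.info("%s -> %s: skipped (no instruments at p < %g)",
                    exposure_id, outcome_id, p_threshold)
        return result
    result.instruments = iset
    if iset.weak:
        result.skipped = True
        result.skip_reason = "weak_instruments"
        logger.info("%s -> %s: skipped (F = %.2f < %.1f)",
                    exposure_id, outcome_id, iset.F, config.f_min)
        return result

    exp_sel = exposure.loc[exposure["snp_id"].isin(iset.snp_ids)]
    out_sel = outcome.loc[outcome["snp_id"].isin(iset.snp_ids)]
    pairs_all, tally = harmonize(exp_sel, out_sel)
    result.harmonization_tally = tally
    pairs = kept_pairs(pairs_all)
    pairs = pairs.loc[pairs["beta_exp"] != 0.0].reset_index(drop=True)
    logger.info("%s -> %s: %d instruments, harmonization %s",
                exposure_id, outcome_id, len(pairs), tally)
    if len(pairs) < 1:
        result.skipped = True
        result.skip_reason = "no_harmonized_pairs"
        return result

    if len(pairs) == 1:
        result.estimates["wald"] = wald_ratio(pairs.iloc[0])
        result.estimates["ivw"] = ivw(pairs)
        return result

    result.estimates["ivw"] = ivw(pairs)
    if len(pairs) >= 3:
        slope, intercept = egger(pairs)
        result.estimates["egger_slope"] = slope
        result.estimates["egger_intercept"] = intercept
        result.estimates["weighted_median"] = weighted_median(
            pairs, n_boot=config.n_boot, seed=seed
        )
    if len(pairs) >= 4:
        result.sensitivity = sensitivity_report(
            pairs, n_sim=config.n_sim, seed=seed
        )
    return result


def run_forward(
    exposures: pd.DataFrame,
    outcome: pd.DataFrame,
    config: RunConfig,
    ld: LDTable | None = None,
) -> dict[str, TraitResult]:
    """Forward MR scan over every exposure trait, with family-wise FDR."""
    results: dict[str, TraitResult] = {}
    by_trait = _split_by_trait(exposures)
    for i, (tid, sub) in enumerate(by_trait.items()):
        results[tid] = analyze_pair(
            sub, outcome, config, config.p_forward, ld=ld,
            seed=_child_seed(config.seed, i),
        )
    tested = [tid for tid, r in results.items() if "ivw" in r.estimates]
    if tested:
        qvals = bh_fdr([results[tid].estimates["ivw"].pvalue for tid in tested])
        for tid, q in zip(tested, qvals):
            results[tid].qvalue = float(q)
    return results


def run_reverse(
    outcome: pd.DataFrame,
    exposures: pd.DataFrame,
    config: RunConfig,
    ld: LDTable | None = None,
) -> dict[str, TraitResult]:
    """Reverse MR: the outcome as exposure against each original exposure."""
    results: dict[str, TraitResult] = {}
    by_trait = _split_by_trait(exposures)
    for i, (tid, sub) in enumerate(by_trait.items()):
        results[tid] = analyze_pair(
            outcome, sub, config, config.p_reverse, ld=ld,
            seed=_child_seed(config.seed, 10_000 + i),
            min_snps_warn=config.reverse_min_snps,
        )
    return results


def run_mediation(
    exposures: pd.DataFrame,
    mediators: pd.DataFrame,
    outcome: pd.DataFrame,
    forward: Mapping[str, TraitResult],
    config: RunConfig,
    ld: LDTable | None = None,
    selected_exposures: list[str] | None = None,
) -> tuple[dict[str, list[ScreenDecision]], list[MediationResult]]:
    """Two-step mediator screening and decomposition for chosen exposures.

    ``selected_exposures`` defaults to every forward exposure with a
    suggestive IVW p < alpha (the exploratory tier).
    """
    outcome_id = str(outcome["trait_id"].iloc[0])
    med_by_trait = _split_by_trait(mediators)
    if selected_exposures is None:
        selected_exposures = [
            tid for tid, r in forward.items()
            if "ivw" in r.estimates and r.estimates["ivw"].pvalue < config.alpha
        ]
    screens: dict[str, list[ScreenDecision]] = {}
    mediations: list[MediationResult] = []
    exp_by_trait = _split_by_trait(exposures)
    for i, exp_id in enumerate(sorted(selected_exposures)):
        total = forward[exp_id].estimates.get("ivw")
        if total is None:
            continue
        exp_sub = exp_by_trait[exp_id]
        step1: dict[str, MREstimate] = {}
        step2: dict[str, MREstimate] = {}
        for k, (med_id, med_sub) in enumerate(med_by_trait.items()):
            r1 = analyze_pair(
                exp_sub, med_sub, config, config.p_forward, ld=ld,
                seed=_child_seed(config.seed, 20_000 + 100 * i + k),
            )
            r2 = analyze_pair(
                med_sub, outcome, config, config.p_forward, ld=ld,
                seed=_child_seed(config.seed, 30_000 + 100 * i + k),
            )
            if "ivw" in r1.estimates and "ivw" in r2.estimates:
                step1[med_id] = r1.estimates["ivw"]
                step2[med_id] = r2.estimates["ivw"]
        decisions = screen_mediators(step1, step2, total, alpha=config.alpha)
        screens[exp_id] = decisions
        for d in decisions:
            if d.selected:
                mediations.append(
                    decompose(
                        total.beta,
                        step1[d.mediator_id].beta,
                        step2[d.mediator_id].beta,
                        exposure_id=exp_id,
                        mediator_id=d.mediator_id,
                        outcome_id=outcome_id,
                    )
                )
    return screens, mediations


def _estimates_frame(results: Mapping[str, TraitResult], direction: str) -> pd.DataFrame:
    rows = []
    for tid in sorted(results):
        r = results[tid]
        if r.skipped:
            rows.append(
                dict(direction=direction, exposure=r.exposure_id, outcome=r.outcome_id,
                     method="", nsnp=0, beta=np.nan, se=np.nan, pvalue=np.nan,
                     or_=np.nan, ci_low=np.nan, ci_high=np.nan, qvalue=np.nan,
                     skip_reason=r.skip_reason)
            )
            continue
        for method, est in r.estimates.items():
            rows.append(
                dict(direction=direction, exposure=r.exposure_id, outcome=r.outcome_id,
                     method=method, nsnp=est.n_snp, beta=est.beta, se=est.se,
                     pvalue=est.pvalue, or_=est.or_, ci_low=est.ci_low,
                     ci_high=est.ci_high,
                     qvalue=r.qvalue if method == "ivw" else np.nan,
                     skip_reason="")
            )
    return pd.DataFrame(rows)


def report_frames(report: RunReport) -> dict[str, pd.DataFrame]:
    """Flatten a RunReport into delimited-table-ready frames."""
    frames = {}
    frames["mr_results"] = pd.concat(
        [
            _estimates_frame(report.forward, "forward"),
            _estimates_frame(report.reverse, "reverse"),
        ],
        ignore_index=True,
    )
    sens_rows = []
    for tid in sorted(report.forward):
        r = report.forward[tid]
        if r.sensitivity is None:
            continue
        s = r.sensitivity
        sens_rows.append(
            dict(exposure=r.exposure_id, outcome=r.outcome_id, q=s.q, q_df=s.q_df,
                 q_pvalue=s.q_pvalue, egger_intercept=s.egger_intercept,
                 egger_intercept_se=s.egger_intercept_se,
                 egger_intercept_p=s.egger_intercept_p,
                 presso_global_p=s.presso_global_p,
                 presso_outliers=";".join(s.presso_outliers),
                 presso_distortion_p=s.presso_distortion_p)
        )
    frames["sensitivity"] = pd.DataFrame(sens_rows)
    screen_rows = [
        dict(exposure=exp_id, mediator=d.mediator_id, step1_p=d.step1_p,
             step2_p=d.step2_p, selected=d.selected, reason=d.reason)
        for exp_id in sorted(report.screens)
        for d in report.screens[exp_id]
    ]
    frames["screen"] = pd.DataFrame(screen_rows)
    med_rows = [
        dict(exposure=m.exposure_id, mediator=m.mediator_id, outcome=m.outcome_id,
             total=m.beta_total, indirect=m.indirect, direct=m.direct,
             proportion_pct=m.proportion_pct, congruent=m.congruent,
             exploratory=report.exploratory)
        for m in report.mediations
    ]
    frames["mediation"] = pd.DataFrame(med_rows)
    return frames


def write_report(report: RunReport, out_dir) -> None:
    """Write the report frames as TSVs plus a provenance line."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in report_frames(report).items():
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    (out / "run_info.txt").write_text(
        f"software\t{report.software}\nseed\t{report.seed}\n"
        f"exploratory\t{report.exploratory}\n"
    )
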