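"""Instrumental-variable selection: p-value thresholding, LD clumping and
instrument-strength filtering.

Candidate instruments are SNPs below a per-analysis p-value threshold
(defaults: 5e-8 genome-wide, relaxed to 1e-5 for microbiome/metabolite
exposures, 5e-5 for the reverse direction).  Candidates are greedily clumped
to pairwise independence using a user-supplied table of pairwise LD r-squared
values (r^2 < 0.001 within a 10 Mb window by default).  Set-level instrument
strength is summarised by the F statistic

    F = [R^2 (n - k - 1)] / [k (1 - R^2)]

where R^2 is the variance in the exposure explained by the k retained SNPs
at sample size n; sets with F < 10 are flagged weak and excluded from
analysis.

Per-SNP variance explained is not defined by summary statistics alone; two
standard forms are provided: 2*eaf*(1-eaf)*beta^2 for a unit-variance trait
when the allele frequency is available, else t^2/(t^2 + n - 2) from the
t-statistic.  Ties everywhere break on (p-value, snp_id) for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LDTable",
    "InstrumentSet",
    "select_candidates",
    "clump",
    "snp_r2",
    "f_statistic",
    "build_instrument_set",
]


class LDTable:
    """Sparse symmetric pairwise LD (r-squared) lookup.

    Absent pairs mean r^2 = 0 (linkage equilibrium).
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        r2 = float(r2)
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {r2}")
        self._r2[self._key(a, b)] = r2

    def get(self, a: str, b: str) -> float:
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_file(cls, path, delimiter: str = "\t") -> "LDTable":
        """Read a 3-column (snp_a, snp_b, r2) delimited file with header."""
        df = pd.read_csv(path, sep=delimiter)
        if df.shape[1] < 3:
            raise ValueError("LD table needs 3 columns: snp_a, snp_b, r2")
        table = cls()
        a_col, b_col, r_col = df.columns[:3]
        for a, b, r2 in zip(df[a_col], df[b_col], df[r_col]):
            table.set(str(a), str(b), float(r2))
        return table


@dataclass
class InstrumentSet:
    """Independent instruments for one exposure with strength summary."""

    trait_id: str
    snp_ids: list[str]            # ordered by ascending p-value
    p_threshold: float
    r2: float                     # summed variance explained over retained SNPs
    k: int
    n: int
    F: float
    weak: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("InstrumentSet requires k >= 1")
        self.weak = self.F < 10.0


def select_candidates(records: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Rows with pvalue < p_threshold, sorted by (pvalue, snp_id).

    An empty result is allowed; the caller decides whether that skips the
    trait.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    hits = records.loc[records["pvalue"] < p_threshold]
    return hits.sort_values(["pvalue", "snp_id"], kind="mergesort").reset_index(drop=True)


def _within_window(row_a, row_b, window_bp: int) -> bool:
    chrom_a, chrom_b = row_a["chrom"], row_b["chrom"]
    pos_a, pos_b = row_a["pos"], row_b["pos"]
    if pd.isna(chrom_a) or pd.isna(chrom_b) or pd.isna(pos_a) or pd.isna(pos_b):
        # unknown coordinates: prune conservatively on r2 alone
        return True
    if str(chrom_a) != str(chrom_b):
        return False
    return abs(int(pos_a) - int(pos_b)) <= window_bp


def clump(
    candidates: pd.DataFrame,
    ld: LDTable | None = None,
    r2_max: float = 0.001,
    window_bp: int = 10_000_000,
) -> list[str]:
    """Greedy LD clumping of p-value-sorted candidates.

    Repeatedly accept the best remaining SNP and discard every remaining SNP
    within ``window_bp`` on the same chromosome whose r^2 with it is
    >= ``r2_max``.  Returns accepted snp_ids in acceptance order (ascending
    p-value).
    """
    ld = ld or LDTable()
    work = candidates.sort_values(["pvalue", "snp_id"], kind="mergesort")
    rows = list(work.to_dict("records"))
    accepted: list[str] = []
    while rows:
        best = rows.pop(0)
        accepted.append(best["snp_id"])
        rows = [
            r
            for r in rows
            if not (
                _within_window(best, r, window_bp)
                and ld.get(best["snp_id"], r["snp_id"]) >= r2_max
            )
        ]
    return accepted


def snp_r2(
    beta: float, se: float, n: int, eaf: float | None = None
) -> float:
    """Variance in the exposure explained by one SNP.

    With an effect-allele frequency: ``2*eaf*(1-eaf)*beta^2`` (per-allele
    beta on a unit-variance trait).  Without: ``t^2/(t^2 + n - 2)`` with
    ``t = beta/se``.
    """
    if eaf is not None and not (isinstance(eaf, float) and np.isnan(eaf)):
        return 2.0 * eaf * (1.0 - eaf) * beta * beta
    if n <= 2:
        raise ValueError("sample size must exceed 2 for the t-statistic form")
    t = beta / se
    return t * t / (t * t + n - 2)


def f_statistic(r2: float, n: int, k: int) -> float:
    """Instrument-strength F statistic: [R^2 (n - k - 1)] / [k (1 - R^2)]."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0, 1)")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    return (r2 * (n - k - 1)) / (k * (1.0 - r2))


def build_instrument_set(
    records: pd.DataFrame,
    p_threshold: float,
    ld: LDTable | None = None,
    r2_max: float = 0.001,
    window_bp: int = 10_000_000,
    min_snps_warn: int | None = None,
) -> InstrumentSet | None:
    """Select, clump and strength-summarise instruments for one trait.

    Returns None when no SNP passes the threshold.  If ``min_snps_warn`` is
    given and fewer instruments survive, a warning is emitted but the set is
    still returned (thresholds are never auto-relaxed).
    """
    trait_ids = records["trait_id"].unique()
    if len(trait_ids) != 1:
        raise ValueError("records must contain exactly one trait_id")
    candidates = select_candidates(records, p_threshold)
    if candidates.empty:
        return None
    kept_ids = clump(candidates, ld, r2_max=r2_max, window_bp=window_bp)
    kept = candidates.set_index("snp_id").loc[kept_ids]
    if min_snps_warn is not None and len(kept_ids) < min_snps_warn:
        warnings.warn(
            f"trait {trait_ids[0]!r}: only {len(kept_ids)} instruments at "
            f"p < {p_threshold:g} (wanted >= {min_snps_warn}); proceeding "
            "without relaxing the threshold",
            RuntimeWarning,
            stacklevel=2,
        )
    r2_total = float(
        sum(
            snp_r2(row.beta, row.se, int(row.n), None if pd.isna(row.eaf) else float(row.eaf))
            for row in kept.itertuples()
        )
    )
    n = int(kept["n"].max())
    k = len(kept_ids)
    r2_total = min(r2_total, np.nextafter(1.0, 0.0))  # guard pathological sums
    F = f_statistic(r2_total, n, k)
    return InstrumentSet(
        trait_id=str(trait_ids[0]),
        snp_ids=kept_ids,
        p_threshold=p_threshold,
        r2=r2_total,
        k=k,
        n=n,
        F=F,
    )
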