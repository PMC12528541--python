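"""Reading, validating and writing GWAS summary statistics.

Summary statistics are held in-memory as a :class:`pandas.DataFrame` with one
row per SNP-trait association and a fixed set of canonical columns
(:data:`CANONICAL_FIELDS`).  Effects are always on the additive scale: a
per-allele beta for quantitative traits and a log-odds ratio for binary
traits.  Files are delimited text with a header row (GWAS-SSF-like); the
mapping from canonical field names to source column headers is carried by a
:class:`ColumnMap` so that files from different consortia can be ingested
without renaming on disk.

Rows violating the record invariants (non-positive standard error, p-value
outside (0, 1], multi-allelic or malformed alleles, ...) are dropped and
counted per reason in a :class:`RejectionTally`; they are never silently
ignored.
"""

from __future__ import annotations

import math
import sys
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_FIELDS",
    "REQUIRED_FIELDS",
    "ColumnMap",
    "RejectionTally",
    "SumstatsError",
    "read_sumstats",
    "write_sumstats",
    "validate_records",
]

#: Canonical column names, in file-writing order.
CANONICAL_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
    "eaf",
    "n",
    "trait_id",
)

#: Fields that must have a mapped source column (eaf/chrom/pos may be absent).
REQUIRED_FIELDS = tuple(
    f for f in CANONICAL_FIELDS if f not in ("eaf", "chrom", "pos")
)

_VALID_BASES = frozenset("ACGT")

#: Smallest positive normal double; p-value strings that underflow (e.g.
#: "1e-400") are clamped here rather than becoming an invalid p = 0.
MIN_PVALUE = sys.float_info.min


class SumstatsError(ValueError):
    """Fatal configuration or input error (missing columns, unwritable path)."""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical field names to source column headers.

    Parameters
    ----------
    columns
        ``{canonical_field: source_header}``.  Every field in
        :data:`REQUIRED_FIELDS` must be present; ``eaf``, ``chrom`` and
        ``pos`` are optional.
    delimiter
        Field separator of the source file.
    na_values
        Strings treated as missing (the first is used as the sentinel when
        writing).
    effect_is_or
        If True the mapped effect column holds odds ratios and is
        log-transformed at ingest; the in-memory scale is always beta.
    """

    columns: Mapping[str, str]
    delimiter: str = "\t"
    na_values: tuple[str, ...] = ("NA", "nan", "")
    effect_is_or: bool = False

    def __post_init__(self) -> None:
        missing = [f for f in REQUIRED_FIELDS if f not in self.columns]
        if missing:
            raise SumstatsError(
                f"ColumnMap missing required canonical fields: {missing}"
            )
        unknown = [f for f in self.columns if f not in CANONICAL_FIELDS]
        if unknown:
            raise SumstatsError(f"ColumnMap has unknown canonical fields: {unknown}")

    @classmethod
    def identity(cls, **kwargs) -> "ColumnMap":
        """ColumnMap where source headers equal the canonical names."""
        return cls(columns={f: f for f in CANONICAL_FIELDS}, **kwargs)

    @property
    def sentinel(self) -> str:
        return self.na_values[0] if self.na_values else "NA"


@dataclass
class RejectionTally:
    """Per-reason counts of rows dropped during validation."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str, k: int = 1) -> None:
        if k:
            self.counts[reason] = self.counts.get(reason, 0) + int(k)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __eq__(self, other) -> bool:  # convenient for tests
        if isinstance(other, dict):
            return self.counts == other
        if isinstance(other, RejectionTally):
            return self.counts == other.counts
        return NotImplemented


def _to_float(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def validate_records(
    df: pd.DataFrame, *, effect_is_or: bool = False
) -> tuple[pd.DataFrame, RejectionTally]:
    """Apply the record invariants to a canonical-column frame.

    Returns the accepted rows (with numeric dtypes) and the rejection tally.
    Each rejected row is counted once, under the first failing reason in a
    fixed priority order.
    """
    tally = RejectionTally()
    n_rows = len(df)
    if n_rows == 0:
        out = df.copy()
        return out, tally

    work = df.copy()
    for col in ("effect_allele", "other_allele"):
        work[col] = work[col].astype("string").str.strip().str.upper()
    beta_raw = _to_float(work["beta"])
    se = _to_float(work["se"])
    pvalue = _to_float(work["pvalue"])
    n = _to_float(work["n"])
    eaf = _to_float(work["eaf"]) if "eaf" in work else pd.Series(np.nan, index=work.index)
    eaf_was_present = work["eaf"].notna() if "eaf" in work else pd.Series(False, index=work.index)

    if effect_is_or:
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = pd.Series(np.log(beta_raw.to_numpy(dtype=float)), index=work.index)
        bad_or = beta_raw.notna() & (beta_raw <= 0)
    else:
        beta = beta_raw
        bad_or = pd.Series(False, index=work.index)

    # underflowed p-value strings parse to 0.0; clamp rather than reject
    underflow = pvalue.notna() & (pvalue == 0.0)
    if underflow.any():
        warnings.warn(
            f"{int(underflow.sum())} p-value(s) at or below the representable "
            f"minimum clamped to {MIN_PVALUE!r}",
            RuntimeWarning,
            stacklevel=2,
        )
        pvalue = pvalue.mask(underflow, MIN_PVALUE)

    single_base = lambda s: s.notna() & s.isin(list(_VALID_BASES))  # noqa: E731

    reasons: list[tuple[str, pd.Series]] = [
        ("unparseable_numeric", beta_raw.isna() | se.isna() | pvalue.isna() | n.isna()),
        ("invalid_or", bad_or),
        ("multiallelic_or_invalid_allele",
         ~single_base(work["effect_allele"]) | ~single_base(work["other_allele"])),
        ("same_alleles", work["effect_allele"] == work["other_allele"]),
        ("nonpositive_se", se <= 0),
        ("pvalue_out_of_range", (pvalue <= 0) | (pvalue > 1)),
        ("nonpositive_n", n <= 0),
        ("eaf_out_of_range", eaf_was_present & (eaf.isna() | (eaf <= 0) | (eaf >= 1))),
    ]

    rejected = pd.Series(False, index=work.index)
    for reason, mask in reasons:
        mask = mask.fillna(False).astype(bool) & ~rejected
        tally.add(reason, int(mask.sum()))
        rejected |= mask

    keep = work.loc[~rejected].copy()
    keep["beta"] = beta.loc[keep.index].astype(float)
    keep["se"] = se.loc[keep.index].astype(float)
    keep["pvalue"] = pvalue.loc[keep.index].astype(float)
    keep["n"] = n.loc[keep.index].astype(int)
    keep["eaf"] = eaf.loc[keep.index].astype(float)
    keep["snp_id"] = keep["snp_id"].astype(str)
    keep["trait_id"] = keep["trait_id"].astype(str)
    if "chrom" in keep:
        keep["chrom"] = keep["chrom"].astype("string")
    else:
        keep["chrom"] = pd.Series(pd.NA, index=keep.index, dtype="string")
    if "pos" in keep:
        keep["pos"] = _to_float(keep["pos"]).astype("Int64")
    else:
        keep["pos"] = pd.Series(pd.NA, index=keep.index, dtype="Int64")
    keep["effect_allele"] = keep["effect_allele"].astype(str)
    keep["other_allele"] = keep["other_allele"].astype(str)
    return keep[list(CANONICAL_FIELDS)].reset_index(drop=True), tally


def read_sumstats(
    path, colmap: ColumnMap | None = None
) -> tuple[pd.DataFrame, RejectionTally]:
    """Read a delimited summary-statistics file.

    Parameters
    ----------
    path
        Path to a delimited text file with a header row.
    colmap
        Column mapping; defaults to :meth:`ColumnMap.identity`.

    Returns
    -------
    (records, tally)
        ``records`` is a canonical-column DataFrame in file order;
        ``tally`` counts the dropped rows per reason.

    Raises
    ------
    SumstatsError
        If a mapped column is absent from the header.
    """
    colmap = colmap or ColumnMap.identity()
    try:
        raw = pd.read_csv(
            path,
            sep=colmap.delimiter,
            dtype=str,
            na_values=list(colmap.na_values),
            keep_default_na=False,
        )
    except OSError as exc:
        raise SumstatsError(f"cannot read {path!r}: {exc}") from exc

    missing = [src for src in colmap.columns.values() if src not in raw.columns]
    if missing:
        raise SumstatsError(
            f"mapped column(s) {missing} not found in header of {path!r}"
        )
    canon = pd.DataFrame(
        {field: raw[src] for field, src in colmap.columns.items()}
    )
    for optional in ("eaf", "chrom", "pos"):
        if optional not in canon:
            canon[optional] = pd.NA
    return validate_records(canon, effect_is_or=colmap.effect_is_or)


def write_sumstats(records: pd.DataFrame, path, colmap: ColumnMap | None = None) -> None:
    """Write canonical records to a delimited file.

    Uses the colmap's source headers and missing-value sentinel.  Round-trips
    with :func:`read_sumstats` field-for-field (full float precision).  If
    ``colmap.effect_is_or`` the beta column is exponentiated back to an odds
    ratio on output.
    """
    colmap = colmap or ColumnMap.identity()
    out = pd.DataFrame(index=records.index)
    for field_name, src in colmap.columns.items():
        if field_name in records:
            col = records[field_name]
        else:
            col = pd.Series(pd.NA, index=records.index)
        if field_name == "beta" and colmap.effect_is_or:
            col = np.exp(col.astype(float))
        out[src] = col
    # full-precision text for floats; repr round-trips IEEE doubles
    for field_name, src in colmap.columns.items():
        if field_name in ("beta", "se", "pvalue", "eaf"):
            out[src] = [
                colmap.sentinel if (x is None or (isinstance(x, float) and math.isnan(x)) or x is pd.NA)
                else repr(float(x))
                for x in out[src]
            ]
    try:
        out.to_csv(path, sep=colmap.delimiter, index=False, na_rep=colmap.sentinel)
    except OSError as exc:
        raise SumstatsError(f"cannot write {path!r}: {exc}") from exc


def records_frame(rows: Sequence[dict]) -> pd.DataFrame:
    """Build a canonical frame from dicts (test/construction convenience)."""
    df = pd.DataFrame(rows)
    for optional in ("eaf", "chrom", "pos"):
        if optional not in df:
            df[optional] = pd.NA
    return df[list(CANONICAL_FIELDS)]
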