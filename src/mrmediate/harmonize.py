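"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs both effect estimates for a SNP expressed on the same
effect allele.  The exposure orientation is canonical; the outcome record is
kept as-is, sign-flipped (when its alleles are swapped relative to the
exposure), or resolved through a strand complement (when the outcome file was
reported on the opposite DNA strand).  Palindromic SNPs (A/T or C/G), whose
strand cannot be resolved from alleles alone, are dropped unconditionally, as
are allele pairs that match under no orientation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ACTIONS", "harmonize", "is_palindromic", "classify_alleles"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Possible per-SNP harmonization outcomes.
ACTIONS = (
    "kept_as_is",
    "flipped",
    "dropped_palindromic",
    "dropped_incompatible",
    "dropped_missing",
)

PAIR_COLUMNS = [
    "snp_id",
    "beta_exp",
    "se_exp",
    "beta_out",
    "se_out",
    "eaf_exp",
    "eaf_out",
    "action",
]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for complementary allele pairs (A/T or C/G)."""
    return _COMPLEMENT.get(effect_allele) == other_allele


def classify_alleles(
    exp_ea: str, exp_oa: str, out_ea: str, out_oa: str
) -> str:
    """Classify one SNP's allele configuration.

    Returns one of ``kept_as_is``, ``flipped``, ``dropped_palindromic`` or
    ``dropped_incompatible``.  Palindromy is judged on the exposure side and
    takes precedence over everything else.
    """
    if is_palindromic(exp_ea, exp_oa):
        return "dropped_palindromic"
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return "kept_as_is"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return "flipped"
    c_ea = _COMPLEMENT.get(out_ea)
    c_oa = _COMPLEMENT.get(out_oa)
    if (c_ea, c_oa) == (exp_ea, exp_oa):
        return "kept_as_is"
    if (c_ea, c_oa) == (exp_oa, exp_ea):
        return "flipped"
    return "dropped_incompatible"


def _check_unique(df: pd.DataFrame, side: str) -> None:
    dup = df["snp_id"].duplicated()
    if dup.any():
        ids = df.loc[dup, "snp_id"].unique()[:5]
        raise ValueError(f"duplicate snp_id on {side} side (ambiguous join): {list(ids)}")


def harmonize(
    exposure: pd.DataFrame, outcome: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join exposure and outcome records on snp_id and align effect alleles.

    Parameters
    ----------
    exposure, outcome
        Canonical summary-statistics frames (see :mod:`mrmediate.sumstats`).

    Returns
    -------
    (pairs, tally)
        ``pairs`` has one row per SNP in the union of the two sides with
        columns ``snp_id, beta_exp, se_exp, beta_out, se_out, eaf_exp,
        eaf_out, action``; flipped rows have ``beta_out`` negated and
        ``eaf_out`` replaced by ``1 - eaf_out``.  Dropped rows keep NaN
        effect columns.  ``tally`` counts actions and sums to the size of
        the snp_id union.
    """
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")

    exp = exposure.set_index("snp_id")
    out = outcome.set_index("snp_id")
    all_ids = list(dict.fromkeys(list(exp.index) + [i for i in out.index if i not in exp.index]))

    rows = []
    tally = {a: 0 for a in ACTIONS}
    for snp in all_ids:
        in_exp = snp in exp.index
        in_out = snp in out.index
        if not (in_exp and in_out):
            tally["dropped_missing"] += 1
            rows.append(
                dict(snp_id=snp, beta_exp=np.nan, se_exp=np.nan, beta_out=np.nan,
                     se_out=np.nan, eaf_exp=np.nan, eaf_out=np.nan,
                     action="dropped_missing")
            )
            continue
        e = exp.loc[snp]
        o = out.loc[snp]
        action = classify_alleles(
            e["effect_allele"], e["other_allele"],
            o["effect_allele"], o["other_allele"],
        )
        tally[action] += 1
        beta_out = float(o["beta"])
        eaf_out = float(o["eaf"]) if pd.notna(o["eaf"]) else np.nan
        if action == "flipped":
            beta_out = -beta_out
            if not np.isnan(eaf_out):
                eaf_out = 1.0 - eaf_out
        keep = action in ("kept_as_is", "flipped")
        rows.append(
            dict(
                snp_id=snp,
                beta_exp=float(e["beta"]) if keep else np.nan,
                se_exp=float(e["se"]) if keep else np.nan,
                beta_out=beta_out if keep else np.nan,
                se_out=float(o["se"]) if keep else np.nan,
                eaf_exp=float(e["eaf"]) if keep and pd.notna(e["eaf"]) else np.nan,
                eaf_out=eaf_out if keep else np.nan,
                action=action,
            )
        )
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return pairs, tally


def kept_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Subset of harmonized pairs usable by the estimators."""
    return pairs.loc[pairs["action"].isin(["kept_as_is", "flipped"])].reset_index(drop=True)
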