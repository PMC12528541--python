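import numpy as np
import pandas as pd
import pytest

from mrmediate.sumstats import CANONICAL_FIELDS


def make_records(rows):
    """Canonical summary-statistics frame from a list of dicts."""
    defaults = dict(
        chrom="1", pos=1000, effect_allele="A", other_allele="G",
        beta=0.1, se=0.05, pvalue=0.04, eaf=0.3, n=10000, trait_id="trait",
    )
    full = []
    for i, row in enumerate(rows):
        d = dict(defaults, snp_id=f"rs{i+1}")
        d.update(row)
        full.append(d)
    if not full:
        df = pd.DataFrame(columns=list(CANONICAL_FIELDS))
    else:
        df = pd.DataFrame(full)
    df["chrom"] = df["chrom"].astype("string")
    df["pos"] = df["pos"].astype("Int64")
    return df[list(CANONICAL_FIELDS)]


def make_pairs(beta_exp, beta_out, se_out, se_exp=None, snp_ids=None):
    """Harmonized-pair frame (kept actions only) from effect arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    if se_exp is None:
        se_exp = np.full_like(beta_exp, 0.01)
    else:
        se_exp = np.asarray(se_exp, dtype=float)
    j = len(beta_exp)
    return pd.DataFrame(
        dict(
            snp_id=snp_ids if snp_ids is not None else [f"rs{i+1}" for i in range(j)],
            beta_exp=beta_exp,
            se_exp=se_exp,
            beta_out=beta_out,
            se_out=se_out,
            eaf_exp=np.nan,
            eaf_out=np.nan,
            action="kept_as_is",
        )
    )


@pytest.fixture
def pairs_factory():
    return make_pairs


@pytest.fixture
def records_factory():
    return make_records
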