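"""Instrument selection: thresholding, greedy clumping, strength statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrmediate.instruments import (
    LDTable,
    build_instrument_set,
    clump,
    f_statistic,
    select_candidates,
    snp_r2,
)

from conftest import make_records


class TestSelectCandidates:
    def test_threshold_examples(self):
        records = make_records(
            [dict(pvalue=1e-9), dict(pvalue=2e-6), dict(pvalue=3e-4)]
        )
        assert list(select_candidates(records, 1e-5)["snp_id"]) == ["rs1", "rs2"]
        assert list(select_candidates(records, 5e-8)["snp_id"]) == ["rs1"]

    def test_matches_brute_force_on_random_records(self):
        rng = np.random.default_rng(0)
        records = make_records([dict(pvalue=p) for p in rng.uniform(1e-9, 1, 1000)])
        got = select_candidates(records, 0.01)
        expected = sorted(
            [
                (p, s)
                for p, s in zip(records["pvalue"], records["snp_id"])
                if p < 0.01
            ]
        )
        assert list(zip(got["pvalue"], got["snp_id"])) == expected

    def test_tie_break_is_lexicographic(self):
        records = make_records(
            [dict(snp_id="rsB", pvalue=1e-6), dict(snp_id="rsA", pvalue=1e-6)]
        )
        assert list(select_candidates(records, 1e-5)["snp_id"]) == ["rsA", "rsB"]


class TestClump:
    def test_correlated_neighbours_pruned_to_best_p(self):
        cands = make_records(
            [dict(snp_id="rs1", pos=1000, pvalue=1e-8),
             dict(snp_id="rs2", pos=2000, pvalue=1e-6)]
        )
        ld = LDTable({("rs1", "rs2"): 0.5})
        assert clump(cands, ld) == ["rs1"]

    def test_different_chromosomes_escape_window(self):
        cands = make_records(
            [dict(snp_id="rs1", chrom="1", pos=1000, pvalue=1e-8),
             dict(snp_id="rs2", chrom="2", pos=2000, pvalue=1e-6)]
        )
        ld = LDTable({("rs1", "rs2"): 0.5})
        assert clump(cands, ld) == ["rs1", "rs2"]

    def test_far_apart_same_chromosome_escape_window(self):
        cands = make_records(
            [dict(snp_id="rs1", pos=1, pvalue=1e-8),
             dict(snp_id="rs2", pos=20_000_002, pvalue=1e-6)]
        )
        ld = LDTable({("rs1", "rs2"): 0.5})
        assert clump(cands, ld) == ["rs1", "rs2"]

    def test_random_fixture_matches_greedy_oracle(self):
        rng = np.random.default_rng(42)
        n = 50
        cands = make_records(
            [
                dict(snp_id=f"rs{i:02d}", chrom=str(rng.integers(1, 4)),
                     pos=int(rng.integers(1, 30_000_000)), pvalue=float(rng.uniform(1e-9, 1e-5)))
                for i in range(n)
            ]
        )
        ld = LDTable()
        ids = list(cands["snp_id"])
        for _ in range(200):
            a, b = rng.choice(ids, 2, replace=False)
            ld.set(a, b, float(rng.uniform(0, 1)))
        kept = clump(cands, ld)

        rows = {r["snp_id"]: r for r in cands.to_dict("records")}

        def conflict(a, b):
            ra, rb = rows[a], rows[b]
            same_window = ra["chrom"] == rb["chrom"] and abs(ra["pos"] - rb["pos"]) <= 10_000_000
            return same_window and ld.get(a, b) >= 0.001

        # output is pairwise independent
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert not conflict(a, b)
        # and greedy-consistent/maximal: every rejected SNP conflicts with an
        # accepted SNP of smaller p-value
        order = {s: (p, s) for s, p in zip(cands["snp_id"], cands["pvalue"])}
        for s in ids:
            if s in kept:
                continue
            assert any(conflict(s, a) for a in kept if order[a] < order[s])


class TestSnpR2:
    def test_zero_beta_explains_nothing(self):
        assert snp_r2(0.0, 0.01, 1000, eaf=0.3) == 0.0

    def test_frequency_form(self):
        assert snp_r2(0.1, 0.01, 1000, eaf=0.5) == pytest.approx(0.005)

    def test_t_statistic_fallback(self):
        # t = 5, n = 1000 -> r2 = 25/1023
        assert snp_r2(0.05, 0.01, 1000, eaf=None) == pytest.approx(25 / 1023)
        assert snp_r2(0.05, 0.01, 1000, eaf=float("nan")) == pytest.approx(25 / 1023)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            snp_r2(0.1, 0.01, 2, eaf=None)


class TestFStatistic:
    def test_printed_formula_values(self):
        assert f_statistic(0.0, 100, 1) == 0.0
        assert f_statistic(0.01, 18340, 10) == pytest.approx(
            (0.01 * 18329) / (10 * 0.99)
        )
        # single instrument explaining 0.1% of variance in the microbiome GWAS
        f = f_statistic(0.001, 18340, 1)
        assert f == pytest.approx(18.356, abs=1e-2)
        assert f >= 10  # strong enough to retain

    @pytest.mark.parametrize("r2,n,k", [(1.0, 100, 1), (0.5, 3, 2), (0.5, 10, 0)])
    def test_domain_errors(self, r2, n, k):
        with pytest.raises(ValueError):
            f_statistic(r2, n, k)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        r2=st.floats(0.001, 0.5),
        n=st.integers(100, 10**6),
        k=st.integers(1, 50),
        dr2=st.floats(1e-4, 0.4),
        dn=st.integers(1, 1000),
    )
    def test_monotonicity(self, r2, n, k, dr2, dn):
        base = f_statistic(r2, n, k)
        assert f_statistic(min(r2 + dr2, 0.95), n, k) > base
        assert f_statistic(r2, n + dn, k) > base
        if n > k + 2:
            assert f_statistic(r2, n, k + 1) < base


class TestBuildInstrumentSet:
    def test_weak_set_is_flagged(self):
        records = make_records(
            [dict(pvalue=1e-6, beta=0.01, se=0.004, eaf=0.5, n=18340)]
        )
        iset = build_instrument_set(records, 1e-5)
        assert iset.k == 1
        assert iset.F < 10 and iset.weak

    def test_strong_set_not_flagged(self):
        records = make_records(
            [dict(pvalue=1e-12, beta=0.1, se=0.01, eaf=0.5, n=18340)]
        )
        iset = build_instrument_set(records, 1e-5)
        assert iset.F > 10 and not iset.weak

    def test_no_candidates_returns_none(self):
        records = make_records([dict(pvalue=0.5)])
        assert build_instrument_set(records, 1e-5) is None

    def test_too_few_snps_warns_but_proceeds(self):
        records = make_records([dict(pvalue=1e-6, beta=0.1, se=0.01)])
        with pytest.warns(RuntimeWarning, match="without relaxing"):
            iset = build_instrument_set(records, 1e-5, min_snps_warn=20)
        assert iset is not None and iset.k == 1
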