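"""Fisher's exact test against enumeration oracles; per-site, windowed
and per-gene differential methylation."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from epimung.differential import (
    dmr_scan,
    fisher_two_sided,
    gene_differential,
    per_site_tests,
    scan_window_pvalues,
)
from epimung.io_formats import FeatureRecord
from tests.conftest import make_calls


def oracle_fisher(m1, u1, m2, u2) -> float:
    """Exact-rational enumeration oracle: iterate every table with the
    observed margins and sum the probabilities of those no more likely
    than the observed table (ties exact)."""
    N, n, K = m1 + u1 + m2 + u2, m1 + u1, m1 + m2
    total = comb(N, K)
    probs = {k: Fraction(comb(n, k) * comb(N - n, K - k), total)
             for k in range(max(0, n - (N - K)), min(n, K) + 1)}
    if len(probs) <= 1:
        return 1.0
    obs = probs[m1]
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= obs)))


class TestFisher:
    def test_maximally_split_table(self):
        assert fisher_two_sided(10, 0, 0, 10) == pytest.approx(2 / comb(20, 10), rel=1e-12)

    def test_identical_proportions(self):
        assert fisher_two_sided(5, 5, 5, 5) == 1.0

    def test_two_outcome_table(self):
        # both admissible tables are equally probable
        assert fisher_two_sided(1, 0, 0, 1) == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided(0, 0, 0, 0)

    def test_zero_column_margin_is_certain(self):
        assert fisher_two_sided(0, 5, 0, 7) == 1.0

    def test_sample_swap_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m1, u1, m2, u2 = rng.integers(0, 40, 4)
            if m1 + u1 + m2 + u2 == 0:
                continue
            assert fisher_two_sided(m1, u1, m2, u2) == pytest.approx(
                fisher_two_sided(m2, u2, m1, u1), rel=1e-12)

    @settings(max_examples=150, derandomize=True)
    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    def test_matches_exact_rational_oracle(self, m1, u1, m2, u2):
        if m1 + u1 + m2 + u2 == 0:
            return
        assert fisher_two_sided(m1, u1, m2, u2) == pytest.approx(
            oracle_fisher(m1, u1, m2, u2), rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 300), st.integers(0, 300), st.integers(0, 300), st.integers(0, 300))
    def test_large_tables_match_scipy(self, m1, u1, m2, u2):
        """Cross-check the log-gamma path against an independent
        implementation (scipy uses a 1e-7 tie slack)."""
        if m1 + u1 + m2 + u2 == 0:
            return
        ours = fisher_two_sided(m1, u1, m2, u2)
        theirs = sps.fisher_exact([[m1, u1], [m2, u2]])[1]
        assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-12)


class TestPerSite:
    def test_self_comparison_finds_nothing(self, small_calls):
        _, calls_a, _ = small_calls
        table, summary = per_site_tests(calls_a, calls_a)
        assert summary["n_differential"] == 0
        assert (table["p_value"] == 1.0).all()

    def test_site_covered_in_one_sample_excluded(self):
        a = make_calls([1, 2], [5, 5], [0, 0], methylated=True)
        b = make_calls([1, 2], [5, 0], [0, 0], methylated=[True, False])
        table, summary = per_site_tests(a, b)
        assert summary["n_common"] == 1
        assert list(table["pos"]) == [1]

    def test_planted_flips_detected(self):
        """100 sites flipped between high and low methylation at depth
        ~30 are flagged at p < 0.01 in at least 90% of cases."""
        rng = np.random.default_rng(12)
        n = 100
        d1, d2 = rng.poisson(30, n) + 1, rng.poisson(30, n) + 1
        m1 = rng.binomial(d1, 0.9)
        m2 = rng.binomial(d2, 0.05)
        a = make_calls(np.arange(1, n + 1), m1, d1 - m1, methylated=True)
        b = make_calls(np.arange(1, n + 1), m2, d2 - m2, methylated=False)
        _, summary = per_site_tests(a, b)
        assert summary["n_differential"] >= 0.9 * n

    def test_empty_intersection_rejected(self):
        a = make_calls([1], 5, 0)
        b = make_calls([9], 5, 0)
        with pytest.raises(ValueError):
            per_site_tests(a, b)


class TestDmrScan:
    def test_window_start_arithmetic(self):
        """Length 400, window 200, step 50: starts 1..201 only."""
        a = make_calls(np.arange(1, 401, 3), 10, 0, methylated=True)
        b = make_calls(np.arange(1, 401, 3), 0, 10, methylated=False)
        dmrs = dmr_scan(a, b, {"chr1": 400})
        assert dmrs.attrs["n_windows"] == 5
        assert set(dmrs["start"]) <= {1, 51, 101, 151, 201}

    def test_chromosome_shorter_than_window(self):
        a = make_calls([10], 10, 0, methylated=True)
        dmrs = dmr_scan(a, a, {"chr1": 150})
        assert dmrs.attrs["n_windows"] == 0
        assert len(dmrs) == 0

    def test_identical_windows_not_significant(self, small_calls, small_dataset):
        _, calls_a, _ = small_calls
        dmrs = dmr_scan(calls_a, calls_a,
                        {c: small_dataset.genome.lengths[c]
                         for c in small_dataset.nuclear_chroms})
        assert len(dmrs) == 0

    def test_candidate_rule_is_strict_in_either_sample(self):
        # 5 methylated reads: not a candidate; 6: candidate via sample A
        for m, expect in ((5, 0), (6, 1)):
            a = make_calls([100], m, 0, methylated=True)
            b = make_calls([100], 0, 30, methylated=False)
            p = scan_window_pvalues(a, b, {"chr1": 400})
            assert len(p) == expect * len(p) if expect else len(p) == 0

    def test_record_order_invariance(self, small_calls, small_dataset):
        _, calls_a, calls_b = small_calls
        lengths = {c: small_dataset.genome.lengths[c]
                   for c in small_dataset.nuclear_chroms}
        base = dmr_scan(calls_a, calls_b, lengths)
        shuffled = dmr_scan(calls_a.sample(frac=1, random_state=0),
                            calls_b.sample(frac=1, random_state=1), lengths)
        pd.testing.assert_frame_equal(base, shuffled)

    def test_sample_swap_inverts_direction(self, small_calls, small_dataset):
        _, calls_a, calls_b = small_calls
        lengths = {c: small_dataset.genome.lengths[c]
                   for c in small_dataset.nuclear_chroms}
        fwd = dmr_scan(calls_a, calls_b, lengths)
        rev = dmr_scan(calls_b, calls_a, lengths)
        assert np.allclose(fwd["p_value"], rev["p_value"], rtol=1e-6)
        flip = {"hyper_a": "hyper_b", "hyper_b": "hyper_a", ".": "."}
        assert list(rev["direction"]) == [flip[d] for d in fwd["direction"]]

    def test_planted_dmrs_recovered(self, small_calls, small_dataset):
        _, calls_a, calls_b = small_calls
        dmrs = dmr_scan(calls_a, calls_b,
                        {c: small_dataset.genome.lengths[c]
                         for c in small_dataset.nuclear_chroms})
        for d in small_dataset.truth.dmrs.itertuples():
            hit = dmrs.loc[(dmrs["chrom"] == d.chrom) & (dmrs["start"] <= d.end)
                           & (dmrs["end"] >= d.start)]
            assert len(hit) > 0, f"planted DMR {d.chrom}:{d.start}-{d.end} missed"


class TestGeneDifferential:
    def _gene(self, gid="g1", start=1, end=200):
        return FeatureRecord(gid, "chr1", start, end, "+", "gene")

    def test_identical_gene_not_flagged(self):
        calls = make_calls(np.arange(1, 101), 5, 5, methylated=True)
        table = gene_differential(calls, calls, [self._gene()], "CG")
        assert not table["differential"].any()

    def test_planted_hypermethylated_gene_flagged(self):
        rng = np.random.default_rng(3)
        pos = np.arange(1, 151)
        d = rng.poisson(30, len(pos)) + 1
        m_hi = rng.binomial(d, 0.8)
        m_lo = rng.binomial(d, 0.1)
        a = make_calls(pos, m_hi, d - m_hi, methylated=True)
        b = make_calls(pos, m_lo, d - m_lo, methylated=True)
        table = gene_differential(a, b, [self._gene()], "CG")
        assert table["differential"].all()
        assert table.iloc[0]["p_value"] < 1e-10

    def test_exclusion_accounting(self, small_calls, small_dataset):
        _, calls_a, calls_b = small_calls
        genes = [f for f in small_dataset.features if f.feature_type == "gene"]
        table = gene_differential(calls_a, calls_b, small_dataset.features, "CG")
        assert table.attrs["n_tested"] + table.attrs["n_excluded"] == len(genes)

    def test_zero_depth_gene_excluded(self):
        calls = make_calls([300], 5, 5, methylated=True)  # outside the gene
        table = gene_differential(calls, calls, [self._gene()], "CG")
        assert table.attrs["n_excluded"] == 1
        assert len(table) == 0
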