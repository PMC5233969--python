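"""Methylation-expression association, compartment effect, paralog fold
changes and DEG silencing reports."""

import numpy as np
import pandas as pd
import pytest

import epimung as em
from epimung.integrate import (
    compartment_effect,
    flag_silencing_cases,
    gene_summaries,
    methylation_expression_association,
    paralog_fold_changes,
)
from epimung.io_formats import FeatureRecord
from epimung.simulate import SimulationConfig, generate_dataset


def _summaries(levels, expression, exon_meth=None, intron_meth=None):
    n = len(levels)
    levels = np.asarray(levels, dtype=float)
    df = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)],
        "level_CG": levels, "level_CHG": levels, "level_CHH": levels,
        "level_body": levels,
        "exon_meth": exon_meth if exon_meth is not None else np.zeros(n, int),
        "exon_total": 100, "exon_level": levels,
        "intron_meth": intron_meth if intron_meth is not None else np.zeros(n, int),
        "intron_total": 100, "intron_level": levels,
        "expression": np.asarray(expression, dtype=float),
    })
    return df


class TestAssociation:
    def test_perfect_monotone_decreasing(self):
        lv = np.linspace(0, 1, 50)
        res = methylation_expression_association(_summaries(lv, 100 - 90 * lv), "CG")
        assert res["rho"] == pytest.approx(-1.0)

    def test_permuted_expression_is_null(self):
        rng = np.random.default_rng(0)
        lv = rng.random(500)
        res = methylation_expression_association(_summaries(lv, rng.permutation(lv)), "CG")
        assert abs(res["rho"]) < 0.1

    def test_insufficient_genes_rejected(self):
        with pytest.raises(ValueError):
            methylation_expression_association(_summaries([0.1] * 5, [1] * 5), "CG")

    def test_binned_medians_decrease_with_level(self):
        lv = np.linspace(0.01, 0.99, 200)
        res = methylation_expression_association(_summaries(lv, 10 - 9 * lv), "CG")
        med = res["binned"]["median"].to_numpy()
        assert (np.diff(med) < 0).all()

    def test_planted_negative_coupling_recovered(self, small_dataset, small_calls):
        _, calls_a, _ = small_calls
        summ = gene_summaries(calls_a, small_dataset.features,
                              small_dataset.expression, "sample_a")
        res = methylation_expression_association(summ, "CG")
        assert res["rho"] < 0


class TestCompartment:
    def test_membership_rules(self):
        df = _summaries([0.5, 0.5, 0.5], [1, 1, 1],
                        exon_meth=[10, 0, 10], intron_meth=[0, 10, 10])
        res = compartment_effect(df, min_genes=1)
        assert res["n_exon_only"] == 1   # methylated exons, clean introns
        assert res["n_intron_only"] == 1
        # the doubly methylated gene is in neither set

    def test_small_sets_reported_not_raised(self):
        df = _summaries([0.5], [1.0], exon_meth=[10])
        res = compartment_effect(df)
        assert res["exon_evaluable"] is False
        assert res["rho_difference"] is None

    def test_planted_exon_effect_stronger(self):
        """When only exon methylation suppresses expression, the
        exon-only set shows the stronger (negative) association."""
        cfg = SimulationConfig(
            seed=13, n_chroms=1, chrom_length=300_000, chloroplast_length=20_000,
            n_genes=80, gene_length_min=800, gene_length_max=2000,
            n_tes=0, n_planted_dmrs=0, n_snps=0, n_silenced=0,
            compartment_independent=True, couples_to="exon",
            propensity_low=0.0, pi_cg=0.5, pi_chg=0.3, pi_chh=0.0,
        )
        ds = generate_dataset(cfg)
        est = em.estimate_nonconversion(ds.methylomes.control_a)
        calls = em.call_sites(ds.methylomes.sample_a, est.p_err)
        summ = gene_summaries(calls, ds.features, ds.expression, "sample_a")
        res = compartment_effect(summ)
        assert res["exon_evaluable"] and res["intron_evaluable"]
        assert res["rho_exon"] < 0
        assert abs(res["rho_exon"]) > abs(res["rho_intron"])


class TestParalogs:
    def test_fold_change_arithmetic(self):
        df = _summaries([0.8, 0.2], [4.0, 1.0])
        pairs = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"]})
        table, _ = paralog_fold_changes(pairs, df, "CG", pseudocount=0.01)
        assert table.iloc[0]["meth_fold_change"] == pytest.approx(
            np.log2(0.81 / 0.21), rel=1e-12)

    def test_identical_paralogs_zero_fold_change(self):
        df = _summaries([0.4, 0.4], [2.0, 2.0])
        pairs = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"]})
        table, _ = paralog_fold_changes(pairs, df, "CG")
        assert table.iloc[0]["meth_fold_change"] == 0.0
        assert table.iloc[0]["expr_fold_change"] == 0.0

    def test_pair_swap_antisymmetry(self, small_dataset, small_calls):
        _, calls_a, _ = small_calls
        summ = gene_summaries(calls_a, small_dataset.features,
                              small_dataset.expression, "sample_a")
        pairs = small_dataset.paralog_pairs
        swapped = pairs.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        fwd, c_fwd = paralog_fold_changes(pairs, summ, "CG")
        rev, c_rev = paralog_fold_changes(swapped, summ, "CG")
        assert np.allclose(fwd["meth_fold_change"], -rev["meth_fold_change"])
        assert np.allclose(fwd["expr_fold_change"], -rev["expr_fold_change"])
        assert c_fwd["rho"] == pytest.approx(c_rev["rho"])

    def test_missing_gene_skipped_and_counted(self):
        df = _summaries([0.5, 0.5], [1.0, 1.0])
        pairs = pd.DataFrame({"gene_a": ["g0", "g0"], "gene_b": ["g1", "missing"]})
        _, corr = paralog_fold_changes(pairs, df, "CG")
        assert corr["n_pairs"] == 1
        assert corr["n_skipped"] == 1

    def test_zero_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            paralog_fold_changes(pd.DataFrame(columns=["gene_a", "gene_b"]),
                                 _summaries([0.1], [1.0]), "CG", pseudocount=0.0)


class TestSilencingCases:
    def _features(self):
        return [FeatureRecord("g0", "chr1", 1000, 2000, "+", "gene")]

    def _summaries_pair(self, exon_a, exon_b, expr_a, expr_b):
        a = _summaries([0.5], [expr_a])
        b = _summaries([0.5], [expr_b])
        a["exon_level"] = [exon_a]
        b["exon_level"] = [exon_b]
        return a, b

    def test_concordant_silencing_flagged(self):
        a, b = self._summaries_pair(0.05, 0.9, 10.0, 0.01)
        degs = pd.DataFrame({"gene_id": ["g0"]})
        dmrs = pd.DataFrame(columns=["chrom", "start", "end", "direction"])
        report = flag_silencing_cases(a, b, degs, dmrs, self._features())
        row = report.iloc[0]
        assert row.lower_expressed == "b"
        assert row.silencing_concordant

    def test_no_methylation_difference_unflagged(self):
        a, b = self._summaries_pair(0.05, 0.05, 10.0, 0.01)
        degs = pd.DataFrame({"gene_id": ["g0"]})
        dmrs = pd.DataFrame(columns=["chrom", "start", "end", "direction"])
        report = flag_silencing_cases(a, b, degs, dmrs, self._features())
        assert not report.iloc[0].silencing_concordant

    def test_downstream_dmr_in_lower_sample_flags(self):
        a, b = self._summaries_pair(0.05, 0.05, 0.01, 10.0)  # lower in a
        degs = pd.DataFrame({"gene_id": ["g0"]})
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [2100], "end": [2300],
                             "direction": ["hyper_a"]})
        report = flag_silencing_cases(a, b, degs, dmrs, self._features())
        row = report.iloc[0]
        assert row.downstream_dmr and row.downstream_dmr_hyper_in_lower
        assert row.silencing_concordant

    def test_empty_deg_list(self):
        a, b = self._summaries_pair(0.1, 0.1, 1.0, 1.0)
        report = flag_silencing_cases(a, b, pd.DataFrame(columns=["gene_id"]),
                                      pd.DataFrame(columns=["chrom", "start", "end",
                                                            "direction"]),
                                      self._features())
        assert len(report) == 0

    def test_planted_silenced_gene_flagged_end_to_end(self, small_dataset, small_calls):
        _, calls_a, calls_b = small_calls
        feats = small_dataset.features
        expr = small_dataset.expression
        summ_a = gene_summaries(calls_a, feats, expr, "sample_a")
        summ_b = gene_summaries(calls_b, feats, expr, "sample_b")
        degs = small_dataset.truth.genes.loc[small_dataset.truth.genes["silenced"],
                                             ["gene_id"]]
        dmrs = pd.DataFrame(columns=["chrom", "start", "end", "direction"])
        report = flag_silencing_cases(summ_a, summ_b, degs, dmrs, feats)
        assert len(report) == len(degs)
        assert report["silencing_concordant"].all()
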