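"""Generator contracts: determinism, boundaries, and agreement between
emitted data and the generative model's closed-form expectations."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epimung.genome_context import cytosine_table
from epimung.simulate import (
    CHLOROPLAST,
    ConfigurationError,
    SimulationConfig,
    generate_dataset,
    generate_genome,
    generate_methylomes,
    write_dataset,
)


def tiny_config(**overrides):
    base = dict(seed=3, n_chroms=1, chrom_length=30_000, chloroplast_length=10_000,
                n_genes=8, gene_length_min=500, gene_length_max=1200,
                n_tes=2, te_length_min=200, te_length_max=400,
                n_planted_dmrs=2, n_snps=40, n_silenced=1)
    base.update(overrides)
    return SimulationConfig(**base)


def _hash_dir(path: Path) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(path.rglob("*")) if p.is_file()}


class TestDeterminism:
    def test_identical_seed_byte_identical_outputs(self, tmp_path):
        for sub in ("a", "b"):
            ds = generate_dataset(tiny_config())
            write_dataset(ds, tmp_path / sub, include_truth_sites=True)
        assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        h = []
        for seed in (3, 4):
            ds = generate_dataset(tiny_config(seed=seed))
            write_dataset(ds, tmp_path / str(seed))
            h.append(_hash_dir(tmp_path / str(seed))["genome.fa"])
        assert h[0] != h[1]


class TestGenomeGeneration:
    def test_gc_fraction_one_gives_gc_only_genome(self):
        genome, _, _ = generate_genome(tiny_config(gc_fraction=1.0, n_snps=0))
        for chrom in genome.names:
            assert set(genome[chrom]) <= {"G", "C"}

    def test_no_snps_requested(self):
        _, _, snps = generate_genome(tiny_config(n_snps=0))
        assert snps == []

    def test_snp_refs_match_genome(self):
        genome, _, snps = generate_genome(tiny_config())
        assert all(genome[s.chrom][s.pos - 1] == s.ref_base for s in snps)
        # SNPs avoid the terminal 2 bases
        assert all(s.pos <= len(genome[s.chrom]) - 2 for s in snps)

    def test_genes_non_overlapping_with_exons_inside(self):
        _, features, _ = generate_genome(tiny_config())
        genes = sorted((f for f in features if f.feature_type == "gene"),
                       key=lambda f: (f.chrom, f.start))
        for a, b in zip(genes, genes[1:]):
            assert a.chrom != b.chrom or a.end < b.start
        by_id = {g.id: g for g in genes}
        for f in features:
            if f.feature_type == "exon":
                g = by_id[f.parent]
                assert g.start <= f.start <= f.end <= g.end

    def test_overfull_genome_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_genome(tiny_config(n_genes=100, gene_length_min=1000,
                                        gene_length_max=1000))


class TestMethylomes:
    def test_zero_depth_boundary(self):
        ds = generate_dataset(tiny_config(mean_depth=0.0))
        for frame in (ds.methylomes.sample_a, ds.methylomes.sample_b):
            assert (frame["n_meth"] + frame["n_unmeth"] == 0).all()

    def test_emitted_sites_match_context_enumeration(self):
        """Sample A's site set equals re-enumeration of the reference;
        sample B's equals re-enumeration of the SNP-substituted genome."""
        ds = generate_dataset(tiny_config())
        for frame, genome in ((ds.methylomes.sample_a, ds.genome),
                              (ds.methylomes.sample_b, ds.alt_genome)):
            expected = cytosine_table(genome, ds.nuclear_chroms)
            got = frame[["chrom", "pos", "strand", "context", "trinucleotide"]]
            pd.testing.assert_frame_equal(
                got.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True),
                expected.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True))

    def test_all_pi_zero_leaves_only_nonconversion(self):
        """With no true methylation the genome-wide methylated-read
        fraction equals p_err within 3 binomial SDs."""
        cfg = tiny_config(pi_cg=0.0, pi_chg=0.0, pi_chh=0.0,
                          propensity_low=0.0, n_silenced=0, n_planted_dmrs=0)
        ds = generate_dataset(cfg)
        frame = ds.methylomes.sample_a
        n = int((frame["n_meth"] + frame["n_unmeth"]).sum())
        frac = frame["n_meth"].sum() / n
        se = np.sqrt(cfg.p_err * (1 - cfg.p_err) / n)
        assert abs(frac - cfg.p_err) < 3 * se

    def test_unmethylated_truth_reads_converge_to_p_err(self):
        """Law of large numbers over >=1e5 truly unmethylated sites."""
        ds = generate_dataset(tiny_config(chrom_length=120_000, n_snps=0,
                                          n_planted_dmrs=0, n_silenced=0))
        truth = ds.truth.sites
        unmeth = truth.loc[(~truth["state_a"]) & (truth["context_ref"] != "none"),
                           ["chrom", "pos", "strand"]]
        frame = ds.methylomes.sample_a.merge(unmeth, on=["chrom", "pos", "strand"])
        n = int((frame["n_meth"] + frame["n_unmeth"]).sum())
        assert n > 1e5
        frac = frame["n_meth"].sum() / n
        p = ds.config.p_err
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_chloroplast_truth_unmethylated(self):
        ds = generate_dataset(tiny_config())
        ctl = ds.methylomes.control_a
        assert (ctl["chrom"] == CHLOROPLAST).all()
        n = int((ctl["n_meth"] + ctl["n_unmeth"]).sum())
        assert ctl["n_meth"].sum() / n < 0.01

    def test_planted_dmrs_inside_chromosomes_and_flagged(self):
        ds = generate_dataset(tiny_config())
        assert len(ds.truth.dmrs) == ds.config.n_planted_dmrs
        for d in ds.truth.dmrs.itertuples():
            assert 1 <= d.start < d.end <= ds.genome.lengths[d.chrom]
            assert d.end - d.start + 1 == ds.config.dmr_width
        in_dmr = ds.truth.sites.loc[ds.truth.sites["in_dmr"]]
        assert len(in_dmr) > 0
        # levels differ between samples inside DMRs
        diff = (in_dmr["level_b"] - in_dmr["level_a"]).abs()
        assert diff.median() > 0.4

    def test_truth_covers_every_emitted_cytosine(self):
        ds = generate_dataset(tiny_config())
        key = ["chrom", "pos", "strand"]
        truth_keys = set(map(tuple, ds.truth.sites[key].itertuples(index=False)))
        for frame in (ds.methylomes.sample_a, ds.methylomes.sample_b):
            assert set(map(tuple, frame[key].itertuples(index=False))) <= truth_keys


class TestExpression:
    def test_schema_three_replicates_two_samples(self):
        ds = generate_dataset(tiny_config())
        expr = ds.expression
        assert (expr["abundance"] >= 0).all()
        counts = expr.groupby(["gene_id", "sample"])["replicate"].count()
        assert (counts == ds.config.n_replicates).all()
        assert set(expr["sample"]) == {"sample_a", "sample_b"}

    @staticmethod
    def _many_gene_config(**overrides):
        return tiny_config(chrom_length=400_000, chloroplast_length=5_000,
                           n_genes=500, gene_length_min=200, gene_length_max=500,
                           n_tes=0, n_planted_dmrs=0, n_snps=0, n_silenced=0,
                           **overrides)

    def test_zero_slope_gives_null_correlation(self):
        """beta = 0: |rho| between true level and expression < 0.1 at
        n = 500 genes."""
        ds = generate_dataset(self._many_gene_config(expr_beta=0.0))
        g = ds.truth.genes
        rho, _ = stats.spearmanr(g["true_level_a"], g["mean_expression_a"])
        assert abs(rho) < 0.1

    def test_strong_coupling_gives_strong_anticorrelation(self):
        """beta = 5 with small noise: rho < -0.8."""
        ds = generate_dataset(self._many_gene_config(expr_beta=5.0, expr_sigma=0.1))
        g = ds.truth.genes
        rho, _ = stats.spearmanr(g["true_level_a"], g["mean_expression_a"])
        assert rho < -0.8

    def test_silenced_genes_near_zero_in_sample_b(self):
        ds = generate_dataset(tiny_config())
        sil = ds.truth.genes.loc[ds.truth.genes["silenced"]]
        assert len(sil) == 1
        assert (sil["mean_expression_b"] < 0.05).all()
        assert (sil["mean_expression_a"] > 0.05).all()
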