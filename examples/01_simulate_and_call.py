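"""Simulate a two-cultivar bisulfite dataset and call methylation.

Generates a small synthetic genome with known per-site methylation
truth, estimates the bisulfite non-conversion rate from the
unmethylated chloroplast control, and calls per-site methylation with
the one-sided binomial test + BH correction.
"""

import epimung as em
from epimung.simulate import SimulationConfig, generate_dataset

cfg = SimulationConfig(seed=1, n_chroms=1, chrom_length=120_000,
                       chloroplast_length=40_000, n_genes=40,
                       gene_length_min=800, gene_length_max=2000,
                       n_tes=8, n_planted_dmrs=10, n_snps=400, n_silenced=1)
ds = generate_dataset(cfg)
print(f"genome: {ds.genome.lengths}")
print(f"sample A cytosines: {len(ds.methylomes.sample_a):,}")

est = em.estimate_nonconversion(ds.methylomes.control_a)
print(f"\nnon-conversion rate: {est.p_err:.6f} "
      f"({est.n_meth_control:,}/{est.n_total_control:,} chloroplast reads)")
print("  -> the fraction of reads at truly unmethylated cytosines that "
      "still read as methylated; the binomial null rate.")

calls = em.call_sites(ds.methylomes.sample_a, est.p_err, q_threshold=0.01)
covered = calls[(calls.n_meth + calls.n_unmeth) > 0]
print("\nfraction of covered sites called methylated (planted: "
      f"CG {cfg.pi_cg}, CHG {cfg.pi_chg}, CHH {cfg.pi_chh}):")
for ctx, frac in covered.groupby("context")["methylated"].mean().items():
    print(f"  {ctx:4s} {frac:.3f}")

truth = ds.truth.sites
meth_cg = truth[(truth.context_ref == "CG") & truth.state_a]
joined = covered.merge(meth_cg[["chrom", "pos", "strand"]], on=["chrom", "pos", "strand"])
print(f"\nsensitivity for truly methylated CG sites: {joined.methylated.mean():.3f}")
print("  -> fraction of planted methylated CGs recovered at q < 0.01.")
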