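"""SNP-induced context transitions (obligate epialleles).

Substitutes the inter-cultivar SNPs into the reference, classifies
every cytosine whose CG/CHG/CHH context differs between the two
genomes (including cytosine gain/loss), and cross-tabulates the
called methylation states of both samples against the transition
classes.
"""

import epimung as em
from epimung.epialleles import classify_transitions, crosstab_transitions
from epimung.simulate import SimulationConfig, generate_dataset

cfg = SimulationConfig(seed=1, n_chroms=1, chrom_length=200_000,
                       chloroplast_length=30_000, n_genes=50,
                       gene_length_min=800, gene_length_max=2500,
                       n_tes=5, n_planted_dmrs=0, n_snps=1500, n_silenced=0)
ds = generate_dataset(cfg)
est = em.estimate_nonconversion(ds.methylomes.control_a)
calls_a = em.call_sites(ds.methylomes.sample_a, est.p_err)
calls_b = em.call_sites(ds.methylomes.sample_b, est.p_err)

ref = ds.genome.subset(ds.nuclear_chroms)
alt = ds.alt_genome.subset(ds.nuclear_chroms)
transitions, totals = classify_transitions(ref, ds.snps, alt)
print(f"{totals.attrs['n_snps_changing_context']} of {len(ds.snps)} SNPs "
      f"change a cytosine context, affecting {len(transitions)} cytosines")
print("\nsites per directed transition class (ref > alt; 'none' = "
      "cytosine gained/lost):")
print(totals.to_string(index=False))

table = crosstab_transitions(transitions, calls_a, calls_b)
print("\nmethylation-state change by transition class "
      "(M/U in sample A > sample B):")
print(table.to_string())
print("\n  -> transitions into a higher-frequency context (e.g. CHH>CG) "
      "are enriched for U>M, and gain/loss classes are uncovered on the "
      "side lacking the cytosine: these are obligate epiallele candidates.")
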