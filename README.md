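# epimung

Whole-genome bisulfite (BSseq/MethylC-seq) methylome analysis for
two-accession comparisons, written around the mungbean (*Vigna
radiata*) cultivar setting: from per-cytosine bisulfite count reports
and a genome sequence to methylation calls, weighted methylation
levels and metagene profiles, differentially methylated
sites/regions/genes, SNP-induced cytosine-context transitions
(obligate epialleles), and methylation–expression integration.

It is a library first (import `epimung`), with an `examples/`
directory of narrative scripts and a thin `epimung` CLI for
shell-driven pipelines. A first-class synthetic-data generator
produces two-cultivar datasets with known per-site ground truth, so
every stage is testable without sequencing data.

## The statistics at the core

**Contexts.** Plant cytosine methylation is tracked in the CG, CHG and
CHH contexts (H ∈ {A,T,C}), read 5′→3′ on the cytosine's own strand.
Minus-strand cytosines are reported at the plus-strand coordinate of
the G (the Bismark convention); coordinates are 1-based inclusive
everywhere.

**Calling.** Bisulfite conversion is imperfect; the non-conversion
rate `p_err` is estimated from the (unmethylated) chloroplast genome
as pooled `Σm / Σ(m+u)` over its cytosines. Each covered nuclear site
with m methylated of n total reads is tested one-sided against
`X ~ Binomial(n, p_err)` with exact `p = P(X ≥ m)`; p-values are
converted to q-values (Benjamini–Hochberg by default) across all
covered sites of a sample, and a site is methylated iff `q < 0.01`.
Read counts are then *corrected*: significant sites keep their counts,
non-significant sites have all reads regarded as unmethylated.

**Weighted levels.** The methylation level of a region is the
depth-weighted ratio `W = Σm / Σ(m+u)` over the corrected counts of
one context's cytosines in the region; a region with no covered sites
has an undefined (not zero) level.

**DMRs.** 200 bp windows slide along each chromosome in 50 bp steps
(150 bp overlap). Windows with more than 5 pooled corrected methylated
reads in either sample are candidates; a candidate is a DMR when the
two-sided Fisher's exact test on the pooled 2×2 count table gives
`p < 0.01`.

**Obligate epialleles.** A SNP within two bases of a cytosine can
change its context (CG↔CHG, CHG↔CHH, CG↔CHH) or create/destroy the
cytosine itself, making any methylation difference between accessions
fully dependent on the genetic variant. Contexts are compared between
the reference and the fully SNP-substituted genome, and methylation
states of both samples are cross-tabulated per transition class.

**Integration.** Gene-body methylation is related to expression by
Spearman rank correlation; paralog pairs are compared via
pseudocount-stabilized log2 fold changes of methylation and
expression; and the exon-vs-intron compartment effect is measured in
genes methylated in only one compartment.

## Worked example

```sh
python examples/01_simulate_and_call.py
```

```
genome: {'chr1': 120000, 'chloroplast': 40000}
sample A cytosines: 41,897

non-conversion rate: 0.001114 (474/425,512 chloroplast reads)
  -> the fraction of reads at truly unmethylated cytosines that still
     read as methylated; the binomial null rate.

fraction of covered sites called methylated (planted: CG 0.589, CHG 0.515, CHH 0.179):
  CG   0.594
  CHG  0.518
  CHH  0.179

sensitivity for truly methylated CG sites: 1.000
  -> fraction of planted methylated CGs recovered at q < 0.01.
```

The generator planted context-specific methylation probabilities of
0.589 / 0.515 / 0.179 and a non-conversion rate of 0.001114; the
pipeline recovers all four from the simulated read counts alone. The
remaining examples cover profiles and landscapes (`02`), differential
methylation (`03`), SNP-induced context transitions (`04`) and
expression integration (`05`).

The same steps from a shell:

```sh
epimung simulate --out-dir data --seed 1
epimung call --cx data/sampleA.CX.txt --control-cx data/controlA.CX.txt -o calls_A.tsv
epimung dmr --calls-a calls_A.tsv --calls-b calls_B.tsv --genome data/genome.fa -o dmrs.bed
epimung snp-context --genome data/genome.fa --vcf data/snps.vcf -o transitions.tsv
```

## Layout

- `src/epimung/io_formats.py` — FASTA / GFF3 / VCF / CX-report /
  expression-table readers and writers, BED output
- `src/epimung/genome_context.py` — strand-aware cytosine enumeration,
  context classification, flanking composition
- `src/epimung/simulate.py` — the synthetic two-cultivar generator
- `src/epimung/calling.py` — non-conversion estimation, binomial
  calling, read-count correction, site filter
- `src/epimung/levels.py` — weighted levels, metagene/TE profiles,
  window landscapes, genomic-category tallies
- `src/epimung/differential.py` — Fisher's exact test, per-site /
  windowed / per-gene differential methylation
- `src/epimung/epialleles.py` — SNP substitution and context-transition
  analysis
- `src/epimung/integrate.py` — methylation–expression association,
  paralogs, compartment effect, DEG case reports
- `src/epimung/cli.py` — the `epimung` command
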