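# Methods

## Scope and data model

The package analyses per-cytosine bisulfite read counts (the
7-column Bismark-style CX report: chrom, 1-based position, strand,
methylated count, unmethylated count, context, trinucleotide) against
a reference genome and a GFF3 annotation. All external coordinates are
1-based inclusive; minus-strand cytosines carry the plus-strand
coordinate of their G. A cytosine's context is decided from the two
bases 3′ of it on its own strand: second base G → CG; else third base
G → CHG; else CHH. At a sequence end the context is assigned iff
decidable from the available bases (a terminal CG is CG; a terminal
C followed by one non-G base is undefined), and any N at a needed
position makes it undefined; undefined sites are excluded. No
imputation is performed anywhere.

## Methylation calling

The bisulfite non-conversion rate `p_err` is the pooled methylated
read fraction over all cytosines of the unmethylated chloroplast
control, all contexts together. Covered nuclear sites are tested
one-sided: `p = P(X ≥ m)` for `X ~ Binomial(n, p_err)`, evaluated
through the regularized incomplete beta function (an exact closed form
of the tail sum, not a normal approximation). Q-values are computed
per sample across all covered sites of all contexts jointly —
Benjamini–Hochberg by default, a single-λ Storey estimate as an
option — and a site is methylated iff `q < q_threshold` (default
0.01, configurable; the threshold is a package choice). Corrected
counts keep the raw counts at significant sites and move every read to
unmethylated at non-significant sites, conserving per-site depth.
Zero-coverage rows are accepted, passed through with `p = q = 1`,
unmethylated status and corrected counts (0, 0), and never tested.
The high-confidence site filter (`filter_sites`) retains sites with
raw depth strictly greater than 10 supporting a raw level strictly
greater than 0.9 (both configurable, both strict); it is a standalone
operation, not applied implicitly by any downstream step.

## Weighted levels and profiles

A region's weighted level is `Σ c_meth / Σ (c_meth + c_unmeth)` over
corrected counts of one context's sites in the region, both strands
(a raw-count mode exists for diagnostics). Zero-denominator levels are
undefined (NaN), distinct from 0, and excluded from cross-feature
means: absence of data is not hypomethylation. Metagene profiles split
each feature body into 20 equal-width bins (remainder bases to the
final 3′ bin) and each 2000 bp flank into 20 bins — common metaplot
practice, configurable — reverse minus-strand features so bins read
5′→3′, and average per-feature bin levels over features with defined
levels (a pooled-counts mode is available); features shorter than the
bin count are skipped and counted. Window landscapes count methylated
sites per context in non-overlapping 50 kb windows, the last window
truncated at the chromosome end. Genomic-category tallies assign each
methylated site to exactly one of UTR > CDS (exon minus UTR) > intron
> 1 kb strand-aware upstream > intergenic, by that precedence.

## Differential methylation

Fisher's exact two-sided p-value sums, at fixed margins, the
probabilities of all tables no more likely than the observed one.
Tables with total ≤ 200 use exact integer arithmetic (ties exact);
larger tables use a log-gamma evaluation whose tie tolerance (1e-8
relative) is matched to the numerical accuracy of gammaln sums at
that size. Degenerate tables with a zero row or column margin have a
single admissible outcome and return p = 1; only the all-zero table
errors. Batched callers deduplicate identical tables before testing.

Per-site tests intersect the two samples on (chrom, pos, strand,
context) at raw depth ≥ 1 in both ("commonly called") and test the
corrected counts at p < 0.01, uncorrected for multiplicity by default
(a BH option exists). The DMR scan pools corrected counts of all three
contexts (per-context mode optional) in 200 bp windows stepped by
50 bp, starting at 1 and fully contained in the chromosome — fixed
width keeps the candidate threshold comparable — with a window a
candidate iff pooled methylated reads strictly exceed 5 in at least
one sample, and a DMR iff Fisher p < 0.01; direction compares window
weighted levels. Adjacent significant windows are reported
individually, not merged. Gene-level tests pool corrected counts over
the gene body per context; genes with zero pooled depth in either
sample are excluded and counted.

## SNP-induced context transitions

The alternate genome is the reference with every SNP substituted, so
clustered SNPs compose correctly. Positions within 2 bases of a SNP
are examined on both strands; a site yields a transition when its
decidable context differs between genomes, with cytosine gain/loss
(`none>CG`, `CG>none`, …) kept as separate classes rather than folded
into the six directed interchanges. Transitions are attributed per
affected cytosine (one SNP can affect up to four sites across
strands); the per-SNP tally is the count of distinct causal SNPs, and
both roll-ups are emitted since the directed per-site grain is what
the methylation cross-tab needs. The cross-tab looks up the called
status at each transition site in the reference-mapped and
alternate-mapped samples; sites uncovered in either land in a separate
column, so row sums always equal class totals. A whole-genome
re-enumeration diff (`brute_force_transitions`) provides an
independent oracle; the two agree exactly on SNV-only genome pairs.

## Expression integration

Gene expression per sample is the mean over replicates; all
associations are Spearman rank correlations (robust to the
heavy-tailed expression scale — the package reports rank, not linear,
association). The compartment analysis defines set E as genes with
zero corrected methylated reads in introns and more than zero in exons
(intronless genes with methylated exons qualify) and set I as the
converse; each set's compartment level is correlated with expression,
and sets under 10 genes are reported as not evaluable rather than
raising. Paralog fold changes are `log2((w_a+ε)/(w_b+ε))` with
pseudocount ε = 0.01 (bounded log-ratios at zero levels), exactly
antisymmetric under pair swap. DEG case reports take the DEG list as
input (DEG calling is out of scope), and flag a gene as
silencing-concordant when the lower-expressed sample has the higher
exon methylation or a downstream (default 2 kb, strand-aware) DMR
hypermethylated in it.

## The synthetic-data generator

The generator emulates the statistical structure of a two-accession
WGBS + RNAseq experiment at desk scale. Defaults (the package's
standard study conditions): two 500 kb chromosomes at 35% GC (a
plant-typical composition) plus a 150 kb chloroplast control; 200
non-overlapping genes of 1–4 kb with 1–4 exons, terminal UTRs and
synthesized introns, and 40 TEs; per-context methylated-site
probabilities π = 0.589 / 0.515 / 0.179 (CG/CHG/CHH) and
non-conversion rate 0.001114, the rates reported for the mungbean
leaf methylome; Beta(8, 2) methylation levels at methylated sites
(mean 0.8, producing the observed high-methylation peak) and level
`p_err` at unmethylated ones; Poisson(30) depth per site and sample;
50 planted 200 bp DMRs with level shift 0.8; 2000 SNPs uniform over
the nuclear genome avoiding the terminal 2 bases; 3
methylation-silenced genes; and expression with
`log(mean) = 3 − 5·w + N(0, 0.5)` per gene and sample (w the true
gene-body mean level), log-normal replicates (σ = 0.1, 3 replicates).

Three structural choices matter:

* **Per-gene propensities with an exact-π calibration.** I.i.d.
  per-site Bernoulli(π) states would concentrate every gene-body
  level near π·E[Beta] and erase the field's characteristic bimodal
  gene-body CG/CHG distribution. Instead each gene draws a CG and a
  CHG propensity from a balanced two-point mixture {0.95, 0.05} whose
  weight makes the genic marginal equal π, and the intergenic
  background probability is then calibrated so the genome-wide
  marginal equals π exactly whatever the realized draw. CHH states
  are i.i.d. everywhere, giving the narrow unimodal CHH spectrum.
  With `compartment_independent=True` propensities are drawn per
  (gene, compartment), decoupling exon and intron methylation for
  compartment-effect studies.
* **DMRs shift away from the nearer extreme.** Within a planted DMR,
  sample B's level is shifted by `dmr_delta` upward when the window's
  mean level is ≤ 0.5 and downward otherwise, clamped to [0, 1]; a
  blind one-sided shift would plant no signal on an already-saturated
  or already-empty window. The per-DMR direction is recorded in the
  truth table.
* **Sample B is generated against the SNP-substituted genome.** B
  shares A's true state and level except at context-changed cytosines
  (state redrawn i.i.d. from the new context's π; lost cytosines are
  absent from B's report), inside planted DMRs, and in the exons of
  silenced genes (forced high in B, low in A, with B's expression set
  near zero).

One `numpy.random.default_rng` stream seeded once drives every draw;
identical config and seed give byte-identical files.

What the generator does **not** emulate — and hence what passing
tests do not show about real data: read-level artifacts (mapping
bias, PCR duplicates, M-bias, strand coverage imbalance; depth is
site-independent Poisson), spatial autocorrelation of methylation
beyond gene-scale propensities (no heterochromatin blocks or
centromeric gradients), TE-body hypermethylation by default (TEs are
annotated but methylated like background so genome-wide context
proportions stay at π; an opt-in `te_propensity` plants the TE
metaplot pattern), overdispersion of counts beyond binomial, and any
sequence-driven methylation preference (flanking composition around
methylated sites is uniform by construction, so composition analyses
on synthetic data show the machinery, not biology).

## Problem sizes and numerical choices

The test suite and the acceptance script run the standard conditions
above (≈ 3.5 × 10⁵ cytosines per sample, ≈ 2 × 10⁴ DMR windows) plus
smaller dedicated runs: a 300 kb global-null pair for the DMR
false-positive rate, a 150 kb-chloroplast run (> 10⁶ control reads)
for non-conversion recovery, and a 150-gene exon-coupled run
(`propensity_low = 0`, `pi_chh = 0`) for the compartment effect,
where a zero low-propensity is what makes "genes lacking intron
methylation" a non-empty class. Exact-test oracles are exhaustive
where feasible (all binomial tails to n = 50 at 1e-12 relative; all
2×2 tables with row sums ≤ 30) and randomized-but-seeded elsewhere.
Stochastic recovery checks use 3-standard-error bands around
closed-form expectations of the generative model.

## Known limitations

Symmetric CG pairs are kept as separate strand records throughout
(matching the CX report) rather than merged; no beta-binomial
overdispersion model is offered; DMR windows are reported unmerged;
q-value choice and calling threshold are configuration, not inference;
and the per-site Fisher test at low depth has little power — the
"commonly called" intersection at depth ≥ 1 deliberately mirrors a
permissive upstream rather than enforcing a depth floor.
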