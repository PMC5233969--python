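"""Synthetic two-cultivar bisulfite datasets with known ground truth.

The generator emulates the statistical structure of a two-accession
whole-genome bisulfite experiment at desk scale: a random nuclear
genome with annotated genes and TEs plus an unmethylated chloroplast
control; per-cytosine read counts for two samples with context-specific
methylation frequencies, Beta-distributed methylation levels at
methylated sites, bisulfite non-conversion at unmethylated sites and
Poisson sequencing depth; planted differentially methylated regions;
SNPs that change cytosine contexts (sample B counts are generated from
the SNP-substituted genome); and per-gene expression negatively coupled
to true gene-body methylation, with a few genes planted as
methylation-silenced in sample B.

Per-site methylation states are Bernoulli draws, but for CG and CHG the
success probability inside a gene is a per-gene *propensity* drawn from
a two-point mixture {high, low} whose weight is chosen so the marginal
per-site probability equals the configured pi exactly. This produces
the bimodal gene-body weighted-level distribution seen in real plant
methylomes (a low peak near 0 and a gene-body-methylated peak near
E[Beta]) while leaving genome-wide context proportions at pi. CHH
states are i.i.d. everywhere, giving the narrow unimodal CHH gene-level
spectrum. Depth is site-independent Poisson: the pipeline consumes
counts, not reads, so no read-level simulation is attempted.

A single RNG stream, seeded once, drives every draw; identical config
and seed give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .epialleles import apply_snps
from .genome_context import cytosine_table
from .io_formats import (
    FeatureRecord,
    GenomeSequence,
    SNPVariant,
    synthesize_introns,
    write_cx_report,
    write_expression_table,
    write_fasta,
    write_gff_features,
    write_paralog_pairs,
    write_snp_vcf,
)

CHLOROPLAST = "chloroplast"


class ConfigurationError(ValueError):
    """The requested simulation is internally inconsistent or does not fit."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset.

    Defaults are the package's standard study conditions: a 2 x 500 kb
    nuclear genome at 35% GC with a 150 kb chloroplast control, mean
    depth 30, per-context methylated-site probabilities
    0.589 / 0.515 / 0.179 (CG / CHG / CHH), non-conversion rate
    0.001114, Beta(8, 2) levels at methylated sites, 50 planted 200 bp
    DMRs with level shift 0.8, and 2000 SNPs.
    """

    seed: int = 1
    # genome
    n_chroms: int = 2
    chrom_length: int = 500_000
    gc_fraction: float = 0.35
    chloroplast_length: int = 150_000
    # methylation truth
    pi_cg: float = 0.589
    pi_chg: float = 0.515
    pi_chh: float = 0.179
    beta_a: float = 8.0
    beta_b: float = 2.0
    p_err: float = 0.001114
    mean_depth: float = 30.0
    propensity_high: float = 0.95
    propensity_low: float = 0.05
    compartment_independent: bool = False
    te_propensity: float | None = None
    # annotation
    n_genes: int = 200
    gene_length_min: int = 1000
    gene_length_max: int = 4000
    flank_length: int = 2000
    n_tes: int = 40
    te_length_min: int = 500
    te_length_max: int = 2000
    # planted differences
    n_planted_dmrs: int = 50
    dmr_width: int = 200
    dmr_delta: float = 0.8
    n_snps: int = 2000
    n_silenced: int = 3
    # expression
    expr_intercept: float = 3.0
    expr_beta: float = 5.0
    expr_sigma: float = 0.5
    expr_rep_sigma: float = 0.1
    n_replicates: int = 3
    couples_to: str = "gene_body"  # or "exon"

    def validate(self) -> None:
        for name in ("pi_cg", "pi_chg", "pi_chh", "p_err", "gc_fraction",
                     "propensity_high", "propensity_low"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.gc_fraction):
            raise ConfigurationError("gc_fraction must be positive")
        if self.mean_depth < 0:
            raise ConfigurationError("mean_depth must be >= 0")
        if not (0.0 < self.dmr_delta <= 1.0):
            raise ConfigurationError("dmr_delta must be in (0, 1]")
        if self.propensity_low >= self.propensity_high:
            raise ConfigurationError("propensity_low must be < propensity_high")
        for pi in (self.pi_cg, self.pi_chg):
            if not (self.propensity_low <= pi <= self.propensity_high):
                raise ConfigurationError(
                    "pi_cg/pi_chg must lie within [propensity_low, propensity_high] "
                    "for the per-gene mixture to average to pi")
        if self.couples_to not in ("gene_body", "exon"):
            raise ConfigurationError("couples_to must be 'gene_body' or 'exon'")
        if self.n_silenced > self.n_genes:
            raise ConfigurationError("n_silenced exceeds n_genes")

    @property
    def pi(self) -> dict[str, float]:
        return {"CG": self.pi_cg, "CHG": self.pi_chg, "CHH": self.pi_chh}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Recovery targets for every pipeline stage.

    ``sites`` covers every emitted nuclear cytosine (both genomes) with
    true state and level per sample; ``dmrs`` the planted windows with
    direction; ``transitions`` the intended context change per affected
    site; ``genes`` per-gene structure, planted silencing and (after
    expression generation) true mean expression per sample.
    """

    sites: pd.DataFrame
    dmrs: pd.DataFrame
    transitions: pd.DataFrame
    genes: pd.DataFrame


@dataclass
class Methylomes:
    """CX-report frames for both samples plus chloroplast controls."""

    sample_a: pd.DataFrame
    sample_b: pd.DataFrame
    control_a: pd.DataFrame
    control_b: pd.DataFrame


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence          # nuclear chromosomes + chloroplast
    alt_genome: GenomeSequence      # SNP-substituted (sample B reference)
    features: list[FeatureRecord]
    snps: list[SNPVariant]
    methylomes: Methylomes
    truth: GroundTruth
    expression: pd.DataFrame
    paralog_pairs: pd.DataFrame

    @property
    def nuclear_chroms(self) -> list[str]:
        return [n for n in self.genome.names if n != CHLOROPLAST]


# ---------------------------------------------------------------------------
# genome + annotation + SNPs
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return bases.tobytes().decode("ascii")


def _place_intervals(rng: np.random.Generator, chrom_len: int,
                     lengths: list[int], what: str) -> list[tuple[int, int]]:
    """Non-overlapping placement: random gaps (>=1 bp) between items in
    random order along the chromosome. 1-based inclusive intervals."""
    n = len(lengths)
    if n == 0:
        return []
    free = chrom_len - sum(lengths)
    if free < n + 1:
        raise ConfigurationError(
            f"cannot place {n} {what} (total {sum(lengths)} bp) on a "
            f"{chrom_len} bp chromosome")
    gaps = rng.multinomial(free - (n + 1), np.full(n + 1, 1.0 / (n + 1))) + 1
    intervals = []
    cursor = 0
    for i, length in enumerate(lengths):
        cursor += gaps[i]
        intervals.append((cursor + 1, cursor + length))
        cursor += length
    return intervals


def _gene_structure(rng: np.random.Generator, gene: FeatureRecord) -> list[FeatureRecord]:
    """Exons and UTRs for one gene. 1-4 exons, alternating segments of
    at least 50 bp; UTRs are the terminal <=100 bp of the outer exons."""
    length = gene.length
    max_exons = max(1, min(4, length // 300))
    n_exons = int(rng.integers(1, max_exons + 1))
    n_seg = 2 * n_exons - 1
    extra = rng.multinomial(length - 50 * n_seg, np.full(n_seg, 1.0 / n_seg))
    seg_lengths = extra + 50
    feats: list[FeatureRecord] = []
    cursor = gene.start
    exon_no = 0
    for i, seg in enumerate(seg_lengths):
        start, end = cursor, cursor + int(seg) - 1
        cursor = end + 1
        if i % 2 == 0:
            exon_no += 1
            feats.append(FeatureRecord(f"{gene.id}.exon{exon_no}", gene.chrom,
                                       start, end, gene.strand, "exon", gene.id))
    exons = [f for f in feats if f.feature_type == "exon"]
    first, last = exons[0], exons[-1]  # genomic order
    utr5_len = min(100, first.length)
    utr3_len = min(100, last.length)
    if gene.strand == "+":
        feats.append(FeatureRecord(f"{gene.id}.utr5", gene.chrom, first.start,
                                   first.start + utr5_len - 1, "+", "five_prime_UTR", gene.id))
        feats.append(FeatureRecord(f"{gene.id}.utr3", gene.chrom, last.end - utr3_len + 1,
                                   last.end, "+", "three_prime_UTR", gene.id))
    else:
        feats.append(FeatureRecord(f"{gene.id}.utr5", gene.chrom, last.end - utr5_len + 1,
                                   last.end, "-", "five_prime_UTR", gene.id))
        feats.append(FeatureRecord(f"{gene.id}.utr3", gene.chrom, first.start,
                                   first.start + utr3_len - 1, "-", "three_prime_UTR", gene.id))
    return feats


def generate_genome(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeSequence, list[FeatureRecord], list[SNPVariant]]:
    """Random genome (i.i.d. bases at ``gc_fraction``), non-overlapping
    gene and TE annotation with synthesized introns, a separate
    chloroplast control sequence, and uniformly placed SNPs.

    SNPs avoid the last 2 bases of each chromosome so that plus-strand
    context windows at affected sites stay defined; the alternate base
    is uniform over the three non-reference bases.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    seqs = {f"chr{i + 1}": _random_sequence(rng, config.chrom_length, config.gc_fraction)
            for i in range(config.n_chroms)}
    seqs[CHLOROPLAST] = _random_sequence(rng, config.chloroplast_length, config.gc_fraction)
    genome = GenomeSequence(seqs)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]

    # deal genes/TEs round-robin across chromosomes, then place per chrom
    gene_lengths = rng.integers(config.gene_length_min, config.gene_length_max + 1,
                                size=config.n_genes)
    te_lengths = rng.integers(config.te_length_min, config.te_length_max + 1,
                              size=config.n_tes)
    features: list[FeatureRecord] = []
    gene_no = 0
    te_no = 0
    for ci, chrom in enumerate(chroms):
        g_lens = [int(x) for x in gene_lengths[ci::config.n_chroms]]
        t_lens = [int(x) for x in te_lengths[ci::config.n_chroms]]
        kinds = ["gene"] * len(g_lens) + ["TE"] * len(t_lens)
        lens = g_lens + t_lens
        order = rng.permutation(len(lens))
        intervals = _place_intervals(rng, config.chrom_length,
                                     [lens[i] for i in order], "features")
        for (start, end), oi in zip(intervals, order):
            if kinds[oi] == "gene":
                gene_no += 1
                strand = "+" if rng.random() < 0.5 else "-"
                gene = FeatureRecord(f"gene{gene_no:04d}", chrom, start, end, strand, "gene")
                features.append(gene)
                features.extend(_gene_structure(rng, gene))
            else:
                te_no += 1
                features.append(FeatureRecord(f"TE{te_no:04d}", chrom, start, end, "+", "TE"))
    features.extend(synthesize_introns(features))

    # SNPs: uniform distinct positions, avoiding the terminal 2 bases
    placeable = config.n_chroms * (config.chrom_length - 2)
    if config.n_snps > placeable:
        raise ConfigurationError(f"cannot place {config.n_snps} SNPs on {placeable} bases")
    flat = rng.choice(placeable, size=config.n_snps, replace=False)
    flat.sort()
    snps: list[SNPVariant] = []
    span = config.chrom_length - 2
    for f in flat:
        chrom = chroms[int(f) // span]
        pos = int(f) % span + 1
        ref = genome[chrom][pos - 1]
        others = [b for b in "ACGT" if b != ref]
        alt = others[int(rng.integers(0, 3))]
        snps.append(SNPVariant(chrom, pos, ref, alt))
    return genome, features, snps


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def _paint_indices(length: int, intervals: list[tuple[int, int]], values: list[int],
                   fill: int = -1) -> np.ndarray:
    arr = np.full(length, fill, dtype=np.int32)
    for (start, end), v in zip(intervals, values):
        arr[start - 1:end] = v
    return arr


def _mixture_weight(pi: float, high: float, low: float) -> float:
    return (pi - low) / (high - low)


def generate_methylomes(
    genome: GenomeSequence,
    features: list[FeatureRecord],
    snps: list[SNPVariant],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    silenced_genes: set[str] | None = None,
) -> tuple[Methylomes, GroundTruth]:
    """Per-cytosine counts for both samples plus the ground truth.

    Sample A is generated against the reference genome, sample B against
    the SNP-substituted genome. B shares A's true state and level except
    (i) at cytosines whose context differs between the genomes (state
    redrawn from the new context's pi; C-loss sites are absent from B),
    (ii) inside planted DMRs (level shifted by ``dmr_delta`` away from
    the nearer extreme, clamped to [0, 1]), and (iii) in exons of the
    planted silenced genes (forced to the high propensity in B, low in
    A). Chloroplast cytosines are unmethylated-truth (level ``p_err``)
    in both samples.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if silenced_genes is None:
        silenced_genes = set()
    chroms = [n for n in genome.names if n != CHLOROPLAST]

    alt_genome = apply_snps(genome, snps)
    ref_table = cytosine_table(genome, chroms)
    alt_table = cytosine_table(alt_genome, chroms)
    merged = ref_table.merge(alt_table, on=["chrom", "pos", "strand"], how="outer",
                             suffixes=("_ref", "_alt"), sort=False)
    order = {c: i for i, c in enumerate(chroms)}
    merged["_c"] = merged["chrom"].map(order)
    merged = merged.sort_values(["_c", "pos", "strand"], kind="stable").drop(columns="_c")
    merged = merged.reset_index(drop=True)
    for col in ("context_ref", "context_alt"):
        merged[col] = merged[col].fillna("none")
    n = len(merged)

    # --- gene / compartment / TE maps per position --------------------
    genes = [f for f in features if f.feature_type == "gene"]
    gene_ids = [g.id for g in genes]
    gene_index = {g.id: i for i, g in enumerate(genes)}
    gene_map = {c: np.full(genome.lengths[c], -1, dtype=np.int32) for c in chroms}
    exon_map = {c: np.zeros(genome.lengths[c], dtype=bool) for c in chroms}
    te_map = {c: np.zeros(genome.lengths[c], dtype=bool) for c in chroms}
    for f in features:
        if f.feature_type == "gene":
            gene_map[f.chrom][f.start - 1:f.end] = gene_index[f.id]
        elif f.feature_type == "exon":
            exon_map[f.chrom][f.start - 1:f.end] = True
        elif f.feature_type == "TE":
            te_map[f.chrom][f.start - 1:f.end] = True

    site_gene = np.full(n, -1, dtype=np.int32)
    site_exon = np.zeros(n, dtype=bool)
    site_te = np.zeros(n, dtype=bool)
    for chrom in chroms:
        mask = (merged["chrom"] == chrom).to_numpy()
        pos0 = merged.loc[mask, "pos"].to_numpy() - 1
        site_gene[mask] = gene_map[chrom][pos0]
        site_exon[mask] = exon_map[chrom][pos0]
        site_te[mask] = te_map[chrom][pos0]

    # --- per-site state probability for sample A (reference context) --
    ctx_ref = merged["context_ref"].to_numpy()
    ctx_alt = merged["context_alt"].to_numpy()
    pi_of = config.pi
    prob_a = np.zeros(n)
    for ctx, pi in pi_of.items():
        prob_a[ctx_ref == ctx] = pi

    # per-gene (or per gene x compartment) CG/CHG propensities
    high, low = config.propensity_high, config.propensity_low
    n_units = len(genes) * (2 if config.compartment_independent else 1)
    gene_prop = {}
    for ctx in ("CG", "CHG"):
        # balanced two-point mixture: exactly the weight's share of units
        # is high-propensity, so the genic marginal stays at pi without
        # the extra between-gene sampling variance of i.i.d. assignment
        w = _mixture_weight(pi_of[ctx], high, low)
        n_high = int(round(w * n_units))
        prop = np.full(n_units, low)
        prop[rng.permutation(n_units)[:n_high]] = high
        gene_prop[ctx] = prop
    for ctx in ("CG", "CHG"):
        in_gene = (site_gene >= 0) & (ctx_ref == ctx)
        unit = site_gene[in_gene]
        if config.compartment_independent:
            unit = unit * 2 + site_exon[in_gene].astype(np.int32)
        prob_a[in_gene] = gene_prop[ctx][unit]
    if config.te_propensity is not None:
        prob_a[site_te & (ctx_ref != "none")] = config.te_propensity

    silenced_idx = np.array([gene_index[g] for g in silenced_genes], dtype=np.int32)
    sil_exon = np.isin(site_gene, silenced_idx) & site_exon
    prob_a[sil_exon & (ctx_ref != "none")] = low

    # calibrate the intergenic background so the genome-wide marginal
    # state probability equals pi exactly per context, whatever the
    # realized genic propensity draw
    background = (site_gene < 0) & ~site_te & ~sil_exon
    for ctx, pi in pi_of.items():
        in_ctx = ctx_ref == ctx
        base = in_ctx & background
        n_base = int(base.sum())
        if n_base == 0:
            continue
        deficit = pi * int(in_ctx.sum()) - float(prob_a[in_ctx & ~base].sum())
        prob_a[base] = min(max(deficit / n_base, 0.0), 1.0)

    has_a = ctx_ref != "none"
    has_b = ctx_alt != "none"

    state_a = np.zeros(n, dtype=bool)
    state_a[has_a] = rng.random(int(has_a.sum())) < prob_a[has_a]
    level_a = np.full(n, np.nan)
    level_a[has_a] = np.where(state_a[has_a],
                              rng.beta(config.beta_a, config.beta_b, int(has_a.sum())),
                              config.p_err)

    # --- sample B truth ----------------------------------------------
    state_b = state_a.copy()
    level_b = level_a.copy()
    changed = has_b & (ctx_alt != ctx_ref)  # context changed or C gained
    prob_b = np.zeros(n)
    for ctx, pi in pi_of.items():
        prob_b[changed & (ctx_alt == ctx)] = pi
    state_b[changed] = rng.random(int(changed.sum())) < prob_b[changed]
    level_b[changed] = np.where(
        state_b[changed],
        rng.beta(config.beta_a, config.beta_b, int(changed.sum())),
        config.p_err)
    sil_b = sil_exon & has_b
    state_b[sil_b] = rng.random(int(sil_b.sum())) < high
    level_b[sil_b] = np.where(state_b[sil_b],
                              rng.beta(config.beta_a, config.beta_b, int(sil_b.sum())),
                              config.p_err)
    state_b[~has_b] = False
    level_b[~has_b] = np.nan

    # --- planted DMRs -------------------------------------------------
    dmr_rows = []
    in_dmr = np.zeros(n, dtype=bool)
    if config.n_planted_dmrs > 0:
        per_chrom = np.full(len(chroms), config.n_planted_dmrs // len(chroms))
        per_chrom[:config.n_planted_dmrs % len(chroms)] += 1
        pos_arr = merged["pos"].to_numpy()
        for chrom, k in zip(chroms, per_chrom):
            L = genome.lengths[chrom]
            intervals = _place_intervals(rng, L, [config.dmr_width] * int(k), "DMRs")
            cmask = (merged["chrom"] == chrom).to_numpy()
            for start, end in intervals:
                smask = cmask & (pos_arr >= start) & (pos_arr <= end) & has_b
                mean_a = np.nanmean(level_a[smask]) if smask.any() else 0.0
                sign = 1.0 if mean_a <= 0.5 else -1.0
                level_b[smask] = np.clip(level_b[smask] + sign * config.dmr_delta, 0.0, 1.0)
                in_dmr |= smask
                dmr_rows.append((chrom, start, end,
                                 "hyper_b" if sign > 0 else "hyper_a"))
    dmrs = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "direction"])

    # --- read counts --------------------------------------------------
    def draw_counts(mask: np.ndarray, level: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        depth = rng.poisson(config.mean_depth, int(mask.sum()))
        n_meth = rng.binomial(depth, level[mask])
        return n_meth, depth - n_meth

    m_a, u_a = draw_counts(has_a, level_a)
    sample_a = pd.DataFrame({
        "chrom": merged.loc[has_a, "chrom"].to_numpy(),
        "pos": merged.loc[has_a, "pos"].to_numpy(),
        "strand": merged.loc[has_a, "strand"].to_numpy(),
        "n_meth": m_a, "n_unmeth": u_a,
        "context": ctx_ref[has_a],
        "trinucleotide": merged.loc[has_a, "trinucleotide_ref"].to_numpy(),
    })
    m_b, u_b = draw_counts(has_b, level_b)
    sample_b = pd.DataFrame({
        "chrom": merged.loc[has_b, "chrom"].to_numpy(),
        "pos": merged.loc[has_b, "pos"].to_numpy(),
        "strand": merged.loc[has_b, "strand"].to_numpy(),
        "n_meth": m_b, "n_unmeth": u_b,
        "context": ctx_alt[has_b],
        "trinucleotide": merged.loc[has_b, "trinucleotide_alt"].to_numpy(),
    })

    # --- chloroplast control ------------------------------------------
    chloro = cytosine_table(genome, [CHLOROPLAST])
    controls = []
    for _ in range(2):
        depth = rng.poisson(config.mean_depth, len(chloro))
        n_meth = rng.binomial(depth, config.p_err)
        ctl = chloro.copy()
        ctl.insert(3, "n_meth", n_meth)
        ctl.insert(4, "n_unmeth", depth - n_meth)
        controls.append(ctl[["chrom", "pos", "strand", "n_meth", "n_unmeth",
                             "context", "trinucleotide"]])

    truth_sites = pd.DataFrame({
        "chrom": merged["chrom"], "pos": merged["pos"], "strand": merged["strand"],
        "context_ref": ctx_ref, "context_alt": ctx_alt,
        "state_a": state_a, "level_a": level_a,
        "state_b": state_b, "level_b": level_b,
        "in_dmr": in_dmr, "gene": [gene_ids[i] if i >= 0 else "" for i in site_gene],
        "exon": site_exon,
    })
    transitions = truth_sites.loc[ctx_ref != ctx_alt,
                                  ["chrom", "pos", "strand", "context_ref", "context_alt"]].copy()
    transitions["class"] = transitions["context_ref"] + ">" + transitions["context_alt"]
    transitions = transitions.reset_index(drop=True)

    gene_truth = _gene_truth(genes, truth_sites, silenced_genes, config)
    truth = GroundTruth(truth_sites, dmrs, transitions, gene_truth)
    methylomes = Methylomes(sample_a, sample_b, controls[0], controls[1])
    return methylomes, truth


def _gene_truth(genes, truth_sites: pd.DataFrame, silenced: set[str],
                config: SimulationConfig) -> pd.DataFrame:
    """True mean methylation level per gene and sample: gene-body (all
    contexts pooled) and exon-restricted variants."""
    sub = truth_sites.loc[truth_sites["gene"] != ""]
    rows = []
    grouped = {g: grp for g, grp in sub.groupby("gene")}
    for g in genes:
        grp = grouped.get(g.id)
        if grp is None or len(grp) == 0:
            body_a = body_b = exon_a = exon_b = np.nan
        else:
            body_a = float(np.nanmean(grp["level_a"]))
            body_b = float(np.nanmean(grp["level_b"]))
            ex = grp.loc[grp["exon"]]
            exon_a = float(np.nanmean(ex["level_a"])) if len(ex) else np.nan
            exon_b = float(np.nanmean(ex["level_b"])) if len(ex) else np.nan
        rows.append((g.id, g.chrom, g.start, g.end, g.strand, g.id in silenced,
                     body_a, body_b, exon_a, exon_b))
    return pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "start", "end", "strand", "silenced",
        "true_level_a", "true_level_b", "true_exon_level_a", "true_exon_level_b"])


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    features: list[FeatureRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene expression for both samples, negatively coupled to true
    methylation.

    Per gene and sample, ``log(mean) = intercept - beta * w + N(0,
    sigma)`` where ``w`` is the sample's true gene-body (or exon, per
    ``couples_to``) mean methylation level; replicate abundances are
    log-normal around the mean. Genes planted as silenced get a
    near-zero mean in sample B. Fills ``truth.genes`` columns
    ``mean_expression_a`` / ``mean_expression_b``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = truth.genes
    w_cols = (("true_level_a", "true_level_b") if config.couples_to == "gene_body"
              else ("true_exon_level_a", "true_exon_level_b"))
    rows = []
    means = {"a": [], "b": []}
    for g in genes.itertuples(index=False):
        for sample, w_col in zip(("a", "b"), w_cols):
            w = getattr(g, w_col)
            w = 0.0 if np.isnan(w) else w
            log_mean = (config.expr_intercept - config.expr_beta * w
                        + rng.normal(0.0, config.expr_sigma))
            if sample == "b" and g.silenced:
                log_mean = np.log(0.01)
            means[sample].append(float(np.exp(log_mean)))
            for rep in range(1, config.n_replicates + 1):
                abundance = float(np.exp(log_mean + rng.normal(0.0, config.expr_rep_sigma)))
                rows.append((g.gene_id, f"sample_{sample}", rep, round(abundance, 6)))
    genes["mean_expression_a"] = means["a"]
    genes["mean_expression_b"] = means["b"]
    return pd.DataFrame(rows, columns=["gene_id", "sample", "replicate", "abundance"])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator with one RNG stream seeded once."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome, features, snps = generate_genome(config, rng)
    genes = [f for f in features if f.feature_type == "gene"]
    sil = rng.choice(len(genes), size=config.n_silenced, replace=False) if config.n_silenced else []
    silenced = {genes[int(i)].id for i in sil}
    methylomes, truth = generate_methylomes(genome, features, snps, config, rng,
                                            silenced_genes=silenced)
    expression = generate_expression(features, truth, config, rng)
    perm = rng.permutation(len(genes))
    pair_rows = [(genes[int(perm[i])].id, genes[int(perm[i + 1])].id)
                 for i in range(0, len(genes) - 1, 2)]
    pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b"])
    alt_genome = apply_snps(genome, snps)
    return SimulatedDataset(config, genome, alt_genome, features, snps,
                            methylomes, truth, expression, pairs)


def write_dataset(ds: SimulatedDataset, out_dir: str | Path,
                  include_truth_sites: bool = False) -> None:
    """Write every artifact of a simulated dataset under ``out_dir``.

    Per-site truth is large and only written when
    ``include_truth_sites`` is set; interval/gene/transition truth is
    always written under ``truth/``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta({c: ds.genome[c] for c in ds.nuclear_chroms}, out / "genome.fa")
    write_fasta({CHLOROPLAST: ds.genome[CHLOROPLAST]}, out / "chloroplast.fa")
    write_gff_features(ds.features, out / "features.gff3")
    write_snp_vcf(ds.snps, out / "snps.vcf")
    write_cx_report(ds.methylomes.sample_a, out / "sampleA.CX.txt")
    write_cx_report(ds.methylomes.sample_b, out / "sampleB.CX.txt")
    write_cx_report(ds.methylomes.control_a, out / "controlA.CX.txt")
    write_cx_report(ds.methylomes.control_b, out / "controlB.CX.txt")
    write_expression_table(ds.expression, out / "expression.tsv")
    write_paralog_pairs(ds.paralog_pairs, out / "paralogs.tsv")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    ds.truth.dmrs.to_csv(truth_dir / "dmrs.tsv", sep="\t", index=False)
    ds.truth.transitions.to_csv(truth_dir / "transitions.tsv", sep="\t", index=False)
    ds.truth.genes.to_csv(truth_dir / "genes.tsv", sep="\t", index=False)
    degs = ds.truth.genes.loc[ds.truth.genes["silenced"],
                              ["gene_id"]].assign(direction="down_in_b")
    degs.to_csv(truth_dir / "degs.tsv", sep="\t", index=False)
    ds.config.to_yaml(out / "config.yaml")
    if include_truth_sites:
        ds.truth.sites.to_csv(truth_dir / "sites.tsv", sep="\t", index=False)
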