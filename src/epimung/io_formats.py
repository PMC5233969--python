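"""Readers and writers for the external formats the pipeline touches.

Conventions shared by every function in this module:

* All coordinates are **1-based inclusive** at every external boundary,
  matching GFF3, VCF and the Bismark per-cytosine ("CX") report dialect.
* Minus-strand cytosines are reported at the plus-strand coordinate of
  the G on the plus strand (the Bismark convention).
* The CX report is exactly 7 tab-separated columns with no header:
  ``chrom  pos  strand  n_meth  n_unmeth  context  trinucleotide``.

Bulk analysis functions elsewhere in the package operate on pandas
DataFrames; streaming record generators are provided where the contract
is per-record (``read_cx_report``).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")
FEATURE_TYPES = ("gene", "exon", "intron", "five_prime_UTR", "three_prime_UTR", "TE")

#: Column order of the 7-column Bismark-style CX report.
CX_COLUMNS = ("chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide")

_VALID_RESIDUES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violates the syntax or dialect expected of its format."""


class ValidationError(ValueError):
    """Parsed content contradicts the supplied reference data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class GenomeSequence(Mapping):
    """An in-memory genome: unique sequence names mapped to uppercase
    sequences over the alphabet {A, C, G, T, N}.

    Behaves as a read-only mapping from name to sequence string. Also
    houses control sequences (e.g. the unmethylated chloroplast genome)
    alongside the nuclear chromosomes.
    """

    def __init__(self, sequences: Mapping[str, str]):
        cleaned: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if len(seq) == 0:
                raise FormatError(f"sequence {name!r} is empty")
            bad = set(seq) - _VALID_RESIDUES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise FormatError(
                    f"illegal residue {seq[pos]!r} in sequence {name!r} "
                    f"at offset {pos + 1} (1-based)"
                )
            if name in cleaned:
                raise FormatError(f"duplicate sequence name {name!r}")
            cleaned[name] = seq
        if not cleaned:
            raise FormatError("no sequences")
        self._sequences = cleaned

    def __getitem__(self, name: str) -> str:
        return self._sequences[name]

    def __iter__(self):
        return iter(self._sequences)

    def __len__(self) -> int:
        return len(self._sequences)

    @property
    def names(self) -> list[str]:
        return list(self._sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._sequences.items()}

    def subset(self, names: Iterable[str]) -> "GenomeSequence":
        return GenomeSequence({n: self._sequences[n] for n in names})

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        parts = ", ".join(f"{n}:{len(s)}bp" for n, s in self._sequences.items())
        return f"GenomeSequence({parts})"


@dataclass(frozen=True)
class SiteCounts:
    """One cytosine position with strand, context and read counts.

    ``pos`` is the 1-based plus-strand coordinate of the cytosine (for a
    minus-strand cytosine, the coordinate of the G on the plus strand).
    ``trinucleotide`` is read 5'->3' on the cytosine's own strand and may
    be shorter than 3 bases at a sequence end.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    trinucleotide: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self):
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be non-negative")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True)
class FeatureRecord:
    """A genomic feature with 1-based inclusive coordinates."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_type: str
    parent: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(
                f"feature {self.id!r}: end {self.end} < start {self.start}"
            )
        if self.feature_type not in FEATURE_TYPES:
            raise FormatError(f"feature {self.id!r}: unknown type {self.feature_type!r}")
        if self.feature_type in ("exon", "intron", "five_prime_UTR", "three_prime_UTR") and not self.parent:
            raise FormatError(f"{self.feature_type} {self.id!r} lacks a gene parent")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SNPVariant:
    """A biallelic single-nucleotide variant between two accessions."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.ref_base not in "ACGT" or self.alt_base not in "ACGT":
            raise ValueError("ref/alt must be single bases in {A,C,G,T}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence`.

    Sequences are uppercased; header description text after the first
    whitespace is dropped from names. Duplicate names, empty files and
    residues outside {A,C,G,T,N} raise :class:`FormatError` (the residue
    error names the offending record and 1-based offset).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence | Mapping[str, str], path: str | Path) -> None:
    """Write sequences as wrapped FASTA (70 columns)."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# CX reports
# ---------------------------------------------------------------------------

def read_cx_report(path: str | Path) -> Iterator[SiteCounts]:
    """Stream a 7-column CX report as :class:`SiteCounts` records.

    Yields records in file order with constant per-record working state.
    Zero-coverage rows are preserved (downstream operations filter them).
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 tab-separated columns, got {len(fields)}"
                )
            chrom, pos, strand, n_meth, n_unmeth, context, tri = fields
            try:
                pos_i, m_i, u_i = int(pos), int(n_meth), int(n_unmeth)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if m_i < 0 or u_i < 0:
                raise FormatError(f"{path}:{lineno}: negative read count")
            if context not in CONTEXTS:
                raise FormatError(f"{path}:{lineno}: unknown context token {context!r}")
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            yield SiteCounts(chrom, pos_i, strand, context, tri, m_i, u_i)


def read_cx_frame(path: str | Path) -> pd.DataFrame:
    """Load a CX report as a DataFrame with :data:`CX_COLUMNS` columns.

    Vectorized equivalent of :func:`read_cx_report` for bulk analysis.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=list(CX_COLUMNS),
            dtype={"chrom": str, "pos": np.int64, "strand": str,
                   "n_meth": np.int64, "n_unmeth": np.int64,
                   "context": str, "trinucleotide": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(CX_COLUMNS))
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: malformed CX report ({exc})") from None
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        raise FormatError(f"{path}: negative read count")
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        tok = df.loc[bad, "context"].iloc[0]
        raise FormatError(f"{path}: unknown context token {tok!r}")
    return df


def write_cx_report(sites: Iterable[SiteCounts] | pd.DataFrame, path: str | Path) -> None:
    """Write sites as a 7-column CX report, in the given order, no header."""
    if isinstance(sites, pd.DataFrame):
        sites[list(CX_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)
        return
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.n_meth}\t{s.n_unmeth}"
                f"\t{s.context}\t{s.trinucleotide}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 features
# ---------------------------------------------------------------------------

_GFF_TYPE_MAP = {
    "gene": "gene",
    "exon": "exon",
    "intron": "intron",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "transposable_element": "TE",
    "TE": "TE",
}


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff_features(path: str | Path) -> list[FeatureRecord]:
    """Read gene/exon/UTR/TE features from GFF3; synthesize introns.

    Feature types outside the closed set are ignored with a warning
    (mRNA records are still used to resolve exon parents to genes).
    Intron records are synthesized as the gaps between consecutive exons
    of the same gene whenever the file carries no explicit introns for
    that gene.
    """
    raw: list[tuple[str, str, int, int, str, dict]] = []
    id_to_parent: dict[str, str] = {}
    id_to_type: dict[str, str] = {}
    unknown: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns, got {len(cols)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attr_text = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end {end_i} < start {start_i}")
            attrs = _parse_gff_attributes(attr_text)
            fid = attrs.get("ID", "")
            if fid:
                id_to_parent[fid] = attrs.get("Parent", "")
                id_to_type[fid] = ftype
            if ftype not in _GFF_TYPE_MAP and ftype != "mRNA":
                unknown.add(ftype)
                continue
            raw.append((chrom, ftype, start_i, end_i, strand, attrs))
    if unknown:
        log.warning("ignored %d unknown GFF feature types: %s", len(unknown), sorted(unknown))

    def resolve_gene(parent: str) -> str:
        # walk mRNA (or deeper) parent chains up to the gene record
        seen = set()
        while parent in id_to_type and id_to_type[parent] != "gene" and parent not in seen:
            seen.add(parent)
            parent = id_to_parent.get(parent, "")
        return parent

    features: list[FeatureRecord] = []
    counters: dict[str, int] = {}
    for chrom, ftype, start, end, strand, attrs in raw:
        if ftype == "mRNA":
            continue
        mapped = _GFF_TYPE_MAP[ftype]
        parent = resolve_gene(attrs.get("Parent", ""))
        if mapped == "exon" and not parent:
            raise FormatError(f"exon at {chrom}:{start}-{end} lacks a Parent attribute")
        fid = attrs.get("ID", "")
        if not fid:
            counters[mapped] = counters.get(mapped, 0) + 1
            fid = f"{mapped}_{counters[mapped]}"
        features.append(FeatureRecord(fid, chrom, start, end, strand, mapped, parent))

    features.extend(synthesize_introns(features))
    return features


def synthesize_introns(features: Iterable[FeatureRecord]) -> list[FeatureRecord]:
    """Introns as gaps between consecutive exons of a gene, for genes
    without explicit intron records."""
    by_gene: dict[str, list[FeatureRecord]] = {}
    has_introns: set[str] = set()
    meta: dict[str, FeatureRecord] = {}
    for f in features:
        if f.feature_type == "exon":
            by_gene.setdefault(f.parent, []).append(f)
        elif f.feature_type == "intron":
            has_introns.add(f.parent)
        elif f.feature_type == "gene":
            meta[f.id] = f
    introns: list[FeatureRecord] = []
    for gene_id, exons in sorted(by_gene.items()):
        if gene_id in has_introns:
            continue
        exons = sorted(exons, key=lambda e: e.start)
        for i, (a, b) in enumerate(zip(exons, exons[1:]), start=1):
            if b.start > a.end + 1:
                introns.append(FeatureRecord(
                    f"{gene_id}.intron{i}", a.chrom, a.end + 1, b.start - 1,
                    a.strand, "intron", gene_id,
                ))
    return introns


_GFF_TYPE_OUT = {"TE": "transposable_element"}


def write_gff_features(features: Iterable[FeatureRecord], path: str | Path) -> None:
    """Write features as GFF3 (introns are omitted: they are derivable)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            if f.feature_type == "intron":
                continue
            attrs = f"ID={f.id}"
            if f.parent:
                attrs += f";Parent={f.parent}"
            ftype = _GFF_TYPE_OUT.get(f.feature_type, f.feature_type)
            fh.write(f"{f.chrom}\tepimung\t{ftype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# VCF (SNVs only)
# ---------------------------------------------------------------------------

def read_snp_table(path: str | Path, genome: GenomeSequence | None = None) -> list[SNPVariant]:
    """Read biallelic SNVs from a (possibly minimal) VCF.

    Multi-allelic rows are split into one record per alternate allele;
    indels and multi-nucleotide records are skipped with a logged count.
    When a genome is supplied, every REF base is validated against it and
    mismatches raise :class:`ValidationError` listing the offending
    positions.
    """
    snps: list[SNPVariant] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                cols = line.split()
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 VCF columns")
            chrom, pos, _vid, ref, alt_field = cols[:5]
            try:
                pos_i = int(pos)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer POS") from None
            if len(ref) != 1 or ref not in "ACGT":
                n_skipped += 1
                continue
            for alt in alt_field.split(","):
                if len(alt) != 1 or alt not in "ACGT" or alt == ref:
                    n_skipped += 1
                    continue
                snps.append(SNPVariant(chrom, pos_i, ref, alt))
    if n_skipped:
        log.info("%s: skipped %d non-SNV allele records", path, n_skipped)
    if genome is not None:
        bad = [s for s in snps
               if s.chrom not in genome or genome[s.chrom][s.pos - 1] != s.ref_base]
        if bad:
            where = ", ".join(f"{s.chrom}:{s.pos}" for s in bad[:10])
            raise ValidationError(
                f"{len(bad)} SNP REF bases do not match the genome (e.g. {where})"
            )
    return snps


def write_snp_vcf(snps: Iterable[SNPVariant], path: str | Path) -> None:
    """Write SNVs as a minimal VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref_base}\t{s.alt_base}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# expression / paralog tables, BED output
# ---------------------------------------------------------------------------

EXPRESSION_COLUMNS = ("gene_id", "sample", "replicate", "abundance")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read the per-gene expression TSV (``gene_id sample replicate
    abundance``); validates non-negativity and key uniqueness."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EXPRESSION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing expression columns {sorted(missing)}")
    if (df["abundance"] < 0).any():
        raise FormatError(f"{path}: negative abundance")
    if df.duplicated(["gene_id", "sample", "replicate"]).any():
        raise FormatError(f"{path}: duplicate (gene, sample, replicate) keys")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df[list(EXPRESSION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_paralog_pairs(path: str | Path) -> pd.DataFrame:
    """Read the two-column paralog pair TSV (``gene_a gene_b``)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns gene_a, gene_b")
    return df[["gene_a", "gene_b"]]


def write_paralog_pairs(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_a", "gene_b"]].to_csv(path, sep="\t", index=False)


def write_bed_dmrs(dmrs: pd.DataFrame, path: str | Path) -> None:
    """Write DMR windows as BED6: 0-based half-open interval, name,
    -log10(p) rounded to 3 decimals as score, '.' strand."""
    with open(path, "w") as fh:
        for i, row in enumerate(dmrs.itertuples(index=False), start=1):
            p = max(float(row.p_value), 1e-300)
            score = round(-np.log10(p), 3)
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\tDMR_{i}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# methylation-call table round-trip (internal TSV dialect)
# ---------------------------------------------------------------------------

CALLS_COLUMNS = list(CX_COLUMNS) + ["p_value", "q_value", "status", "c_meth", "c_unmeth"]


def write_calls_table(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a methylation-call DataFrame as TSV; the boolean
    ``methylated`` column is rendered as a status string."""
    out = calls.copy()
    out["status"] = np.where(out["methylated"], "methylated", "unmethylated")
    out[CALLS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_calls_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    df["methylated"] = df["status"] == "methylated"
    return df.drop(columns=["status"])
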