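"""SNP-induced cytosine-context transitions (obligate epialleles).

A SNP within two bases of a cytosine can change that cytosine's
context (CG<->CHG, CHG<->CHH, CG<->CHH), create a new cytosine
(C-gain) or destroy one (C-loss). Such variants make the methylation
difference between two accessions *obligate*: it is fully dependent on
the underlying genetic variant. This module substitutes SNPs into the
reference, classifies every context transition between the two
genomes, and cross-tabulates the called methylation states of the two
samples against the transition classes.

Contexts are evaluated on the fully substituted alternate genome, so
clustered SNPs compose correctly; transitions are attributed per
affected cytosine, with the per-SNP tally recovered by counting
distinct causal SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_context import classify_context, cytosine_table
from .io_formats import GenomeSequence, SNPVariant, ValidationError

#: window, in bases, within which a SNP can alter a cytosine's context
CONTEXT_REACH = 2

STATE_CATEGORIES = ("M>M", "M>U", "U>M", "U>U")


def apply_snps(genome: GenomeSequence, snps: list[SNPVariant]) -> GenomeSequence:
    """Return the genome with every SNP substituted (pure substitution:
    lengths and coordinates unchanged).

    Raises :class:`ValidationError` listing positions whose REF base
    does not match the genome.
    """
    arrays = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    bad = []
    for s in snps:
        if s.chrom not in arrays or not (1 <= s.pos <= len(arrays[s.chrom])):
            bad.append(s)
            continue
        if chr(arrays[s.chrom][s.pos - 1]) != s.ref_base:
            bad.append(s)
            continue
        arrays[s.chrom][s.pos - 1] = ord(s.alt_base)
    if bad:
        where = ", ".join(f"{s.chrom}:{s.pos}" for s in bad[:10])
        raise ValidationError(f"{len(bad)} SNPs do not match the reference (e.g. {where})")
    return GenomeSequence({name: arr.decode("ascii") for name, arr in arrays.items()})


def _context_at(seq: str, pos: int, strand: str) -> str | None:
    """Own-strand context of the position, or None.

    Returns ``None`` when there is no cytosine on that strand at the
    position *or* its context is undecidable (N / sequence end); use
    :func:`_has_c` to distinguish the two.
    """
    if strand == "+":
        if seq[pos - 1] != "C":
            return None
        return classify_context(seq[pos - 1:pos + 2])
    if seq[pos - 1] != "G":
        return None
    from .genome_context import reverse_complement
    tri = reverse_complement(seq[max(pos - 3, 0):pos])
    return classify_context(tri)


def _has_c(seq: str, pos: int, strand: str) -> bool:
    base = seq[pos - 1]
    return base == "C" if strand == "+" else base == "G"


def classify_transitions(
    ref_genome: GenomeSequence,
    snps: list[SNPVariant],
    alt_genome: GenomeSequence | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every cytosine whose context differs between genomes.

    Scans the positions within :data:`CONTEXT_REACH` bases of each SNP
    on both strands. A position yields a transition record when its
    decidable context differs between the genomes, or when a cytosine
    exists in exactly one genome at that strand/position (C-gain /
    C-loss, labelled with context ``none`` on the missing side).
    Positions whose context is undecidable (N) on either side are
    skipped.

    Returns ``(transitions, class_totals)``. ``transitions`` has one
    row per affected cytosine with its nearest causal SNP; classes are
    directed ``"<ref>><alt>"`` strings (e.g. ``"CHG>CHH"``,
    ``"none>CG"``). ``class_totals`` tallies sites per class and
    carries ``attrs['n_snps_changing_context']`` (distinct causal
    SNPs).
    """
    if alt_genome is None:
        alt_genome = apply_snps(ref_genome, snps)

    snps_by_chrom: dict[str, list[SNPVariant]] = {}
    for s in snps:
        snps_by_chrom.setdefault(s.chrom, []).append(s)

    rows = []
    for chrom, chrom_snps in snps_by_chrom.items():
        ref_seq = ref_genome[chrom]
        alt_seq = alt_genome[chrom]
        L = len(ref_seq)
        snp_pos = np.array(sorted({s.pos for s in chrom_snps}))
        snp_map = {s.pos: s for s in chrom_snps}
        candidates = sorted({
            p for sp in snp_pos
            for p in range(max(1, sp - CONTEXT_REACH), min(L, sp + CONTEXT_REACH) + 1)
        })
        for pos in candidates:
            for strand in ("+", "-"):
                c_ref = _has_c(ref_seq, pos, strand)
                c_alt = _has_c(alt_seq, pos, strand)
                if not c_ref and not c_alt:
                    continue
                ctx_ref = _context_at(ref_seq, pos, strand) if c_ref else "none"
                ctx_alt = _context_at(alt_seq, pos, strand) if c_alt else "none"
                if ctx_ref is None or ctx_alt is None:  # undecidable (N / end)
                    continue
                if ctx_ref == ctx_alt:
                    continue
                causal = _nearest_causal_snp(snp_map, snp_pos, pos, strand,
                                             gain_loss=(ctx_ref == "none" or ctx_alt == "none"))
                if causal is None:
                    continue
                rows.append((chrom, pos, strand, ctx_ref, ctx_alt,
                             f"{ctx_ref}>{ctx_alt}",
                             causal.pos, causal.ref_base, causal.alt_base))
    transitions = pd.DataFrame(rows, columns=[
        "chrom", "pos", "strand", "context_ref", "context_alt", "class",
        "snp_pos", "snp_ref", "snp_alt"])
    if len(transitions):
        transitions = transitions.sort_values(
            ["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
        totals = (transitions.groupby("class").size()
                  .rename("n_sites").reset_index())
        n_causal = transitions.drop_duplicates(["chrom", "snp_pos"]).shape[0]
    else:
        totals = pd.DataFrame(columns=["class", "n_sites"])
        n_causal = 0
    totals.attrs["n_snps_changing_context"] = int(n_causal)
    return transitions, totals


def _nearest_causal_snp(snp_map, snp_pos: np.ndarray, pos: int, strand: str,
                        gain_loss: bool) -> SNPVariant | None:
    """The nearest SNP that can explain a transition at (pos, strand).

    For C-gain/C-loss the causal SNP is at the site itself; for an
    interchange it lies within the site's own-strand context window
    (pos..pos+2 on '+', pos-2..pos on '-').
    """
    if gain_loss:
        return snp_map.get(pos)
    window = range(pos, pos + CONTEXT_REACH + 1) if strand == "+" \
        else range(pos - CONTEXT_REACH, pos + 1)
    best = None
    for p in window:
        if p in snp_map and (best is None or abs(p - pos) < abs(best.pos - pos)):
            best = snp_map[p]
    return best


def brute_force_transitions(
    ref_genome: GenomeSequence,
    alt_genome: GenomeSequence,
) -> pd.DataFrame:
    """Whole-genome re-enumeration diff (independent of the SNP-local
    scan): outer-join the full cytosine tables of both genomes by
    (chrom, pos, strand) and keep sites whose decidable context
    differs, with ``none`` for a cytosine absent from one genome.

    Used as the oracle for :func:`classify_transitions`; the two must
    agree exactly on any pair of genomes differing only by SNVs.
    """
    ref = cytosine_table(ref_genome)[["chrom", "pos", "strand", "context"]]
    alt = cytosine_table(alt_genome)[["chrom", "pos", "strand", "context"]]
    merged = ref.merge(alt, on=["chrom", "pos", "strand"], how="outer",
                       suffixes=("_ref", "_alt"))
    merged["context_ref"] = merged["context_ref"].fillna("none")
    merged["context_alt"] = merged["context_alt"].fillna("none")
    diff = merged.loc[merged["context_ref"] != merged["context_alt"]].copy()
    diff["class"] = diff["context_ref"] + ">" + diff["context_alt"]
    return diff.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


def crosstab_transitions(
    transitions: pd.DataFrame,
    calls_ref_sample: pd.DataFrame,
    calls_alt_sample: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-tabulate methylation-state changes against transition classes.

    ``calls_ref_sample`` are calls of the reference-mapped sample and
    ``calls_alt_sample`` of the alternate-genome-mapped sample (shared
    coordinates). For each transition the called status is looked up at
    (chrom, pos, strand) in both samples; a site uncovered (raw depth
    0 or absent) in either sample lands in the ``uncovered`` column,
    otherwise in the M>M / M>U / U>M / U>U cell of its class. Row sums
    equal class totals.
    """
    def status_frame(calls: pd.DataFrame, col: str) -> pd.DataFrame:
        covered = (calls["n_meth"] + calls["n_unmeth"]) >= 1
        sub = calls.loc[covered, ["chrom", "pos", "strand", "methylated"]].copy()
        return sub.rename(columns={"methylated": col})

    merged = transitions.merge(status_frame(calls_ref_sample, "meth_ref"),
                               on=["chrom", "pos", "strand"], how="left")
    merged = merged.merge(status_frame(calls_alt_sample, "meth_alt"),
                          on=["chrom", "pos", "strand"], how="left")
    classes = sorted(transitions["class"].unique()) if len(transitions) else []
    table = pd.DataFrame(0, index=pd.Index(classes, name="class"),
                         columns=list(STATE_CATEGORIES) + ["uncovered"], dtype=np.int64)
    if len(merged) == 0:
        return table
    uncovered = merged["meth_ref"].isna() | merged["meth_alt"].isna()
    ref_s = merged["meth_ref"].map({True: "M", False: "U"})
    alt_s = merged["meth_alt"].map({True: "M", False: "U"})
    cat = (ref_s + ">" + alt_s).where(~uncovered, "uncovered")
    counts = pd.crosstab(merged["class"], cat.rename("cat"))
    for col in counts.columns:
        table.loc[counts.index, col] += counts[col]
    return table
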