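"""Strand-aware enumeration and classification of cytosine contexts.

Plant DNA methylation is described in three sequence contexts read
5'->3' on the cytosine's own strand: CG, CHG and CHH, where H is A, T
or C. The context of a cytosine is decided from the following two bases
on its strand:

* second base G  -> CG (the third base is irrelevant),
* else third base G -> CHG,
* else (second and third both in {A,T,C}) -> CHH.

At a sequence end the context is assigned iff it is decidable from the
available bases: a terminal ``CG`` is still CG, but a terminal ``CT``
is undefined (the third base would be needed). Any N at a position
required for the decision makes the context undefined; undefined sites
are excluded from enumeration. Minus-strand cytosines (a G on the plus
strand) are reported at the plus-strand coordinate of that G.
"""

from __future__ import annotations

from collections.abc import Iterator
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte codes used by the vectorized scanner
_A, _C, _G, _T, _N = (ord(c) for c in "ACGTN")
_PAD = 0  # sentinel for "no base" (sequence end)


@dataclass(frozen=True)
class CytosineSite:
    """A cytosine with decidable context.

    ``pos`` is 1-based in plus-strand coordinates; ``trinucleotide`` is
    read 5'->3' on the cytosine's own strand and may be 2 bases at a
    sequence end (terminal CG).
    """

    chrom: str
    pos: int
    strand: str
    context: str
    trinucleotide: str


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_context(trinucleotide: str) -> str | None:
    """Classify a 1-3 base own-strand context word; ``None`` if undefined.

    Raises ``ValueError`` unless the first base is C.
    """
    if not trinucleotide or trinucleotide[0] != "C":
        raise ValueError(f"context word must start with C, got {trinucleotide!r}")
    b2 = trinucleotide[1] if len(trinucleotide) > 1 else ""
    b3 = trinucleotide[2] if len(trinucleotide) > 2 else ""
    if b2 == "G":
        return "CG"
    if b2 not in ("A", "T", "C"):
        return None  # N, or end of sequence: second base needed
    if b3 == "G":
        return "CHG"
    if b3 in ("A", "T", "C"):
        return "CHH"
    return None  # third base needed and absent/N


def _context_codes(b2: np.ndarray, b3: np.ndarray) -> np.ndarray:
    """Vectorized context decision. Returns 0 undefined, 1 CG, 2 CHG, 3 CHH."""
    is_h2 = (b2 == _A) | (b2 == _T) | (b2 == _C)
    is_h3 = (b3 == _A) | (b3 == _T) | (b3 == _C)
    out = np.zeros(b2.shape, dtype=np.int8)
    out[b2 == _G] = 1
    out[is_h2 & (b3 == _G)] = 2
    out[is_h2 & is_h3] = 3
    return out


_CODE_TO_CONTEXT = {1: "CG", 2: "CHG", 3: "CHH"}


def cytosine_table(genome: GenomeSequence, chroms: list[str] | None = None) -> pd.DataFrame:
    """Enumerate every decidable-context cytosine on both strands.

    Returns a DataFrame with columns ``chrom, pos, strand, context,
    trinucleotide`` sorted by (chrom in genome order, pos, strand with
    '+' first). This is the bulk substrate for all site-level analyses.
    """
    frames = []
    names = chroms if chroms is not None else genome.names
    for chrom in names:
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        L = len(arr)
        pad = np.concatenate([np.full(2, _PAD, np.uint8), arr, np.full(2, _PAD, np.uint8)])

        # plus strand: base C at i (0-based); next bases at i+1, i+2
        plus_idx = np.flatnonzero(arr == _C)
        b2 = pad[plus_idx + 3]
        b3 = pad[plus_idx + 4]
        plus_codes = _context_codes(b2, b3)

        # minus strand: plus-strand G at i; own-strand bases are the
        # complements of i, i-1, i-2 read towards lower coordinates
        minus_idx = np.flatnonzero(arr == _G)
        mb2 = _complement_codes(pad[minus_idx + 1])
        mb3 = _complement_codes(pad[minus_idx + 0])
        minus_codes = _context_codes(mb2, mb3)

        rows = []
        keep = plus_codes > 0
        for i, code in zip(plus_idx[keep], plus_codes[keep]):
            rows.append((chrom, int(i) + 1, "+", _CODE_TO_CONTEXT[int(code)],
                         seq[i:i + 3]))
        keep = minus_codes > 0
        for i, code in zip(minus_idx[keep], minus_codes[keep]):
            tri = reverse_complement(seq[max(int(i) - 2, 0):int(i) + 1])
            rows.append((chrom, int(i) + 1, "-", _CODE_TO_CONTEXT[int(code)], tri))
        frame = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "trinucleotide"])
        if len(frame):
            frame = frame.sort_values(
                ["pos", "strand"], ascending=[True, True], kind="stable"
            ).reset_index(drop=True)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "trinucleotide"])
    return pd.concat(frames, ignore_index=True)


def _complement_codes(codes: np.ndarray) -> np.ndarray:
    out = np.full(codes.shape, _PAD, dtype=np.uint8)
    out[codes == _A] = _T
    out[codes == _T] = _A
    out[codes == _C] = _G
    out[codes == _G] = _C
    out[codes == _N] = _N
    return out


def enumerate_cytosines(genome: GenomeSequence) -> Iterator[CytosineSite]:
    """Yield :class:`CytosineSite` records sorted by (chrom, pos, strand)."""
    table = cytosine_table(genome)
    for row in table.itertuples(index=False):
        yield CytosineSite(row.chrom, int(row.pos), row.strand, row.context,
                           row.trinucleotide)


def flanking_composition(
    sites: pd.DataFrame,
    genome: GenomeSequence,
    k: int = 5,
) -> dict[str, pd.DataFrame]:
    """Base composition of the +/-k bases flanking cytosines, per context.

    ``sites`` needs columns ``chrom, pos, strand, context`` (typically
    methylated calls of one or more contexts). Frequencies are computed
    on each site's own strand (minus-strand flanks are
    reverse-complemented); sites whose window overruns a sequence end,
    or that cover an N, are skipped and counted in the result's
    ``attrs['n_skipped']``. Each returned DataFrame is indexed by offset
    -k..k with columns A/C/G/T summing to 1 per row; offset 0 is 100% C.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(sites) == 0:
        raise ValueError("no sites supplied")

    offsets = np.arange(-k, k + 1)
    result: dict[str, pd.DataFrame] = {}
    n_skipped = 0
    for context, grp in sites.groupby("context", sort=True):
        counts = np.zeros((2 * k + 1, 4), dtype=np.int64)
        used = 0
        for (chrom, strand), sub in grp.groupby(["chrom", "strand"], sort=True):
            arr = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
            pos0 = sub["pos"].to_numpy() - 1
            ok = (pos0 - k >= 0) & (pos0 + k < len(arr))
            n_skipped += int((~ok).sum())
            pos0 = pos0[ok]
            if len(pos0) == 0:
                continue
            window = arr[pos0[:, None] + offsets[None, :]]  # (n, 2k+1)
            if strand == "-":
                window = _complement_codes(window[:, ::-1])
            has_n = (window == _N).any(axis=1)
            n_skipped += int(has_n.sum())
            window = window[~has_n]
            used += len(window)
            for j, base in enumerate((_A, _C, _G, _T)):
                counts[:, j] += (window == base).sum(axis=0)
        if used == 0:
            continue
        freq = counts / counts.sum(axis=1, keepdims=True)
        df = pd.DataFrame(freq, index=pd.Index(offsets, name="offset"),
                          columns=["A", "C", "G", "T"])
        df.attrs["n_sites"] = used
        result[context] = df
    if not result:
        raise ValueError("all sites skipped (windows overran sequence ends)")
    for df in result.values():
        df.attrs["n_skipped"] = n_skipped
    return result
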