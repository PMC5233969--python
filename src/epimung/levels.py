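"""Weighted methylation levels, metagene/TE profiles, window landscapes
and genomic-category tallies.

The weighted methylation level of a region is the depth-weighted ratio
``sum(m) / sum(m + u)`` over all cytosines of one context in the
region, using corrected read counts from the calling step by default.
A region with zero denominator has an *undefined* level (NaN), which is
distinct from 0.0 and excluded from cross-feature means: absence of
data is not hypomethylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import FeatureRecord, GenomeSequence


@dataclass(frozen=True)
class WeightedLevel:
    """Per-region, per-context weighted methylation level."""

    region_id: str
    context: str
    numerator: int
    denominator: int

    @property
    def level(self) -> float:
        """``numerator / denominator``; NaN when the denominator is 0."""
        if self.denominator == 0:
            return float("nan")
        return self.numerator / self.denominator

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def _count_columns(use_corrected: bool) -> tuple[str, str]:
    return ("c_meth", "c_unmeth") if use_corrected else ("n_meth", "n_unmeth")


def weighted_level(
    calls: pd.DataFrame,
    region: FeatureRecord | tuple[str, int, int],
    context: str | None = None,
    use_corrected: bool = True,
) -> WeightedLevel:
    """Weighted level of one region (both strands pooled).

    ``region`` is a :class:`FeatureRecord` or a ``(chrom, start, end)``
    tuple with 1-based inclusive coordinates. ``context=None`` pools all
    three contexts. Raises ``KeyError`` for a chromosome absent from the
    call set.
    """
    if isinstance(region, tuple):
        chrom, start, end = region
        region_id = f"{chrom}:{start}-{end}"
    else:
        chrom, start, end, region_id = region.chrom, region.start, region.end, region.id
    if chrom not in set(calls["chrom"].unique()):
        raise KeyError(f"unknown chromosome {chrom!r}")
    mask = (calls["chrom"] == chrom) & (calls["pos"] >= start) & (calls["pos"] <= end)
    if context is not None:
        mask &= calls["context"] == context
    sub = calls.loc[mask]
    mcol, ucol = _count_columns(use_corrected)
    num = int(sub[mcol].sum())
    den = num + int(sub[ucol].sum())
    return WeightedLevel(region_id, context or "all", num, den)


def region_levels(
    calls: pd.DataFrame,
    features: list[FeatureRecord],
    context: str | None = None,
    use_corrected: bool = True,
) -> pd.DataFrame:
    """Vectorized weighted levels for many regions at once.

    Returns a DataFrame indexed like ``features`` with columns
    ``id, numerator, denominator, level`` (NaN level when undefined).
    Regions may overlap; each site contributes to every region covering
    it.
    """
    mcol, ucol = _count_columns(use_corrected)
    sub = calls if context is None else calls.loc[calls["context"] == context]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        by_chrom[chrom] = (
            grp["pos"].to_numpy(),
            grp[mcol].to_numpy(),
            grp[ucol].to_numpy(),
        )
    rows = []
    for f in features:
        if f.chrom in by_chrom:
            pos, m, u = by_chrom[f.chrom]
            lo = np.searchsorted(pos, f.start, side="left")
            hi = np.searchsorted(pos, f.end, side="right")
            num = int(m[lo:hi].sum())
            den = num + int(u[lo:hi].sum())
        else:
            num = den = 0
        rows.append((f.id, num, den, num / den if den else np.nan))
    return pd.DataFrame(rows, columns=["id", "numerator", "denominator", "level"])


# ---------------------------------------------------------------------------
# metagene / TE profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Binned average methylation across length-normalized features.

    ``levels`` has one value per bin in 5'->3' order: ``flank_bins``
    upstream bins, ``body_bins`` body bins, ``flank_bins`` downstream
    bins. ``n_features`` counts features contributing at least one
    defined bin; ``n_skipped`` counts features shorter than
    ``body_bins`` bases.
    """

    context: str
    flank_bp: int
    body_bins: int
    flank_bins: int
    levels: np.ndarray
    n_per_bin: np.ndarray
    n_features: int
    n_skipped: int

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def to_frame(self) -> pd.DataFrame:
        seg = (["upstream"] * self.flank_bins + ["body"] * self.body_bins
               + ["downstream"] * self.flank_bins)
        return pd.DataFrame({
            "bin": np.arange(self.n_bins), "segment": seg,
            "mean_level": self.levels, "n_features": self.n_per_bin,
        })


def metagene_profile(
    calls: pd.DataFrame,
    features: list[FeatureRecord],
    flank_bp: int = 2000,
    body_bins: int = 20,
    flank_bins: int = 20,
    context: str | None = "CG",
    use_corrected: bool = True,
    pooled: bool = False,
) -> MetageneProfile:
    """Average methylation over length-normalized feature bodies and
    fixed-width flanks.

    Each feature body is split into ``body_bins`` equal-width intervals
    (remainder bases go to the final 3' bin); each flank into
    ``flank_bins`` equal-width intervals. Per-feature per-bin weighted
    levels are computed from both strands; minus-strand features are
    reversed so bin order is always 5'->3'. The profile value of a bin
    is the mean over features with a defined level there (``pooled=True``
    instead pools counts across features before dividing). Features
    shorter than ``body_bins`` bases are skipped and counted.
    """
    if not features:
        raise ValueError("empty feature list")
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    mcol, ucol = _count_columns(use_corrected)
    sub = calls if context is None else calls.loc[calls["context"] == context]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        by_chrom[chrom] = (grp["pos"].to_numpy(), grp[mcol].to_numpy(), grp[ucol].to_numpy())

    n_bins = 2 * flank_bins + body_bins
    sum_levels = np.zeros(n_bins)
    n_defined = np.zeros(n_bins, dtype=np.int64)
    pooled_m = np.zeros(n_bins, dtype=np.int64)
    pooled_t = np.zeros(n_bins, dtype=np.int64)
    n_features = 0
    n_skipped = 0
    flank_binw = flank_bp / flank_bins if flank_bins else 0.0

    for f in features:
        body_len = f.end - f.start + 1
        if body_len < body_bins:
            n_skipped += 1
            continue
        if f.chrom not in by_chrom:
            continue
        pos, m, u = by_chrom[f.chrom]
        lo = np.searchsorted(pos, f.start - flank_bp, side="left")
        hi = np.searchsorted(pos, f.end + flank_bp, side="right")
        if lo == hi:
            continue
        p = pos[lo:hi]
        fm, fu = m[lo:hi], u[lo:hi]

        bins = np.empty(len(p), dtype=np.int64)
        left = p < f.start
        right = p > f.end
        body = ~(left | right)
        body_binw = body_len // body_bins  # remainder bases into final bin
        bins[body] = flank_bins + np.minimum(
            (p[body] - f.start) // body_binw, body_bins - 1)
        if flank_bins:
            bins[left] = np.floor((p[left] - (f.start - flank_bp)) / flank_binw).astype(np.int64)
            bins[right] = (flank_bins + body_bins
                           + np.minimum(np.floor((p[right] - f.end - 1) / flank_binw),
                                        flank_bins - 1).astype(np.int64))
        elif left.any() or right.any():  # no flank bins requested
            keep = body
            p, fm, fu, bins = p[keep], fm[keep], fu[keep], bins[keep]
        if f.strand == "-":
            bins = n_bins - 1 - bins

        bm = np.bincount(bins, weights=fm, minlength=n_bins)
        bt = np.bincount(bins, weights=fm + fu, minlength=n_bins)
        defined = bt > 0
        if not defined.any():
            continue
        n_features += 1
        sum_levels[defined] += bm[defined] / bt[defined]
        n_defined += defined
        pooled_m += bm.astype(np.int64)
        pooled_t += bt.astype(np.int64)

    with np.errstate(invalid="ignore"):
        if pooled:
            levels = np.where(pooled_t > 0, pooled_m / np.maximum(pooled_t, 1), np.nan)
        else:
            levels = np.where(n_defined > 0, sum_levels / np.maximum(n_defined, 1), np.nan)
    return MetageneProfile(context or "all", flank_bp, body_bins, flank_bins,
                           levels, n_defined, n_features, n_skipped)


# ---------------------------------------------------------------------------
# window landscape
# ---------------------------------------------------------------------------

def window_counts(
    calls: pd.DataFrame,
    genome: GenomeSequence,
    window_bp: int = 50_000,
    chroms: list[str] | None = None,
) -> pd.DataFrame:
    """Methylated-site counts per context in non-overlapping windows.

    Windows tile each chromosome ``[1..w], [w+1..2w], ...`` with the
    last window truncated at the chromosome end. Returns one row per
    window with columns ``chrom, start, end, CG, CHG, CHH``; all windows
    are emitted, including empty ones.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    meth = calls.loc[calls["methylated"]]
    frames = []
    for chrom in (chroms if chroms is not None else genome.names):
        L = genome.lengths[chrom]
        n_win = (L + window_bp - 1) // window_bp
        starts = np.arange(n_win, dtype=np.int64) * window_bp + 1
        ends = np.minimum(starts + window_bp - 1, L)
        frame = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
        sub = meth.loc[meth["chrom"] == chrom]
        for ctx in ("CG", "CHG", "CHH"):
            p = sub.loc[sub["context"] == ctx, "pos"].to_numpy()
            frame[ctx] = np.bincount((p - 1) // window_bp, minlength=n_win).astype(np.int64)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# genomic-category tallies
# ---------------------------------------------------------------------------

#: precedence order, low to high: later categories overwrite earlier ones
_CATEGORIES = ("intergenic", "upstream", "intron", "CDS", "UTR")


def categorize_sites(
    calls: pd.DataFrame,
    features: list[FeatureRecord],
    upstream_bp: int = 1000,
    lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Assign every methylated site to exactly one genomic category.

    Categories with precedence UTR > CDS (exon minus UTR) > intron >
    upstream (``upstream_bp`` 5' of the gene start, strand-aware) >
    intergenic. Returns a context x category table of methylated-site
    tallies whose grand total equals the number of methylated input
    sites.
    """
    meth = calls.loc[calls["methylated"]]
    if lengths is None:
        lengths = {}
        for chrom, grp in calls.groupby("chrom"):
            lengths[chrom] = int(grp["pos"].max())
        for f in features:
            lengths[f.chrom] = max(lengths.get(f.chrom, 0), f.end)

    rank = {c: i for i, c in enumerate(_CATEGORIES)}
    masks = {chrom: np.zeros(L, dtype=np.int8) for chrom, L in lengths.items()}

    def paint(chrom: str, start: int, end: int, category: str) -> None:
        if chrom not in masks:
            return
        L = len(masks[chrom])
        lo, hi = max(start, 1), min(end, L)
        if lo > hi:
            return
        seg = masks[chrom][lo - 1:hi]
        np.maximum(seg, rank[category], out=seg)

    # paint in increasing precedence so higher categories overwrite
    for f in features:
        if f.feature_type == "gene":
            if f.strand == "-":
                paint(f.chrom, f.end + 1, f.end + upstream_bp, "upstream")
            else:
                paint(f.chrom, f.start - upstream_bp, f.start - 1, "upstream")
    for f in features:
        if f.feature_type == "intron":
            paint(f.chrom, f.start, f.end, "intron")
    for f in features:
        if f.feature_type == "exon":
            paint(f.chrom, f.start, f.end, "CDS")
    for f in features:
        if f.feature_type in ("five_prime_UTR", "three_prime_UTR"):
            paint(f.chrom, f.start, f.end, "UTR")

    table = pd.DataFrame(0, index=pd.Index(["CG", "CHG", "CHH"], name="context"),
                         columns=list(_CATEGORIES), dtype=np.int64)
    for (chrom, ctx), grp in meth.groupby(["chrom", "context"]):
        if chrom not in masks:
            continue
        codes = masks[chrom][grp["pos"].to_numpy() - 1]
        counts = np.bincount(codes, minlength=len(_CATEGORIES))
        table.loc[ctx] += counts
    return table
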