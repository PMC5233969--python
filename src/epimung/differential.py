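"""Two-sample differential methylation: per-site Fisher tests, windowed
DMR detection, and gene-level tests.

The DMR procedure slides a fixed 200 bp window along each chromosome in
50 bp steps (150 bp overlap), pools corrected methylated/unmethylated
read counts per sample within the window, keeps windows with more than
``min_meth_reads`` methylated reads in at least one sample as
candidates, and calls a window a DMR when a two-sided Fisher's exact
test on the pooled 2x2 table gives p below the threshold (0.01 by
default, uncorrected). Only fully-contained windows are scanned so the
candidate read threshold is comparable across windows.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import FeatureRecord

#: above this table total, switch from exact integer arithmetic to a
#: log-gamma evaluation of the hypergeometric mass
_EXACT_N_MAX = 200
#: tie slack for the float path; gammaln sums carry ~1e-11 relative
#: error at large N, so the slack must comfortably exceed that
_TIE_SLACK = 1e-8


def fisher_two_sided(m1: int, u1: int, m2: int, u2: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[m1, u1], [m2, u2]].

    With margins fixed, sums the probabilities of all tables whose
    hypergeometric probability does not exceed the observed table's.
    Tables with total <= 200 use exact integer arithmetic (ties exact);
    larger tables use a log-gamma evaluation with a tie tolerance
    matched to its numerical accuracy. Raises
    ``ValueError`` on the all-zero table; a table with a zero row or
    column margin has a single admissible outcome and returns 1.0.
    """
    if min(m1, u1, m2, u2) < 0:
        raise ValueError("negative count in contingency table")
    N = m1 + u1 + m2 + u2
    if N == 0:
        raise ValueError("all-zero contingency table")
    n = m1 + u1       # row margin (sample 1 reads)
    K = m1 + m2       # column margin (methylated reads)
    lo, hi = max(0, n - (N - K)), min(n, K)
    if lo == hi:
        return 1.0
    if N <= _EXACT_N_MAX:
        # exact: numerators are integers C(n,k)*C(N-n,K-k); ties exact
        nums = [comb(n, k) * comb(N - n, K - k) for k in range(lo, hi + 1)]
        obs = nums[m1 - lo]
        total = comb(N, K)
        return min(1.0, sum(v for v in nums if v <= obs) / total)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + gammaln(N - n + 1) - gammaln(K - k + 1) - gammaln(N - n - K + k + 1)
        - (gammaln(N + 1) - gammaln(K + 1) - gammaln(N - K + 1))
    )
    pmf = np.exp(logpmf)
    obs = pmf[m1 - lo]
    return float(min(1.0, pmf[pmf <= obs * (1.0 + _TIE_SLACK)].sum()))


def fisher_many(tables: np.ndarray) -> np.ndarray:
    """Vectorized-by-deduplication Fisher p for an (n, 4) array of
    [m1, u1, m2, u2] tables. Repeated tables are computed once."""
    tables = np.asarray(tables, dtype=np.int64)
    uniq, inverse = np.unique(tables, axis=0, return_inverse=True)
    p_uniq = np.array([fisher_two_sided(*row) for row in uniq])
    return p_uniq[inverse.ravel()]


# ---------------------------------------------------------------------------
# per-site tests
# ---------------------------------------------------------------------------

_SITE_KEY = ["chrom", "pos", "strand", "context"]


def per_site_tests(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    p_threshold: float = 0.01,
    use_corrected: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Fisher tests at every site covered in both samples.

    Sites are intersected on (chrom, pos, strand, context) with raw
    depth >= 1 in both samples ("commonly called"); the tested counts
    are corrected by default. Returns the per-site table with columns
    ``m_a, u_a, m_b, u_b, p_value, differential`` plus a summary dict
    ``{"n_common", "n_differential"}``.
    """
    mcol, ucol = ("c_meth", "c_unmeth") if use_corrected else ("n_meth", "n_unmeth")
    cov_a = calls_a.loc[(calls_a["n_meth"] + calls_a["n_unmeth"]) >= 1,
                        _SITE_KEY + [mcol, ucol]]
    cov_b = calls_b.loc[(calls_b["n_meth"] + calls_b["n_unmeth"]) >= 1,
                        _SITE_KEY + [mcol, ucol]]
    merged = cov_a.merge(cov_b, on=_SITE_KEY, suffixes=("_a", "_b"))
    if len(merged) == 0:
        raise ValueError("no commonly covered sites between the two samples")
    merged = merged.rename(columns={
        f"{mcol}_a": "m_a", f"{ucol}_a": "u_a",
        f"{mcol}_b": "m_b", f"{ucol}_b": "u_b",
    })
    tables = merged[["m_a", "u_a", "m_b", "u_b"]].to_numpy()
    merged["p_value"] = fisher_many(tables)
    merged["differential"] = merged["p_value"] < p_threshold
    summary = {
        "n_common": int(len(merged)),
        "n_differential": int(merged["differential"].sum()),
    }
    return merged, summary


# ---------------------------------------------------------------------------
# DMR scan
# ---------------------------------------------------------------------------

def _pool_windows(
    calls: pd.DataFrame,
    chrom: str,
    n_windows: int,
    window_bp: int,
    step_bp: int,
    mcol: str,
    ucol: str,
    context: str | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (meth, unmeth) corrected counts per window for one chrom."""
    sub = calls.loc[calls["chrom"] == chrom]
    if context is not None:
        sub = sub.loc[sub["context"] == context]
    m_sum = np.zeros(n_windows, dtype=np.int64)
    u_sum = np.zeros(n_windows, dtype=np.int64)
    if len(sub) == 0:
        return m_sum, u_sum
    pos = sub["pos"].to_numpy()
    m = sub[mcol].to_numpy()
    u = sub[ucol].to_numpy()
    # window k covers [1 + k*step, window_bp + k*step]
    k_min = np.ceil((pos - window_bp) / step_bp).astype(np.int64)
    k_max = (pos - 1) // step_bp
    for off in range(window_bp // step_bp + 1):
        k = k_min + off
        ok = (k <= k_max) & (k >= 0) & (k < n_windows)
        np.add.at(m_sum, k[ok], m[ok])
        np.add.at(u_sum, k[ok], u[ok])
    return m_sum, u_sum


def dmr_scan(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    lengths: dict[str, int],
    window_bp: int = 200,
    step_bp: int = 50,
    min_meth_reads: int = 5,
    p_threshold: float = 0.01,
    context: str | None = None,
    use_corrected: bool = True,
) -> pd.DataFrame:
    """Windowed DMR detection between two samples.

    Scans fixed-width windows starting at 1, 1+step, ... with
    start <= L - window_bp + 1 (fully contained only). A window is a
    candidate iff its pooled methylated reads strictly exceed
    ``min_meth_reads`` in at least one sample; a candidate is a DMR iff
    the two-sided Fisher p on pooled counts is below ``p_threshold``.
    All three contexts are pooled unless ``context`` is given.

    Returns significant windows with columns ``chrom, start, end, m_a,
    u_a, m_b, u_b, p_value, direction`` (direction by comparing window
    weighted levels: ``hyper_a`` / ``hyper_b`` / ``.`` on ties). Scan
    statistics are in ``result.attrs`` (``n_windows``,
    ``n_candidates``).
    """
    if not (window_bp > step_bp >= 1):
        raise ValueError("require window_bp > step_bp >= 1")
    mcol, ucol = ("c_meth", "c_unmeth") if use_corrected else ("n_meth", "n_unmeth")
    out_frames = []
    n_windows_total = 0
    n_candidates = 0
    for chrom in lengths:
        L = lengths[chrom]
        if L < window_bp:
            continue
        n_windows = (L - window_bp) // step_bp + 1
        n_windows_total += n_windows
        m_a, u_a = _pool_windows(calls_a, chrom, n_windows, window_bp, step_bp, mcol, ucol, context)
        m_b, u_b = _pool_windows(calls_b, chrom, n_windows, window_bp, step_bp, mcol, ucol, context)
        cand = (m_a > min_meth_reads) | (m_b > min_meth_reads)
        n_candidates += int(cand.sum())
        if not cand.any():
            continue
        idx = np.flatnonzero(cand)
        tables = np.stack([m_a[idx], u_a[idx], m_b[idx], u_b[idx]], axis=1)
        p = fisher_many(tables)
        sig = p < p_threshold
        if not sig.any():
            continue
        idx = idx[sig]
        starts = idx * step_bp + 1
        frame = pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + window_bp - 1,
            "m_a": m_a[idx], "u_a": u_a[idx],
            "m_b": m_b[idx], "u_b": u_b[idx],
            "p_value": p[sig],
        })
        with np.errstate(invalid="ignore", divide="ignore"):
            lev_a = frame["m_a"] / (frame["m_a"] + frame["u_a"])
            lev_b = frame["m_b"] / (frame["m_b"] + frame["u_b"])
        frame["direction"] = np.select(
            [lev_a > lev_b, lev_b > lev_a], ["hyper_a", "hyper_b"], default=".")
        out_frames.append(frame)
    if out_frames:
        result = pd.concat(out_frames, ignore_index=True)
    else:
        result = pd.DataFrame(columns=["chrom", "start", "end", "m_a", "u_a",
                                       "m_b", "u_b", "p_value", "direction"])
    result.attrs["n_windows"] = n_windows_total
    result.attrs["n_candidates"] = n_candidates
    return result


def scan_window_pvalues(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    lengths: dict[str, int],
    window_bp: int = 200,
    step_bp: int = 50,
    min_meth_reads: int = 5,
    context: str | None = None,
    use_corrected: bool = True,
) -> np.ndarray:
    """P-values of all candidate windows (for null-rate diagnostics)."""
    mcol, ucol = ("c_meth", "c_unmeth") if use_corrected else ("n_meth", "n_unmeth")
    pvals = []
    for chrom in lengths:
        L = lengths[chrom]
        if L < window_bp:
            continue
        n_windows = (L - window_bp) // step_bp + 1
        m_a, u_a = _pool_windows(calls_a, chrom, n_windows, window_bp, step_bp, mcol, ucol, context)
        m_b, u_b = _pool_windows(calls_b, chrom, n_windows, window_bp, step_bp, mcol, ucol, context)
        cand = (m_a > min_meth_reads) | (m_b > min_meth_reads)
        idx = np.flatnonzero(cand)
        if len(idx) == 0:
            continue
        tables = np.stack([m_a[idx], u_a[idx], m_b[idx], u_b[idx]], axis=1)
        pvals.append(fisher_many(tables))
    return np.concatenate(pvals) if pvals else np.empty(0)


# ---------------------------------------------------------------------------
# gene-level tests
# ---------------------------------------------------------------------------

def gene_differential(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    features: list[FeatureRecord],
    context: str,
    p_threshold: float = 0.01,
    use_corrected: bool = True,
) -> pd.DataFrame:
    """Per-gene differential methylation in one context.

    Pools corrected counts over each gene body in both samples and
    applies the two-sided Fisher test. Genes with zero pooled depth in
    either sample are excluded and counted in
    ``result.attrs['n_excluded']`` (``n_tested + n_excluded`` equals the
    number of gene features).
    """
    from .levels import region_levels

    genes = [f for f in features if f.feature_type == "gene"]
    lev_a = region_levels(calls_a, genes, context=context, use_corrected=use_corrected)
    lev_b = region_levels(calls_b, genes, context=context, use_corrected=use_corrected)
    df = pd.DataFrame({
        "gene_id": lev_a["id"],
        "m_a": lev_a["numerator"],
        "u_a": lev_a["denominator"] - lev_a["numerator"],
        "m_b": lev_b["numerator"],
        "u_b": lev_b["denominator"] - lev_b["numerator"],
        "level_a": lev_a["level"],
        "level_b": lev_b["level"],
    })
    tested = (lev_a["denominator"] > 0) & (lev_b["denominator"] > 0)
    n_excluded = int((~tested).sum())
    df = df.loc[tested.to_numpy()].reset_index(drop=True)
    if len(df):
        df["p_value"] = fisher_many(df[["m_a", "u_a", "m_b", "u_b"]].to_numpy())
    else:
        df["p_value"] = np.empty(0)
    df["differential"] = df["p_value"] < p_threshold
    df.attrs["n_tested"] = int(len(df))
    df.attrs["n_excluded"] = n_excluded
    return df
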