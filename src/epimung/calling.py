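"""Binomial methylation calling with non-conversion calibration.

Bisulfite treatment converts unmethylated cytosines to uracil (read as
T); methylated cytosines stay C. Conversion is imperfect, so a truly
unmethylated site still shows a small fraction of "methylated" reads.
That non-conversion rate ``p_err`` is estimated from the chloroplast
genome, which is essentially unmethylated, as the pooled fraction of
methylated read support over all chloroplast cytosines.

Each covered nuclear site is then tested one-sided against
``X ~ Binomial(n_total, p_err)``: the p-value is the exact upper tail
``P(X >= n_meth)``. P-values are converted to q-values across all
covered sites of a sample (Benjamini-Hochberg by default, Storey
optional), and a site is called methylated iff ``q < q_threshold``.

Read-count correction: reads at significant sites are kept as they are;
at non-significant sites every read is regarded as unmethylated. The
corrected counts conserve total depth and feed all weighted-level
arithmetic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class NonConversionEstimate:
    """Pooled non-conversion rate from an unmethylated control sequence."""

    p_err: float
    n_meth_control: int
    n_total_control: int


def estimate_nonconversion(control_counts: pd.DataFrame) -> NonConversionEstimate:
    """Estimate ``p_err`` as sum(n_meth) / sum(n_meth + n_unmeth) over all
    control-sequence cytosines, all contexts pooled.

    ``control_counts`` must come from the unmethylated control (e.g.
    chloroplast) only; raises ``ValueError`` on zero total depth.
    """
    n_meth = int(control_counts["n_meth"].sum())
    n_total = n_meth + int(control_counts["n_unmeth"].sum())
    if n_total == 0:
        raise ValueError("zero total control depth: cannot estimate non-conversion")
    return NonConversionEstimate(n_meth / n_total, n_meth, n_total)


def binomial_p(n_meth, n_total, p_err: float):
    """Exact one-sided upper-tail binomial p-value ``P(X >= n_meth)``.

    Accepts scalars or numpy arrays. Computed via the regularized
    incomplete beta function (``scipy.stats.binom.sf``), which is an
    exact closed form of the tail sum, not a normal approximation.
    """
    n_meth = np.asarray(n_meth)
    n_total = np.asarray(n_total)
    if np.any(n_meth > n_total):
        raise ValueError("n_meth exceeds n_total")
    if np.any(n_meth < 0) or np.any(n_total < 1):
        raise ValueError("counts out of range")
    if not (0 <= p_err < 1):
        raise ValueError("p_err must be in [0, 1)")
    # P(X >= k) = sf(k - 1); k = 0 gives exactly 1.
    p = stats.binom.sf(n_meth - 1, n_total, p_err)
    if p.ndim == 0:
        return float(p)
    return p


def _storey_qvalues(p: np.ndarray, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate."""
    m = len(p)
    pi0 = min(1.0, (p > lambda_).sum() / ((1.0 - lambda_) * m))
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    ranked = pi0 * p[order] * m / (np.arange(m) + 1)
    # enforce monotonicity from the largest p down
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.clip(q, 0.0, 1.0)


def qvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Convert p-values to q-values; ``method`` is ``"bh"`` or ``"storey"``."""
    p = np.asarray(p, dtype=float)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        return _storey_qvalues(p)
    raise ValueError(f"unknown FDR method {method!r}")


def call_sites(
    sites: pd.DataFrame,
    p_err: float,
    q_threshold: float = 0.01,
    fdr: str = "bh",
) -> pd.DataFrame:
    """Call per-site methylation status for one sample.

    ``sites`` is a CX-report DataFrame (see ``io_formats.CX_COLUMNS``).
    Covered sites (depth >= 1) are tested; q-values are computed jointly
    across all covered sites of all contexts. Zero-coverage sites are
    passed through with ``p = q = 1``, status unmethylated and corrected
    counts (0, 0) — no data, no call.

    Returns the input columns plus ``p_value, q_value, methylated,
    c_meth, c_unmeth`` where the corrected counts follow the rule: keep
    raw counts at significant sites, move all reads to unmethylated at
    non-significant sites. Total depth is conserved per site.
    """
    if len(sites) == 0:
        raise ValueError("empty site table")
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must be in (0, 1)")
    out = sites.copy()
    n_meth = out["n_meth"].to_numpy()
    depth = n_meth + out["n_unmeth"].to_numpy()
    covered = depth >= 1

    p = np.ones(len(out))
    p[covered] = binomial_p(n_meth[covered], depth[covered], p_err)
    q = np.ones(len(out))
    if covered.any():
        q[covered] = qvalues(p[covered], method=fdr)

    methylated = covered & (q < q_threshold)
    out["p_value"] = p
    out["q_value"] = q
    out["methylated"] = methylated
    out["c_meth"] = np.where(methylated, n_meth, 0)
    out["c_unmeth"] = np.where(methylated, out["n_unmeth"].to_numpy(), depth)
    return out


def filter_sites(calls: pd.DataFrame, min_depth: int = 10, min_level: float = 0.9) -> pd.DataFrame:
    """High-confidence site filter: raw depth strictly greater than
    ``min_depth`` and per-site raw level ``n_meth / depth`` strictly
    greater than ``min_level``.

    Both comparisons are strict, so the defaults keep sites with depth
    > 10 supporting > 90% methylation. Note ``min_level = 0`` still
    drops level-0 (fully unmethylated) sites by strictness.
    """
    depth = calls["n_meth"] + calls["n_unmeth"]
    with np.errstate(invalid="ignore"):
        level = np.where(depth > 0, calls["n_meth"] / depth.replace(0, 1), np.nan)
    keep = (depth > min_depth) & (level > min_level)
    return calls.loc[keep.to_numpy(dtype=bool)].reset_index(drop=True)
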