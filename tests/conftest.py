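"""Shared fixtures: a small simulated two-sample dataset and helpers
for building call tables by hand."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import epimung as em
from epimung.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One 60 kb chromosome, 20 genes, 5 planted DMRs, 150 SNPs."""
    cfg = SimulationConfig(
        seed=5, n_chroms=1, chrom_length=60_000, chloroplast_length=20_000,
        n_genes=20, gene_length_min=500, gene_length_max=1500,
        n_tes=5, te_length_min=200, te_length_max=500,
        n_planted_dmrs=5, n_snps=150, n_silenced=1,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_calls(small_dataset):
    """Calls for both samples of the small dataset, with the estimated
    non-conversion rate."""
    est = em.estimate_nonconversion(small_dataset.methylomes.control_a)
    calls_a = em.call_sites(small_dataset.methylomes.sample_a, est.p_err)
    calls_b = em.call_sites(small_dataset.methylomes.sample_b, est.p_err)
    return est, calls_a, calls_b


def make_calls(
    positions,
    n_meth,
    n_unmeth,
    chrom: str = "chr1",
    strand: str = "+",
    context: str = "CG",
    methylated=None,
) -> pd.DataFrame:
    """Hand-built call table; corrected counts mirror the raw counts for
    methylated sites and move all reads to unmethylated otherwise."""
    n = len(positions)
    m = np.broadcast_to(np.asarray(n_meth), (n,)).astype(np.int64)
    u = np.broadcast_to(np.asarray(n_unmeth), (n,)).astype(np.int64)
    if methylated is None:
        methylated = m > 0
    methylated = np.broadcast_to(np.asarray(methylated), (n,)).astype(bool)
    return pd.DataFrame({
        "chrom": chrom,
        "pos": np.asarray(positions, dtype=np.int64),
        "strand": strand,
        "context": context,
        "trinucleotide": "CGT",
        "n_meth": m,
        "n_unmeth": u,
        "p_value": np.where(methylated, 0.0, 1.0),
        "q_value": np.where(methylated, 0.0, 1.0),
        "methylated": methylated,
        "c_meth": np.where(methylated, m, 0),
        "c_unmeth": np.where(methylated, u, m + u),
    })
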