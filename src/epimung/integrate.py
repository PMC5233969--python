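"""Methylation-expression integration.

Relates gene-body methylation to transcript abundance: rank correlation
of gene-body weighted levels with mean expression, the exon-vs-intron
compartment effect (association measured separately in genes methylated
in only one compartment), paralog methylation/expression fold-change
comparison, and case reports for differentially expressed genes whose
expression difference tracks a methylation difference.

All associations are Spearman rank correlations: invariant under
monotone transforms of the heavy-tailed expression scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FeatureRecord
from .levels import region_levels


def gene_summaries(
    calls: pd.DataFrame,
    features: list[FeatureRecord],
    expression: pd.DataFrame,
    sample: str,
    use_corrected: bool = True,
) -> pd.DataFrame:
    """Per-gene methylation and expression summary for one sample.

    Columns: per-context gene-body weighted levels (``level_CG`` etc.,
    NaN when undefined), pooled exon/intron corrected counts and levels
    (all contexts), and ``expression`` = mean abundance over the
    sample's replicates.
    """
    genes = [f for f in features if f.feature_type == "gene"]
    out = pd.DataFrame({"gene_id": [g.id for g in genes]})
    for ctx in ("CG", "CHG", "CHH"):
        lv = region_levels(calls, genes, context=ctx, use_corrected=use_corrected)
        out[f"level_{ctx}"] = lv["level"].to_numpy()
        out[f"num_{ctx}"] = lv["numerator"].to_numpy()
        out[f"den_{ctx}"] = lv["denominator"].to_numpy()
    body = region_levels(calls, genes, context=None, use_corrected=use_corrected)
    out["level_body"] = body["level"].to_numpy()

    by_gene: dict[str, dict[str, list[FeatureRecord]]] = {}
    for f in features:
        if f.feature_type in ("exon", "intron"):
            by_gene.setdefault(f.parent, {}).setdefault(f.feature_type, []).append(f)
    for comp in ("exon", "intron"):
        feats = [f for g in genes for f in by_gene.get(g.id, {}).get(comp, [])]
        lv = region_levels(calls, feats, context=None, use_corrected=use_corrected)
        lv["gene_id"] = [f.parent for f in feats]
        agg = lv.groupby("gene_id")[["numerator", "denominator"]].sum()
        out[f"{comp}_meth"] = out["gene_id"].map(agg["numerator"]).fillna(0).astype(np.int64)
        out[f"{comp}_total"] = out["gene_id"].map(agg["denominator"]).fillna(0).astype(np.int64)
        with np.errstate(invalid="ignore"):
            out[f"{comp}_level"] = np.where(out[f"{comp}_total"] > 0,
                                            out[f"{comp}_meth"] / out[f"{comp}_total"].replace(0, 1),
                                            np.nan)

    expr = expression.loc[expression["sample"] == sample]
    mean_expr = expr.groupby("gene_id")["abundance"].mean()
    out["expression"] = out["gene_id"].map(mean_expr)
    return out


def methylation_expression_association(
    summaries: pd.DataFrame,
    context: str,
    level_column: str | None = None,
    bin_width: float = 0.05,
    min_genes: int = 10,
) -> dict:
    """Spearman association between gene-body methylation and expression.

    Uses ``level_<context>`` (or an explicit ``level_column``) against
    mean expression over genes where both are defined. Also returns a
    binned summary: genes partitioned into methylation-level bins of
    ``bin_width`` with median expression per bin. Raises ``ValueError``
    below ``min_genes`` usable genes.
    """
    col = level_column or f"level_{context}"
    sub = summaries.loc[summaries[col].notna() & summaries["expression"].notna()]
    if len(sub) < min_genes:
        raise ValueError(f"only {len(sub)} genes with defined {col} and expression")
    rho, p = stats.spearmanr(sub[col], sub["expression"])
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    bins = pd.cut(sub[col], bins=edges, include_lowest=True)
    binned = (sub.groupby(bins, observed=True)["expression"]
              .agg(["median", "size"]).reset_index(names="level_bin"))
    return {"rho": float(rho), "p_value": float(p), "n": int(len(sub)), "binned": binned}


def compartment_effect(summaries: pd.DataFrame, min_genes: int = 10) -> dict:
    """Exon-only vs intron-only methylation effect on expression.

    Set E = genes with zero corrected methylated reads in introns and
    more than zero in exons; set I = the converse. For each evaluable
    set, the Spearman association of its compartment level with
    expression is computed; a set below ``min_genes`` is reported as
    not evaluable rather than raising.
    """
    set_e = summaries.loc[(summaries["intron_meth"] == 0) & (summaries["exon_meth"] > 0)]
    set_i = summaries.loc[(summaries["exon_meth"] == 0) & (summaries["intron_meth"] > 0)]
    result: dict = {"n_exon_only": int(len(set_e)), "n_intron_only": int(len(set_i))}
    for key, sub, col in (("exon", set_e, "exon_level"), ("intron", set_i, "intron_level")):
        sub = sub.loc[sub[col].notna() & sub["expression"].notna()]
        if len(sub) < min_genes:
            result[f"rho_{key}"] = None
            result[f"{key}_evaluable"] = False
            continue
        rho, p = stats.spearmanr(sub[col], sub["expression"])
        result[f"rho_{key}"] = float(rho)
        result[f"p_{key}"] = float(p)
        result[f"{key}_evaluable"] = True
    if result.get("rho_exon") is not None and result.get("rho_intron") is not None:
        result["rho_difference"] = result["rho_exon"] - result["rho_intron"]
    else:
        result["rho_difference"] = None
    return result


def paralog_fold_changes(
    pairs: pd.DataFrame,
    summaries: pd.DataFrame,
    context: str = "CG",
    pseudocount: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """log2 fold changes of methylation and expression across paralog
    pairs, and their Spearman correlation.

    Methylation fold change: ``log2((w_a + e) / (w_b + e))`` on the
    ``level_<context>`` of each pair member; expression likewise on
    mean abundance. Pairs with a member missing from the summaries (or
    with undefined level) are skipped and counted in
    ``corr['n_skipped']``. The returned table also carries the raw
    ``w_a`` / ``w_b`` columns (the per-pair scatter of levels).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    col = f"level_{context}"
    lookup = summaries.set_index("gene_id")
    rows = []
    n_skipped = 0
    for pair in pairs.itertuples(index=False):
        if pair.gene_a not in lookup.index or pair.gene_b not in lookup.index:
            n_skipped += 1
            continue
        a, b = lookup.loc[pair.gene_a], lookup.loc[pair.gene_b]
        if np.isnan(a[col]) or np.isnan(b[col]) or np.isnan(a["expression"]) or np.isnan(b["expression"]):
            n_skipped += 1
            continue
        meth_fc = np.log2((a[col] + pseudocount) / (b[col] + pseudocount))
        expr_fc = np.log2((a["expression"] + pseudocount) / (b["expression"] + pseudocount))
        rows.append((pair.gene_a, pair.gene_b, a[col], b[col], meth_fc, expr_fc))
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "w_a", "w_b",
                                        "meth_fold_change", "expr_fold_change"])
    corr: dict = {"n_pairs": int(len(table)), "n_skipped": n_skipped}
    if len(table) >= 3:
        rho, p = stats.spearmanr(table["meth_fold_change"], table["expr_fold_change"])
        corr["rho"] = float(rho)
        corr["p_value"] = float(p)
    else:
        corr["rho"] = None
    return table, corr


def flag_silencing_cases(
    summaries_a: pd.DataFrame,
    summaries_b: pd.DataFrame,
    degs: pd.DataFrame,
    dmrs: pd.DataFrame,
    features: list[FeatureRecord],
    downstream_bp: int = 2000,
) -> pd.DataFrame:
    """Case report for differentially expressed genes (DEGs).

    ``degs`` needs a ``gene_id`` column; DEG calling itself is an
    upstream input. For each DEG the report gives both samples' exon
    methylation levels, whether a DMR overlaps the gene's strand-aware
    downstream window (``downstream_bp`` past the 3' end), and a
    ``silencing_concordant`` flag set when the lower-expressed sample
    has the higher exon methylation or a downstream DMR hypermethylated
    in it. An empty DEG list yields an empty report.
    """
    gene_by_id = {f.id: f for f in features if f.feature_type == "gene"}
    a = summaries_a.set_index("gene_id")
    b = summaries_b.set_index("gene_id")
    rows = []
    for deg in degs.itertuples(index=False):
        gid = deg.gene_id
        if gid not in gene_by_id or gid not in a.index or gid not in b.index:
            continue
        g = gene_by_id[gid]
        exon_a = float(a.loc[gid, "exon_level"])
        exon_b = float(b.loc[gid, "exon_level"])
        expr_a = float(a.loc[gid, "expression"])
        expr_b = float(b.loc[gid, "expression"])
        lower = "a" if expr_a < expr_b else "b"
        if g.strand == "+":
            ds_start, ds_end = g.end + 1, g.end + downstream_bp
        else:
            ds_start, ds_end = g.start - downstream_bp, g.start - 1
        overlap = dmrs.loc[(dmrs["chrom"] == g.chrom)
                           & (dmrs["start"] <= ds_end) & (dmrs["end"] >= ds_start)]
        ds_dmr = len(overlap) > 0
        ds_hyper_lower = bool((overlap["direction"] == f"hyper_{lower}").any()) if ds_dmr else False
        exon_diff = (exon_a > exon_b) if lower == "a" else (exon_b > exon_a)
        exon_known = not (np.isnan(exon_a) or np.isnan(exon_b))
        flag = (exon_known and exon_diff) or ds_hyper_lower
        rows.append((gid, expr_a, expr_b, lower, exon_a, exon_b,
                     ds_dmr, ds_hyper_lower, flag))
    return pd.DataFrame(rows, columns=[
        "gene_id", "expression_a", "expression_b", "lower_expressed",
        "exon_level_a", "exon_level_b", "downstream_dmr",
        "downstream_dmr_hyper_in_lower", "silencing_concordant"])
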