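"""Gene association of housekeeping core promoters and set enrichment.

A gene is associated with a housekeeping core promoter (HK-CP) when one of
its TSSs lies within ``tss_assoc_radius_bp`` (default 300 bp) of the region
center.  Associated genes are split into catalogued housekeeping genes (HKG)
and the remainder (nonHKG), contrasted in expression, and compared by a
hypergeometric over-representation test per functional term with
Benjamini-Hochberg FDR control, followed by a differential fold-change
analysis of the two groups' -log(FDR) profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig

__all__ = [
    "GeneAssociation",
    "map_hkcp_to_genes",
    "expression_summary",
    "term_enrichment",
    "differential_enrichment",
    "significance_symbol",
    "read_gmt",
    "write_gmt",
]

_MAIN_BIOTYPES = ("protein_coding", "lncRNA", "pseudogene")


@dataclass(frozen=True)
class GeneAssociation:
    gene_id: str
    biotype: str
    hkcp_region_ids: tuple
    group: str  # 'HKG' or 'nonHKG'


def significance_symbol(p: float) -> str:
    """Conventional significance symbols: **** <= 1e-4 ... ns > 0.05."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def map_hkcp_to_genes(
    hk_cps: pd.DataFrame,
    tss_table: pd.DataFrame,
    radius_bp: int = 300,
):
    """Associate genes whose TSS lies within ``radius_bp`` of an HK-CP center.

    Returns (associations, biotype_table): a list of
    :class:`GeneAssociation` and a biotype x group count table (protein
    coding / lncRNA / pseudogene / others vs HKG / nonHKG).
    """
    if radius_bp <= 0:
        raise ValueError("radius_bp must be > 0")
    centers = ((hk_cps["start"] + hk_cps["end"]) // 2).to_numpy()
    region_ids = hk_cps["region_id"].to_numpy() if "region_id" in hk_cps.columns else hk_cps.index.to_numpy()
    chroms = hk_cps["chrom"].to_numpy()

    assocs = []
    for gene_id, sub in tss_table.groupby("gene_id"):
        hit_regions = []
        for row in sub.itertuples(index=False):
            on_chrom = chroms == row.chrom
            d = np.abs(centers[on_chrom] - row.tss)
            hits = np.nonzero(d <= radius_bp)[0]
            if hits.size:
                hit_regions.extend(region_ids[on_chrom][hits])
        if hit_regions:
            first = sub.iloc[0]
            group = "HKG" if bool(first.get("is_hkg", False)) else "nonHKG"
            assocs.append(
                GeneAssociation(
                    gene_id=str(gene_id),
                    biotype=str(first["biotype"]),
                    hkcp_region_ids=tuple(sorted(set(map(str, hit_regions)))),
                    group=group,
                )
            )

    table = pd.DataFrame(
        0, index=list(_MAIN_BIOTYPES) + ["others"], columns=["HKG", "nonHKG"]
    )
    for a in assocs:
        biotype = a.biotype if a.biotype in _MAIN_BIOTYPES else "others"
        table.loc[biotype, a.group] += 1
    return assocs, table


def expression_summary(
    tpm: pd.DataFrame,
    gene_groups: pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene mean log-normalized expression and breadth, plus a group test.

    ``tpm`` is genes x samples in TPM; genes with zero TPM everywhere are
    dropped before log-normalization (natural log(TPM+1)).  ``gene_groups``
    maps gene id -> group label (e.g. HKG/nonHKG).  Genes absent from the
    matrix are recorded as missing and excluded from the test.  The group
    comparison is an unpaired two-sided rank-sum test on mean expression.
    """
    expressed = tpm.loc[(tpm > 0).any(axis=1)]
    lognorm = np.log1p(expressed)
    summary = pd.DataFrame(
        {
            "mean_lognorm": lognorm.mean(axis=1),
            "n_cells_expressing": (expressed > 0).sum(axis=1),
        }
    )
    summary["group"] = gene_groups.reindex(summary.index)
    missing = sorted(set(gene_groups.index) - set(summary.index))

    groups = [g for g in pd.unique(gene_groups.dropna()) if g in set(summary["group"])]
    test: dict = {"missing_genes": missing}
    if len(groups) == 2:
        a = summary.loc[summary["group"] == groups[0], "mean_lognorm"]
        b = summary.loc[summary["group"] == groups[1], "mean_lognorm"]
        if len(a) and len(b):
            if a.tolist() == b.tolist():
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            test.update(
                {
                    "groups": (groups[0], groups[1]),
                    "p_value": p,
                    "symbol": significance_symbol(p),
                    "medians": {groups[0]: float(a.median()), groups[1]: float(b.median())},
                }
            )
    return summary, test


def term_enrichment(
    gene_set,
    universe,
    term2genes: dict,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term with BH-FDR.

    Terms are restricted to the universe; the p-value for a term with K
    universe genes, a query of n genes and overlap k is
    P(X >= k | N, K, n).  ``neglog_fdr`` is -log10(FDR).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set) & universe
    n = len(gene_set)
    N = len(universe)
    rows = []
    for term, genes in sorted(term2genes.items()):
        term_genes = set(genes) & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(gene_set & term_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, min(p, 1.0)))
    df = pd.DataFrame(
        rows,
        columns=["term_id", "overlap_count", "set_size", "term_size", "universe_size", "p_value"],
    )
    if len(df):
        df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["fdr"] = np.maximum(df["fdr"], df["p_value"])  # FDR never below p
        df["neglog_fdr"] = -np.log10(df["fdr"].clip(lower=np.finfo(float).tiny))
        df["significant"] = df["fdr"] <= max_fdr
    return df


def differential_enrichment(
    rows_a: pd.DataFrame,
    rows_b: pd.DataFrame,
    min_fold: float = 20.0,
    top_k: int = 10,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Terms whose -log(FDR) differs by at least ``min_fold`` between two sets.

    For terms shared between the two enrichment tables, the fold change is
    max(r_A, r_B)/min(r_A, r_B) with r = -log10(FDR) floored at ``eps``;
    direction marks the side with the larger r.  Results are sorted by
    descending fold change and truncated to ``top_k``.
    """
    a = rows_a.set_index("term_id")["neglog_fdr"]
    b = rows_b.set_index("term_id")["neglog_fdr"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        return pd.DataFrame(
            columns=["term_id", "neglog_fdr_A", "neglog_fdr_B", "fold_change", "direction"]
        )
    ra = np.maximum(a.loc[shared].to_numpy(float), eps)
    rb = np.maximum(b.loc[shared].to_numpy(float), eps)
    fold = np.maximum(ra, rb) / np.minimum(ra, rb)
    out = pd.DataFrame(
        {
            "term_id": shared,
            "neglog_fdr_A": ra,
            "neglog_fdr_B": rb,
            "fold_change": fold,
            "direction": np.where(ra >= rb, "A", "B"),
        }
    )
    out = out[out["fold_change"] >= min_fold]
    out = out.sort_values("fold_change", ascending=False, kind="mergesort").head(top_k)
    return out.reset_index(drop=True)


def read_gmt(path) -> dict:
    """Read a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    term2genes = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term2genes[parts[0]] = [g for g in parts[2:] if g]
    return term2genes


def write_gmt(term2genes: dict, path) -> None:
    with open(path, "w") as fh:
        for term, genes in sorted(term2genes.items()):
            fh.write("\t".join([term, term] + sorted(map(str, genes))) + "\n")
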