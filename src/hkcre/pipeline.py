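"""End-to-end orchestration of the discovery pipeline on a data bundle.

This is the glue the acceptance checks and the CLI run: significance
filtering -> iterative cross-cell merging -> negative-sample construction ->
annotation -> NS-guided filtering -> cluster classification -> gene
association -> cancer activity profiling -> survival stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import annotate_regions, preprocess_histone
from .classify import (
    classify_regions,
    cluster_louvain,
    embed_pca,
    feature_matrix,
    iterative_ns_filter,
)
from .config import PipelineConfig
from .gene_assoc import map_hkcp_to_genes
from .merging import filter_significant, iterative_merge
from .negatives import build_negative_samples
from .survival import (
    activity_profile,
    km_estimate,
    logrank_test,
    prepare_clinical,
    rank_inactive,
    stratify_mean_expression,
    threshold_accounting,
    znorm_by_project,
)

__all__ = ["PipelineResult", "run_pipeline", "run_survival"]


@dataclass
class PipelineResult:
    merged: pd.DataFrame                   # all consensus regions with HK calls
    negative_samples: pd.DataFrame
    annotations: pd.DataFrame              # per-region feature annotations
    ns_annotations: pd.DataFrame
    retained_ids: pd.Index                 # regions surviving the NS filter
    region_classes: pd.DataFrame           # region_id, cluster_id, class_label, retained
    cluster_profiles: pd.DataFrame
    hk_cp_ids: list
    associations: list
    biotype_table: pd.DataFrame
    profiles: pd.DataFrame                 # activity of HK regions in held-out cohorts
    accounting: dict
    inactive_table: pd.DataFrame
    survival: dict = field(default_factory=dict)


def run_pipeline(bundle, config: PipelineConfig | None = None, seed: int = 0) -> PipelineResult:
    """Run the full discovery pipeline on a bundle (synthetic or file-loaded)."""
    cfg = config or PipelineConfig()

    sig = {
        cell: filter_significant(rs, cfg.abc_score_min)
        for cell, rs in bundle.cell_regions.items()
    }
    train = {c: sig[c] for c in bundle.train_cells}
    validate = {c: sig[c] for c in bundle.validate_cells}
    cancer = {c: sig[c] for c in bundle.cancer_cells}

    merged = iterative_merge(train, cfg)
    merged = merged.set_index("region_id", drop=False)

    ns = build_negative_samples(
        list(sig.values()), bundle.chrom_sizes, blacklist=None, config=cfg, seed=seed
    ).df.set_index("region_id", drop=False)

    histone = {
        mark: [preprocess_histone(df) for df in samples.values()]
        for mark, samples in bundle.histone_peaks.items()
    }
    annot = annotate_regions(
        merged[["chrom", "start", "end"]],
        histone_samples=histone,
        tss_table=bundle.tss_table,
        config=cfg,
    )
    annot_ns = annotate_regions(
        ns[["chrom", "start", "end"]],
        histone_samples=histone,
        tss_table=bundle.tss_table,
        config=cfg,
    )

    retained = iterative_ns_filter(annot, annot_ns, cfg)

    kept = annot.loc[retained]
    mat = feature_matrix(kept)
    emb, _ = embed_pca(mat, cfg.n_pcs)
    labels = cluster_louvain(emb, cfg.knn, cfg.louvain_resolution, cfg.rng_seed)

    marks = ["h3k27ac", "h3k4me3", "h3k4me1"]
    profiles = []
    for c in np.unique(labels):
        members = kept.index[labels == c]
        row = {"cluster_id": c, "n": len(members)}
        for m in marks:
            row[m] = float(mat.loc[members, m].mean())
            row[f"{m}_absent"] = bool((kept.loc[members, m] == 0).all())
        row["dntss_bp"] = float(kept.loc[members, "dntss_bp"].median())
        profiles.append(row)
    cluster_profiles = pd.DataFrame(profiles).set_index("cluster_id")
    cluster_labels = classify_regions(cluster_profiles, cfg)

    region_classes = pd.DataFrame(
        {
            "region_id": merged["region_id"],
            "retained": merged.index.isin(retained),
        }
    )
    label_by_region = pd.Series(
        [cluster_labels[c] for c in labels], index=kept.index, name="class_label"
    )
    cluster_by_region = pd.Series(labels, index=kept.index, name="cluster_id")
    region_classes["class_label"] = label_by_region.reindex(region_classes.index)
    region_classes["cluster_id"] = cluster_by_region.reindex(region_classes.index)

    hk_retained = merged.loc[merged.index.isin(retained) & merged["is_hk"]]
    hk_cp_ids = [
        rid for rid in hk_retained.index if label_by_region.get(rid) == "CP"
    ]

    associations, biotype_table = map_hkcp_to_genes(
        merged.loc[hk_cp_ids], bundle.tss_table, cfg.tss_assoc_radius_bp
    )

    act = activity_profile(hk_retained, validate, cancer)
    act["class_label"] = label_by_region.reindex(act.index)
    act_cp = act[act["class_label"] == "CP"]
    accounting = threshold_accounting(act_cp, cfg.hk_fraction)

    assoc_rows = []
    tss_by_gene = bundle.tss_table.set_index("gene_id")
    for a in associations:
        for rid in a.hkcp_region_ids:
            trow = tss_by_gene.loc[a.gene_id]
            if isinstance(trow, pd.DataFrame):
                trow = trow.iloc[0]
            assoc_rows.append((rid, a.gene_id, int(trow["tss"])))
    assoc_df = pd.DataFrame(assoc_rows, columns=["region_id", "gene_id", "tss"])
    inactive = rank_inactive(
        act_cp, assoc_df, bundle.chrom_sizes, 100.0 * cfg.cancer_inactive_frac
    )

    survival = run_survival(bundle, cfg)

    return PipelineResult(
        merged=merged,
        negative_samples=ns,
        annotations=annot,
        ns_annotations=annot_ns,
        retained_ids=retained,
        region_classes=region_classes,
        cluster_profiles=cluster_profiles,
        hk_cp_ids=hk_cp_ids,
        associations=associations,
        biotype_table=biotype_table,
        profiles=act,
        accounting=accounting,
        inactive_table=inactive,
        survival=survival,
    )


def run_survival(bundle, config: PipelineConfig | None = None) -> dict:
    """Joint multi-project survival analysis of the bundle's patient cohorts."""
    cfg = config or PipelineConfig()
    clinical = prepare_clinical(bundle.clinical).set_index("sample_id")
    expr = bundle.tcga_expr.loc[clinical.index]
    z = znorm_by_project(expr, clinical["project"])
    strata = stratify_mean_expression(z, quantile=cfg.strata_quantile)
    times = clinical["overall_survival"].to_numpy(float)
    deceased = clinical["deceased"].to_numpy(bool)
    curves = km_estimate(times, deceased, strata.to_numpy())
    chi2, p = logrank_test(times, deceased, strata.to_numpy())
    return {
        "strata": strata,
        "n_high": int((strata == "HIGH").sum()),
        "n_low": int((strata == "LOW").sum()),
        "km_curves": curves,
        "logrank_chi2": chi2,
        "logrank_p": p,
    }
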