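"""Pipeline configuration.

Every named numeric constant of the discovery pipeline lives here so that a
single flat YAML file fully determines a run.  Defaults are the published
values of the analysis this package implements (ABC-score cutoff 0.015,
20 bp merge gap, 90% housekeeping fraction, 10,000 negative samples, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # --- region quality control and merging ---
    abc_score_min: float = 0.015       # minimum ABC score for a significant CRE-gene row
    hk_fraction: float = 0.90          # a region is housekeeping if active in >= this fraction of cells
    merge_gap_bp: int = 20             # merge raw regions whose gap is <= this many bp

    # --- histone annotation ---
    histone_flank_bp: int = 250        # extension on each flank before peak overlap
    histone_min_overlap_bp: int = 250  # minimum peak/extended-region overlap in bp

    # --- negative samples ---
    ns_count: int = 10_000             # number of negative-sample windows
    ns_length_bp: int = 500            # width of each negative-sample window
    ns_min_gap_bp: int = 3_000         # minimum inter-CRE gap length eligible for sampling
    ns_merge_gapwidth_bp: int = 100    # min gap width when pooling all CREs before gap calling

    # --- other annotations ---
    conservation_halfwidth_bp: int = 500   # fixed window: center +/- halfwidth
    methylation_window_bp: int = 1_000     # concentric CpG window width
    tss_assoc_radius_bp: int = 300         # promoter-gene association radius
    conservation_bp_weighted: bool = False  # unweighted mean over overlapping track rows by default

    # --- NS-guided filtering ---
    ns_suspicious_frac: float = 0.20   # cluster is suspicious if NS fraction exceeds this
    ns_remove_frac: float = 0.50       # sub-cluster regions removed if NS fraction exceeds this
    max_filter_depth: int = 10         # recursion guard for the iterative filter
    n_pcs: int = 3                     # principal components kept for clustering
    knn: int = 15                      # k of the kNN graph fed to Louvain
    louvain_resolution: float = 1.0
    pca_fit_on: str = "pooled"         # 'pooled' (regions+NS) or 'ns' (fit on NS, project regions)

    # --- classification thresholds (discretization of cluster mean z-scores) ---
    z_doubleplus: float = 1.0          # '++' when mean z >= this
    z_plus: float = 0.25               # '+'  when z_plus <= mean z < z_doubleplus
    # '+/-' when |mean z| < z_plus; '-' when mean z <= -z_plus
    distance_bins_bp: tuple = (300, 2_000, 8_000, 15_000)  # very_short/short/intermediate/long/very_long
    distance_category_weight: int = 3  # weight of the distance category in signature matching

    # --- enrichment ---
    enrich_max_fdr: float = 0.05
    enrich_min_fold: float = 20.0
    neglog_base: float = 10.0
    neglog_eps: float = 1e-6           # floor for -log(FDR) ratios

    # --- cancer activity & survival ---
    cancer_inactive_frac: float = 0.35  # "inactive in cancer" analysis threshold
    suppressor_frac: float = 0.20       # stricter suppressor-candidate threshold
    strata_quantile: float = 0.75       # HIGH stratum cut (3rd quartile of mean expression)

    rng_seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "abc_score_min": self.abc_score_min,
            "hk_fraction": self.hk_fraction,
            "ns_suspicious_frac": self.ns_suspicious_frac,
            "ns_remove_frac": self.ns_remove_frac,
            "enrich_max_fdr": self.enrich_max_fdr,
            "cancer_inactive_frac": self.cancer_inactive_frac,
            "suppressor_frac": self.suppressor_frac,
            "strata_quantile": self.strata_quantile,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        bps = {
            "merge_gap_bp": self.merge_gap_bp,
            "histone_flank_bp": self.histone_flank_bp,
            "histone_min_overlap_bp": self.histone_min_overlap_bp,
            "ns_count": self.ns_count,
            "ns_length_bp": self.ns_length_bp,
            "ns_min_gap_bp": self.ns_min_gap_bp,
            "ns_merge_gapwidth_bp": self.ns_merge_gapwidth_bp,
            "conservation_halfwidth_bp": self.conservation_halfwidth_bp,
            "methylation_window_bp": self.methylation_window_bp,
            "tss_assoc_radius_bp": self.tss_assoc_radius_bp,
        }
        for name, value in bps.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.pca_fit_on not in ("pooled", "ns"):
            raise ValueError("pca_fit_on must be 'pooled' or 'ns'")
        self.distance_bins_bp = tuple(self.distance_bins_bp)
        if list(self.distance_bins_bp) != sorted(self.distance_bins_bp):
            raise ValueError("distance_bins_bp must be increasing")

    # --- flat YAML round-trip -------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["distance_bins_bp"] = list(self.distance_bins_bp)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
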