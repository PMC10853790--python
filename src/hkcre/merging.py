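"""Cross-cell-type region merging and housekeeping calling.

The central procedure of the package: candidate cis-regulatory elements
observed independently in many cell types are pooled and merged iteratively.
Each pass merges the remaining raw regions (gap <= ``merge_gap_bp``), selects
the consensus regions supported by the most cell types (first pass: regions
reaching the housekeeping fraction), removes the raw regions they absorb, and
repeats until the pool is empty.  A merged region is *housekeeping* (HK) when
its supporting-cell fraction reaches ``hk_fraction`` (inclusive); all other
regions are cell-type-specific (CTS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import RegionSet, find_overlaps, merge_within

__all__ = [
    "MergedRegion",
    "StabilityRecord",
    "filter_significant",
    "iterative_merge",
    "call_hk",
    "stability_sweep",
    "density_correlation",
]


@dataclass(frozen=True)
class MergedRegion:
    chrom: str
    start: int
    end: int
    supporting_cells: frozenset
    activity_fraction: float
    is_hk: bool

    def __post_init__(self):
        if not 0.0 < self.activity_fraction <= 1.0:
            raise ValueError("activity_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class StabilityRecord:
    n_cells_included: int
    hk_definition_fraction: float
    replicate: int
    n_hk_regions: int
    median_hk_length_bp: float


def filter_significant(raw: RegionSet, abc_score_min: float) -> RegionSet:
    """Drop CRE rows whose ABC score falls below the significance cutoff.

    The boundary is kept: ``score >= abc_score_min`` is retained.
    """
    if "score" not in raw.df.columns:
        raise ValueError("region table has no 'score' column")
    scores = pd.to_numeric(raw.df["score"], errors="coerce")
    if scores.isna().any():
        raise ValueError("region table has missing/non-numeric ABC scores")
    return raw.subset((scores >= abc_score_min).to_numpy())


def iterative_merge(cell_sets: dict, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Iteratively merge per-cell-type region sets into consensus regions.

    Parameters
    ----------
    cell_sets : dict
        Mapping cell-type id -> :class:`RegionSet` (already ABC-filtered).
    config : PipelineConfig
        Supplies ``merge_gap_bp`` and ``hk_fraction``.

    Returns
    -------
    DataFrame with columns chrom, start, end, region_id, cell_types (tuple of
    distinct supporting cell types), n_cells, activity_fraction, is_hk and
    iteration (the pass on which the region was selected).  Output regions
    are pairwise non-overlapping and every raw input region overlaps exactly
    one of them.
    """
    config = config or PipelineConfig()
    n_cells = len(cell_sets)
    frames = []
    for cell_id, rs in cell_sets.items():
        df = rs.df[["chrom", "start", "end"]].copy()
        df["cell_type"] = str(cell_id)
        frames.append(df)
    if not frames or all(len(f) == 0 for f in frames):
        return pd.DataFrame(
            columns=["chrom", "start", "end", "region_id", "cell_types",
                     "n_cells", "activity_fraction", "is_hk", "iteration"]
        )
    pool = pd.concat(frames, ignore_index=True)

    selected_frames = []
    iteration = 0
    while len(pool):
        merged = merge_within(pool, config.merge_gap_bp).df
        counts = merged["n_cell_types"].to_numpy()
        if iteration == 0:
            take = counts / n_cells >= config.hk_fraction
            if not take.any():  # no region reaches the HK bar: fall back to the maximum
                take = counts == counts.max()
        else:
            take = counts == counts.max()
        sel = merged[take].copy()
        sel["iteration"] = iteration
        selected_frames.append(sel)

        # remove raw regions overlapping (>= 1 bp) any selected merged region
        pairs = find_overlaps(pool, sel, min_overlap_bp=1)
        drop = set(pairs[:, 0]) if len(pairs) else set()
        pool = pool.loc[[i for i in pool.index if i not in drop]]
        pool = pool.reset_index(drop=True)
        iteration += 1

    out = pd.concat(selected_frames, ignore_index=True)
    out["cell_types"] = out["cell_types"].map(lambda t: tuple(sorted(set(t))))
    out["n_cells"] = out["cell_types"].map(len)
    out["activity_fraction"] = out["n_cells"] / n_cells
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    out["region_id"] = [f"cre_{i:06d}" for i in range(len(out))]
    out = call_hk(out, config.hk_fraction)
    return out[["chrom", "start", "end", "region_id", "cell_types",
                "n_cells", "activity_fraction", "is_hk", "iteration"]]


def call_hk(merged: pd.DataFrame, hk_fraction: float) -> pd.DataFrame:
    """Set the housekeeping flag: ``is_hk`` iff activity_fraction >= hk_fraction."""
    merged = merged.copy()
    merged["is_hk"] = merged["activity_fraction"] >= hk_fraction
    return merged


def stability_sweep(
    cell_sets: dict,
    fractions=(0.70, 0.80, 0.90, 1.00),
    cell_count_grid=(5, 10, 15, 20),
    n_replicates: int = 3,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """HK-region counts under subsampled cell-type panels and HK definitions.

    For each (n cells, fraction, replicate), draw ``n`` cell types without
    replacement with a per-replicate substream of ``seed``, run the iterative
    merge, and record the number and median length of HK regions.
    """
    config = config or PipelineConfig()
    cells = sorted(cell_sets)
    records = []
    ss = np.random.SeedSequence(seed)
    streams = {}
    for n in cell_count_grid:
        if n > len(cells):
            raise ValueError(f"requested {n} cell types but only {len(cells)} available")
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        for n in cell_count_grid:
            draw = list(rng.choice(cells, size=n, replace=False))
            subset = {c: cell_sets[c] for c in draw}
            for frac in fractions:
                cfg = PipelineConfig(**{**_cfg_dict(config), "hk_fraction": frac})
                merged = iterative_merge(subset, cfg)
                hk = merged[merged["is_hk"]]
                med = float((hk["end"] - hk["start"]).median()) if len(hk) else float("nan")
                records.append(
                    StabilityRecord(n, frac, rep, int(len(hk)), med)
                )
    return pd.DataFrame([r.__dict__ for r in records])


def _cfg_dict(config: PipelineConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)


def density_correlation(
    regions: pd.DataFrame,
    gene_tss: pd.DataFrame,
    bandwidth_bp: float = 1e6,
    chrom_sizes=None,
    n_grid: int = 200,
) -> dict:
    """Correlate the genomic density of region centers with that of gene TSSs.

    A Gaussian kernel of bandwidth ``bandwidth_bp`` is evaluated on a common
    per-chromosome grid for both point sets; the Pearson correlation is
    computed over the concatenated density vectors, and separately over
    per-chromosome point counts (requires >= 2 chromosomes).
    """
    if bandwidth_bp <= 0:
        raise ValueError("bandwidth_bp must be > 0")
    centers = ((regions["start"] + regions["end"]) // 2).to_numpy()
    reg_chrom = regions["chrom"].to_numpy()
    tss_pos = gene_tss["tss"].to_numpy()
    tss_chrom = gene_tss["chrom"].to_numpy()

    chroms = sorted(set(reg_chrom) | set(tss_chrom))
    dens_r, dens_t, curves = [], [], {}
    counts_r, counts_t = [], []
    for chrom in chroms:
        r = centers[reg_chrom == chrom].astype(float)
        t = tss_pos[tss_chrom == chrom].astype(float)
        counts_r.append(len(r))
        counts_t.append(len(t))
        if chrom_sizes is not None and chrom in chrom_sizes:
            lo, hi = 0.0, float(chrom_sizes[chrom])
        else:
            pts = np.concatenate([r, t]) if len(r) + len(t) else np.array([0.0, 1.0])
            lo, hi = pts.min(), pts.max() + 1.0
        grid = np.linspace(lo, hi, n_grid)
        dr = _gaussian_density(r, grid, bandwidth_bp)
        dt = _gaussian_density(t, grid, bandwidth_bp)
        curves[chrom] = pd.DataFrame({"pos": grid, "region_density": dr, "tss_density": dt})
        dens_r.append(dr)
        dens_t.append(dt)

    x = np.concatenate(dens_r)
    y = np.concatenate(dens_t)
    density_r = float(np.corrcoef(x, y)[0, 1])
    if len(chroms) < 2:
        raise ValueError("per-chromosome count correlation needs >= 2 chromosomes")
    count_r = float(np.corrcoef(counts_r, counts_t)[0, 1])
    return {"curves": curves, "density_r": density_r, "count_r": count_r}


def _gaussian_density(points: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    if len(points) == 0:
        return np.zeros_like(grid)
    z = (grid[:, None] - points[None, :]) / bw
    return np.exp(-0.5 * z * z).sum(axis=1) / (len(points) * bw * np.sqrt(2 * np.pi))
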