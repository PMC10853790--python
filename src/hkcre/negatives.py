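"""Negative-sample construction.

Negative samples (NS) are fixed-length windows centered in large gaps between
all known candidate CREs.  They carry no regulatory signal by construction
and serve as the background class for the NS-guided filtering step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import ChromSizes, RegionSet, find_overlaps, gaps, merge_within

__all__ = ["build_negative_samples"]


def build_negative_samples(
    cre_sets,
    chrom_sizes: ChromSizes,
    blacklist: RegionSet | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> RegionSet:
    """Sample ``ns_count`` negative windows from inter-CRE gaps.

    Recipe: (1) pool every supplied CRE set and merge with a minimum gap width
    of ``ns_merge_gapwidth_bp``; (2) take the per-chromosome complement;
    (3) drop gaps touching a chromosome end or intersecting the blacklist
    (centromeres, telomere-adjacent segments); (4) drop gaps shorter than
    ``ns_min_gap_bp``; (5) draw ``ns_count`` gaps uniformly without
    replacement and emit the central ``ns_length_bp`` window of each.

    The 3 kb minimum with a 500 bp central window leaves each window at least
    1,250 bp from the flanking CREs — comfortably clear even after the 250 bp
    histone-annotation extension.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)

    frames = [rs.df[["chrom", "start", "end"]] for rs in cre_sets if len(rs)]
    if not frames:
        raise ValueError("no CRE regions supplied")
    pooled = pd.concat(frames, ignore_index=True)
    merged = merge_within(pooled, config.ns_merge_gapwidth_bp)
    gap_set = gaps(merged, chrom_sizes).df.copy()

    # terminal gaps are unsequenced/low-confidence territory
    at_start = gap_set["start"] == 0
    at_end = gap_set.apply(lambda r: r["end"] == chrom_sizes[r["chrom"]], axis=1)
    gap_set = gap_set[~(at_start | at_end)].reset_index(drop=True)

    if blacklist is not None and len(blacklist):
        pairs = find_overlaps(gap_set, blacklist, min_overlap_bp=1)
        bad = set(pairs[:, 0]) if len(pairs) else set()
        gap_set = gap_set[[i not in bad for i in gap_set.index]].reset_index(drop=True)

    lengths = gap_set["end"] - gap_set["start"]
    gap_set = gap_set[lengths >= config.ns_min_gap_bp].reset_index(drop=True)

    if len(gap_set) < config.ns_count:
        raise ValueError(
            f"only {len(gap_set)} eligible gaps for {config.ns_count} negative samples "
            f"(short by {config.ns_count - len(gap_set)})"
        )
    pick = np.sort(rng.choice(len(gap_set), size=config.ns_count, replace=False))
    chosen = gap_set.iloc[pick].reset_index(drop=True)

    mid = (chosen["start"] + chosen["end"]) // 2  # floor of the midpoint for odd gaps
    ns_start = mid - config.ns_length_bp // 2
    out = pd.DataFrame(
        {
            "chrom": chosen["chrom"],
            "start": ns_start.astype(np.int64),
            "end": (ns_start + config.ns_length_bp).astype(np.int64),
            "region_id": [f"ns_{i:05d}" for i in range(len(chosen))],
            "gap_start": chosen["start"],
            "gap_end": chosen["end"],
        }
    )
    return RegionSet(out)
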