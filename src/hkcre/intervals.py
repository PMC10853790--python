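"""Genomic interval types and brute-force-verifiable interval arithmetic.

All coordinates are internally 0-based half-open (BED convention); readers in
:mod:`hkcre.io` normalize 1-based inclusive inputs on the way in.  Interval
operations are implemented as simple sorted sweeps over numpy arrays so that
their semantics (gap thresholds, overlap lengths, chromosome complements) are
directly auditable against the quadratic oracles used in the test suite.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "ChromSizes",
    "merge_within",
    "find_overlaps",
    "gaps",
]

#: canonical coordinate columns of every region table
CORE_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional metadata.

    ``score`` carries the ABC (activity-by-contact) score when the interval
    originates from a CRE-gene prediction table; ``cell_type`` names the
    sample the interval was observed in.
    """

    chrom: str
    start: int
    end: int
    score: float | None = None
    cell_type: str | None = None
    region_id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        super().__init__(sizes)

    @classmethod
    def from_file(cls, path) -> "ChromSizes":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def to_file(self, path) -> None:
        pd.DataFrame(sorted(self.items()), columns=["chrom", "length"]).to_csv(
            path, sep="\t", header=False, index=False
        )


def _sort_region_frame(df: pd.DataFrame) -> pd.DataFrame:
    keys = ["chrom", "start", "end"]
    if "cell_type" in df.columns:
        keys.append("cell_type")
    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)


class RegionSet:
    """A coordinate-sorted collection of genomic intervals.

    Backed by a :class:`pandas.DataFrame` with at least ``chrom``, ``start``
    and ``end`` columns; arbitrary extra columns (ABC score, target gene,
    supporting cell types, ...) travel with the coordinates.  Iteration
    yields :class:`GenomicInterval` in (chrom, start, end) order, ties broken
    by (end, cell_type) for determinism.
    """

    def __init__(
        self,
        data: pd.DataFrame | Iterable[GenomicInterval],
        convention: str = "bed",
        chrom_sizes: ChromSizes | None = None,
    ):
        if convention != "bed":
            raise ValueError(
                "RegionSet stores 0-based half-open ('bed') coordinates; "
                "convert on read via hkcre.io.read_regions"
            )
        self.convention = convention
        if isinstance(data, pd.DataFrame):
            df = data.copy()
        else:
            df = pd.DataFrame(
                [
                    {
                        "chrom": iv.chrom,
                        "start": iv.start,
                        "end": iv.end,
                        "score": iv.score,
                        "cell_type": iv.cell_type,
                        "region_id": iv.region_id,
                    }
                    for iv in data
                ],
                columns=CORE_COLUMNS + ["score", "cell_type", "region_id"],
            )
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"region table lacks columns {missing}")
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
        if len(bad):
            row = bad.iloc[0]
            raise ValueError(
                f"invalid interval {row['chrom']}:[{row['start']}, {row['end']})"
            )
        if chrom_sizes is not None:
            for chrom, sub in df.groupby("chrom"):
                if chrom not in chrom_sizes:
                    raise ValueError(f"chromosome {chrom} absent from chrom_sizes")
                if int(sub["end"].max()) > chrom_sizes[chrom]:
                    raise ValueError(
                        f"interval on {chrom} extends past its length {chrom_sizes[chrom]}"
                    )
        self.df = _sort_region_frame(df)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        cols = self.df.columns
        for row in self.df.itertuples(index=False):
            d = dict(zip(cols, row))
            yield GenomicInterval(
                d["chrom"],
                int(d["start"]),
                int(d["end"]),
                score=None if pd.isna(d.get("score", None)) else float(d["score"]),
                cell_type=d.get("cell_type") if pd.notna(d.get("cell_type", None)) else None,
                region_id=d.get("region_id") if pd.notna(d.get("region_id", None)) else None,
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        a = self.df[CORE_COLUMNS].reset_index(drop=True)
        b = other.df[CORE_COLUMNS].reset_index(drop=True)
        return a.equals(b)

    @property
    def total_bases(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def subset(self, mask) -> "RegionSet":
        return RegionSet(self.df[mask].reset_index(drop=True))


def _as_frame(regions) -> pd.DataFrame:
    if isinstance(regions, RegionSet):
        return regions.df
    if isinstance(regions, pd.DataFrame):
        return regions
    return RegionSet(regions).df


def merge_within(regions, max_gap_bp: int) -> RegionSet:
    """Merge intervals whose gap is at most ``max_gap_bp`` (transitively).

    Adjacent intervals have gap 0; overlapping intervals have negative gap and
    always merge.  Each output interval records the multiset of contributing
    ``cell_type`` values (``cell_types`` column, sorted tuple), the number of
    distinct contributing cell types (``n_cell_types``) and the number of
    input rows merged (``n_items``).
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be >= 0")
    df = _sort_region_frame(_as_frame(regions))
    if df.empty:
        out = pd.DataFrame(columns=CORE_COLUMNS + ["cell_types", "n_cell_types", "n_items"])
        return RegionSet(out.astype({"start": np.int64, "end": np.int64}, errors="ignore"))

    has_ct = "cell_type" in df.columns
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cts = sub["cell_type"].tolist() if has_ct else [None] * len(sub)
        cur_start, cur_end = int(starts[0]), int(ends[0])
        cur_cts = [cts[0]]
        for s, e, ct in zip(starts[1:], ends[1:], cts[1:]):
            if s - cur_end <= max_gap_bp:  # gap <= threshold -> same cluster
                cur_end = max(cur_end, int(e))
                cur_cts.append(ct)
            else:
                rows.append((chrom, cur_start, cur_end, cur_cts))
                cur_start, cur_end, cur_cts = int(s), int(e), [ct]
        rows.append((chrom, cur_start, cur_end, cur_cts))

    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "_cts"])
    out["cell_types"] = out["_cts"].map(
        lambda lst: tuple(sorted(str(x) for x in lst if x is not None and pd.notna(x)))
    )
    out["n_cell_types"] = out["cell_types"].map(lambda t: len(set(t)))
    out["n_items"] = out["_cts"].map(len)
    out = out.drop(columns="_cts")
    return RegionSet(out)


def find_overlaps(set_a, set_b, min_overlap_bp: int = 1) -> np.ndarray:
    """All index pairs ``(ia, ib)`` with same-chromosome overlap >= ``min_overlap_bp``.

    Indices refer to the row labels of the two input tables.  Sorted-sweep
    implementation; equivalent to the all-pairs quadratic scan.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    a = _as_frame(set_a)
    b = _as_frame(set_b)
    pairs: list[tuple] = []
    if a.empty or b.empty:
        return np.empty((0, 2), dtype=object)
    b_by_chrom = dict(tuple(b.groupby("chrom")))
    for chrom, sub_a in a.groupby("chrom"):
        sub_b = b_by_chrom.get(chrom)
        if sub_b is None:
            continue
        order = np.argsort(sub_b["start"].to_numpy(), kind="mergesort")
        b_start = sub_b["start"].to_numpy()[order]
        b_end = sub_b["end"].to_numpy()[order]
        b_idx = sub_b.index.to_numpy()[order]
        for ia, sa, ea in zip(sub_a.index, sub_a["start"].to_numpy(), sub_a["end"].to_numpy()):
            # candidate B rows must start early enough to reach min_overlap
            hi = np.searchsorted(b_start, ea - min_overlap_bp, side="right")
            if hi == 0:
                continue
            ov = np.minimum(ea, b_end[:hi]) - np.maximum(sa, b_start[:hi])
            hits = np.nonzero(ov >= min_overlap_bp)[0]
            pairs.extend((ia, b_idx[j]) for j in hits)
    if not pairs:
        return np.empty((0, 2), dtype=object)
    return np.array(pairs, dtype=object)


def gaps(regions, chrom_sizes: ChromSizes) -> RegionSet:
    """Complement of a pre-merged region set within each chromosome ``[0, length)``.

    Terminal segments (touching position 0 or the chromosome end) are included
    and can be filtered downstream.  Chromosomes present in ``chrom_sizes``
    but carrying no region yield one full-length gap.
    """
    df = _sort_region_frame(_as_frame(regions))
    for chrom in df["chrom"].unique():
        if chrom not in chrom_sizes:
            raise ValueError(f"no chromosome length supplied for {chrom}")
    rows = []
    grouped = dict(tuple(df.groupby("chrom")))
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        sub = grouped.get(chrom)
        cursor = 0
        if sub is not None:
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                if s < cursor:
                    raise ValueError(
                        f"regions on {chrom} overlap; merge before calling gaps()"
                    )
                if s > cursor:
                    rows.append((chrom, cursor, int(s)))
                cursor = int(e)
        if cursor < length:
            rows.append((chrom, cursor, length))
    out = pd.DataFrame(rows, columns=CORE_COLUMNS)
    if out.empty:
        out = pd.DataFrame({"chrom": pd.Series(dtype=str),
                            "start": pd.Series(dtype=np.int64),
                            "end": pd.Series(dtype=np.int64)})
    return RegionSet(out)
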