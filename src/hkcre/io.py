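"""Readers and writers for BED-like and TSV region tables.

Two input conventions are supported:

* ``"bed"`` — 0-based half-open, the internal convention (no shift on read);
* ``"one-based"`` — 1-based fully-closed (GFF/R style); starts are shifted
  down by one on read and back up on write.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import CORE_COLUMNS, GenomicInterval, RegionSet

__all__ = ["read_regions", "write_regions", "write_bed", "parse_locus"]

_CONVENTIONS = ("bed", "one-based")

# column-name aliases accepted in headered TSV input
_ALIASES = {
    "chrom": {"chrom", "#chrom", "chr", "chromosome", "seqnames"},
    "start": {"start", "chromstart"},
    "end": {"end", "chromend", "stop"},
    "score": {"score", "abc_score", "abc.score", "signal"},
    "cell_type": {"cell_type", "celltype", "cell"},
    "region_id": {"region_id", "name", "id"},
}


def _check_convention(convention: str) -> None:
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}, got {convention!r}")


def parse_locus(text: str, convention: str = "one-based") -> GenomicInterval:
    """Parse a ``chrom:start-end`` locus string into the internal convention."""
    _check_convention(convention)
    m = re.fullmatch(r"([^:]+):([\d,]+)[-–]([\d,]+)", text.strip())
    if m is None:
        raise ValueError(f"cannot parse locus {text!r}")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if convention == "one-based":
        start -= 1
    return GenomicInterval(chrom, start, end)


def _is_headered(first_fields: list[str]) -> bool:
    if len(first_fields) < 3:
        return False
    try:
        int(first_fields[1]), int(first_fields[2])
        return False
    except ValueError:
        return True


def read_regions(path: str | Path, convention: str = "bed") -> RegionSet:
    """Read a BED3+ file or a headered TSV into a sorted :class:`RegionSet`.

    Malformed lines raise with the 1-based line number.  Headered TSVs may
    name columns with common aliases (chrom/chr, start, end/stop, score/
    abc_score, cell_type, region_id/name); extra columns are preserved.
    """
    _check_convention(convention)
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise ValueError(f"{path}: empty file")
    fields = first.rstrip("\n").split("\t")
    headered = _is_headered(fields)

    if headered:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        rename = {}
        for col in df.columns:
            key = col.strip().lower()
            for canonical, names in _ALIASES.items():
                if key in names and canonical not in rename.values():
                    rename[col] = canonical
        df = df.rename(columns=rename)
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: header lacks required columns {missing}")
        offset = 2  # header occupies line 1
    else:
        names = CORE_COLUMNS + ["region_id", "score", "strand"]
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str}, comment="#")
        df.columns = names[: df.shape[1]] + [f"col{j}" for j in range(df.shape[1] - 6)]
        offset = 1

    for col in ("start", "end"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy())[0]
        if bad.size:
            raise ValueError(f"{path}: malformed {col} on line {bad[0] + offset}")
        df[col] = coerced.astype(np.int64)
    if convention == "one-based":
        df["start"] = df["start"] - 1
    invalid = np.nonzero((df["start"].to_numpy() >= df["end"].to_numpy())
                         | (df["start"].to_numpy() < 0))[0]
    if invalid.size:
        raise ValueError(f"{path}: start >= end (or start < 0) on line {invalid[0] + offset}")
    return RegionSet(df)


def write_regions(regions: RegionSet, path: str | Path, convention: str = "bed") -> None:
    """Write a region table as a headered TSV, converting convention on the way out."""
    _check_convention(convention)
    df = regions.df.copy()
    if convention == "one-based":
        df["start"] = df["start"] + 1
    # tuples (e.g. supporting cell types) serialize as comma-joined strings
    for col in df.columns:
        if df[col].map(lambda v: isinstance(v, (tuple, list, set, frozenset))).any():
            df[col] = df[col].map(lambda v: ",".join(map(str, sorted(v))))
    df.to_csv(path, sep="\t", index=False)


def write_bed(regions: RegionSet, path: str | Path, extra_cols: list[str] | None = None) -> None:
    """Write BED3/BED6-style output: chrom, start, end [, name, score, strand | extras]."""
    df = regions.df
    cols = list(CORE_COLUMNS)
    if extra_cols is None:
        if "region_id" in df.columns:
            cols.append("region_id")
        if "score" in df.columns:
            cols.append("score")
    else:
        cols += [c for c in extra_cols if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)
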