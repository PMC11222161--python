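"""Small interval utilities on BED-convention (0-based, half-open) DataFrames.

Every interval table is a pandas DataFrame with at least ``chrom``, ``start``
and ``end`` columns.  Overlap queries go through :mod:`intervaltree`; the
set-algebra helpers (merge, complement, subtract) are thin numpy loops over
per-chromosome sorted arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

INTERVAL_COLS = ["chrom", "start", "end"]


def empty_intervals(extra_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    return pd.DataFrame({c: [] for c in (*INTERVAL_COLS, *extra_cols)}).astype(
        {"start": int, "end": int}, errors="ignore"
    )


def validate_intervals(df: pd.DataFrame, chrom_sizes: dict[str, int] | None = None) -> None:
    """Raise ValueError on malformed intervals (end <= start, out of bounds)."""
    if len(df) == 0:
        return
    if (df["end"] <= df["start"]).any():
        raise ValueError("intervals must satisfy start < end (0-based half-open)")
    if (df["start"] < 0).any():
        raise ValueError("negative interval start")
    if chrom_sizes is not None:
        for chrom, sub in df.groupby("chrom"):
            if chrom not in chrom_sizes:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            if (sub["end"] > chrom_sizes[chrom]).any():
                raise ValueError(f"interval beyond end of {chrom}")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals; touching intervals (end == start) are merged."""
    if len(df) == 0:
        return empty_intervals()
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts, ends = starts[order], ends[order]
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLS)


def complement_intervals(df: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Gaps between the merged input intervals, over every chromosome."""
    merged = merge_intervals(df)
    out = []
    for chrom, size in chrom_sizes.items():
        sub = merged[merged["chrom"] == chrom]
        pos = 0
        for s, e in zip(sub["start"], sub["end"]):
            if s > pos:
                out.append((chrom, pos, min(s, size)))
            pos = max(pos, e)
        if pos < size:
            out.append((chrom, pos, size))
    return pd.DataFrame(out, columns=INTERVAL_COLS)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pieces of ``a`` not covered by ``b`` (a \\ b)."""
    if len(a) == 0:
        return empty_intervals()
    if len(b) == 0:
        return sort_intervals(a[INTERVAL_COLS].copy())
    bm = merge_intervals(b)
    out = []
    for chrom, sub in sort_intervals(a).groupby("chrom", sort=True):
        mask = bm[bm["chrom"] == chrom]
        ms = mask["start"].to_numpy()
        me = mask["end"].to_numpy()
        for s, e in zip(sub["start"], sub["end"]):
            pos = s
            idx = np.searchsorted(me, pos, side="right")
            while idx < len(ms) and ms[idx] < e:
                if ms[idx] > pos:
                    out.append((chrom, pos, ms[idx]))
                pos = max(pos, me[idx])
                idx += 1
            if pos < e:
                out.append((chrom, pos, e))
    return pd.DataFrame(out, columns=INTERVAL_COLS)


def total_length(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 0
    return int((df["end"] - df["start"]).sum())


def build_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), i) for i, (s, e) in zip(sub.index, zip(sub["start"], sub["end"]))
        )
    return trees


def assign_points(points: pd.DataFrame, intervals: pd.DataFrame,
                  pos_col: str = "start") -> list[tuple[int, int]]:
    """(point_row_position, interval_index) pairs for every containment.

    ``interval_index`` is the index label of ``intervals``; a point may hit
    several (overlapping) intervals, or none.
    """
    trees = build_trees(intervals)
    pairs: list[tuple[int, int]] = []
    chroms = points["chrom"].to_numpy()
    pos = points[pos_col].to_numpy()
    for i in range(len(points)):
        tree = trees.get(chroms[i])
        if tree is None:
            continue
        for hit in tree[int(pos[i])]:
            pairs.append((i, hit.data))
    return pairs


def overlaps_any(query: pd.DataFrame, others: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap (>= 1 bp) any interval in others?"""
    trees = build_trees(others)
    out = np.zeros(len(query), dtype=bool)
    for k, (chrom, s, e) in enumerate(zip(query["chrom"], query["start"], query["end"])):
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(int(s), int(e)):
            out[k] = True
    return out


def intersect_length(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total number of bases covered by both a and b."""
    am, bm = merge_intervals(a), merge_intervals(b)
    trees = build_trees(bm)
    total = 0
    for chrom, s, e in zip(am["chrom"], am["start"], am["end"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.overlap(int(s), int(e)):
            total += min(e, hit.end) - max(s, hit.begin)
    return int(total)


def make_tiling_bins(chrom_sizes: dict[str, int], bin_size: int) -> pd.DataFrame:
    """Non-overlapping bins of ``bin_size`` tiling every chromosome."""
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, bin_size)
        ends = np.minimum(starts + bin_size, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)
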