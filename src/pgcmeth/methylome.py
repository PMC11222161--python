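"""Methylation aggregation, element summaries, demethylation rates, escapees.

The atomic unit is the methylation call table: one row per cytosine with
methylated/unmethylated counts (Bismark-coverage style), optionally tagged
with sequence context (CpG/CpA) and allele.  Binned summaries come in two
flavours mirroring the two aggregation rules used throughout:

* per-site averaging (``aggregate_cpg_bins``): mean of per-site %mC over
  sites with depth >= 4, requiring >= 4 qualifying CpGs per bin;
* pooled counting (``aggregate_pooled``): 100 * sum(M) / sum(M+U) with a
  minimum of 10 calls, used for CpA and for sparse allelic data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, build_element_class_map
from .intervals import INTERVAL_COLS, assign_points, build_trees, merge_intervals, sort_intervals

CALL_COLS = ["chrom", "start", "context", "count_meth", "count_unmeth", "allele"]
BIN_COLS = [*INTERVAL_COLS, "mean_5mc", "n_sites", "n_calls", "qc_pass"]

RATE_INTERVALS = ((0, 20), (20, 40), (40, 60), (60, 80), (80, 100))


class EmptyBinsError(ValueError):
    """No bins supplied to an aggregation."""


class MismatchedBinsError(ValueError):
    """Replicate tables are not on identical bin sets."""


class NoPairedBinsError(ValueError):
    """No bin passes QC in both tables of a paired comparison."""


def make_call_table(chrom, start, count_meth, count_unmeth,
                    context="CpG", allele="unphased") -> pd.DataFrame:
    df = pd.DataFrame({
        "chrom": chrom, "start": start,
        "context": context, "allele": allele,
        "count_meth": np.asarray(count_meth, dtype=int),
        "count_unmeth": np.asarray(count_unmeth, dtype=int),
    })
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        raise ValueError("negative methylation counts")
    return df[CALL_COLS]


def _site_bin_pairs(calls: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Long table joining call rows to bin rows (one row per containment)."""
    pairs = assign_points(calls.reset_index(drop=True), bins.reset_index(drop=True))
    if not pairs:
        return pd.DataFrame(columns=["site", "bin"])
    return pd.DataFrame(pairs, columns=["site", "bin"])


def aggregate_cpg_bins(calls: pd.DataFrame, bins: pd.DataFrame,
                       min_depth: int = 4, min_cpgs: int = 4) -> pd.DataFrame:
    """Per-bin average of per-site %mC over CpG sites with depth >= min_depth.

    Bins with fewer than ``min_cpgs`` qualifying sites are flagged
    ``qc_pass=False`` (their mean, where computable, is reported for audit
    but must not be used downstream).
    """
    if len(bins) == 0:
        raise EmptyBinsError("empty bin set")
    cpg = calls[calls["context"] == "CpG"].reset_index(drop=True)
    depth = cpg["count_meth"] + cpg["count_unmeth"]
    cpg = cpg[depth >= min_depth].reset_index(drop=True)
    bins = bins.reset_index(drop=True)
    out = bins[INTERVAL_COLS].copy()
    mean = np.full(len(bins), np.nan)
    n_sites = np.zeros(len(bins), dtype=int)
    n_calls = np.zeros(len(bins), dtype=int)
    if len(cpg):
        pct = 100.0 * cpg["count_meth"] / (cpg["count_meth"] + cpg["count_unmeth"])
        pairs = _site_bin_pairs(cpg, bins)
        if len(pairs):
            grp = pairs.groupby("bin")["site"]
            for b, sites in grp:
                vals = pct.iloc[sites.to_numpy()]
                mean[b] = vals.mean()
                n_sites[b] = len(vals)
                n_calls[b] = int((cpg["count_meth"] + cpg["count_unmeth"]).iloc[sites.to_numpy()].sum())
    out["mean_5mc"] = mean
    out["n_sites"] = n_sites
    out["n_calls"] = n_calls
    out["qc_pass"] = n_sites >= min_cpgs
    return out


def aggregate_pooled(calls: pd.DataFrame, bins: pd.DataFrame,
                     min_calls: int = 10, context: str | None = None) -> pd.DataFrame:
    """Per-bin pooled level 100 * sum(M) / sum(M+U); < min_calls fails QC."""
    if len(bins) == 0:
        raise EmptyBinsError("empty bin set")
    sub = calls if context is None else calls[calls["context"] == context]
    sub = sub.reset_index(drop=True)
    bins = bins.reset_index(drop=True)
    out = bins[INTERVAL_COLS].copy()
    m = np.zeros(len(bins))
    u = np.zeros(len(bins))
    n_sites = np.zeros(len(bins), dtype=int)
    pairs = _site_bin_pairs(sub, bins)
    if len(pairs):
        cm = sub["count_meth"].to_numpy()
        cu = sub["count_unmeth"].to_numpy()
        for b, sites in pairs.groupby("bin")["site"]:
            idx = sites.to_numpy()
            m[b] = cm[idx].sum()
            u[b] = cu[idx].sum()
            n_sites[b] = len(idx)
    total = m + u
    with np.errstate(invalid="ignore"):
        out["mean_5mc"] = np.where(total > 0, 100.0 * m / np.maximum(total, 1), np.nan)
    out["n_sites"] = n_sites
    out["n_calls"] = total.astype(int)
    out["qc_pass"] = total >= min_calls
    return out


def average_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean of replicate bin means; a bin failing QC in any replicate fails."""
    if not tables:
        raise ValueError("no replicate tables")
    first = tables[0]
    for t in tables[1:]:
        if len(t) != len(first) or not (
            t[INTERVAL_COLS].reset_index(drop=True)
            .equals(first[INTERVAL_COLS].reset_index(drop=True))
        ):
            raise MismatchedBinsError("replicates must share an identical bin set")
    out = first[INTERVAL_COLS].reset_index(drop=True).copy()
    means = np.vstack([t["mean_5mc"].to_numpy(dtype=float) for t in tables])
    qc = np.vstack([t["qc_pass"].to_numpy(dtype=bool) for t in tables])
    all_pass = qc.all(axis=0)
    out["mean_5mc"] = np.where(all_pass, np.nanmean(means, axis=0), np.nan)
    out["n_sites"] = np.vstack([t["n_sites"].to_numpy() for t in tables]).min(axis=0)
    out["n_calls"] = np.vstack([t["n_calls"].to_numpy() for t in tables]).sum(axis=0)
    out["qc_pass"] = all_pass
    return out


def summarize_elements(calls: pd.DataFrame, annotation: GenomeAnnotation,
                       class_map: dict[str, pd.DataFrame] | None = None,
                       classes: list[str] | None = None,
                       min_calls: int = 10) -> pd.DataFrame:
    """Pooled 5mC per region class plus a genome-wide row.

    Classes with zero qualifying calls are absent from the output (missing
    is not zero).  Requesting an unknown class label raises KeyError.
    """
    if class_map is None:
        class_map = build_element_class_map(annotation)
    if classes is not None:
        unknown = [c for c in classes if c not in class_map]
        if unknown:
            raise KeyError(f"unknown element class label(s): {unknown}")
        class_map = {c: class_map[c] for c in classes}
    rows = []
    cpg = calls[calls["context"] == "CpG"].reset_index(drop=True)
    cm = cpg["count_meth"].to_numpy()
    cu = cpg["count_unmeth"].to_numpy()
    for label, intervals in class_map.items():
        if len(intervals) == 0:
            continue
        merged = merge_intervals(intervals)
        trees = build_trees(merged)
        mask = np.zeros(len(cpg), dtype=bool)
        chroms = cpg["chrom"].to_numpy()
        pos = cpg["start"].to_numpy()
        for i in range(len(cpg)):
            tree = trees.get(chroms[i])
            if tree is not None and tree[int(pos[i])]:
                mask[i] = True
        m, u = cm[mask].sum(), cu[mask].sum()
        if m + u >= min_calls:
            rows.append((label, 100.0 * m / (m + u), int(mask.sum()), int(m + u)))
    m, u = cm.sum(), cu.sum()
    if m + u >= min_calls:
        rows.append(("genome", 100.0 * m / (m + u), len(cpg), int(m + u)))
    return pd.DataFrame(rows, columns=["element_class", "mean_5mc", "n_sites", "n_calls"])


def demethylation_rate_by_interval(start: pd.DataFrame, end: pd.DataFrame
                                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin rate (m_start - m_end) / m_start, grouped by initial level.

    Bins are paired positionally on (chrom, start, end) and must pass QC in
    both tables; bins starting at 0% are excluded (rate undefined).
    Methylation gain yields a negative rate and is retained with its sign.
    Returns (per_bin, per_interval) tables; intervals are the half-open
    initial-level bands (0,20], (20,40], (40,60], (60,80], (80,100].
    """
    a = sort_intervals(start).reset_index(drop=True)
    b = sort_intervals(end).reset_index(drop=True)
    merged = a.merge(b, on=INTERVAL_COLS, suffixes=("_start", "_end"))
    paired = merged[merged["qc_pass_start"] & merged["qc_pass_end"]
                    & (merged["mean_5mc_start"] > 0)]
    if len(paired) == 0:
        raise NoPairedBinsError("no bin passes QC in both tables")
    ms = paired["mean_5mc_start"].to_numpy()
    me = paired["mean_5mc_end"].to_numpy()
    rate = (ms - me) / ms
    per_bin = paired[INTERVAL_COLS].copy()
    per_bin["m_start"] = ms
    per_bin["m_end"] = me
    per_bin["rate"] = rate
    rows = []
    for lo, hi in RATE_INTERVALS:
        sel = (ms > lo) & (ms <= hi)
        if sel.any():
            rows.append((f"({lo}, {hi}]", float(rate[sel].mean()), int(sel.sum())))
        else:
            rows.append((f"({lo}, {hi}]", np.nan, 0))
    per_interval = pd.DataFrame(rows, columns=["initial_interval", "mean_rate", "n_bins"])
    return per_bin, per_interval


def call_hypermethylated_regions(binmeth: pd.DataFrame, level_threshold: float = 50.0,
                                 max_gap_bins: int = 1, min_bins: int = 3) -> pd.DataFrame:
    """Threshold+gap segmentation of escapee regions from a binned table.

    A bin qualifies when it passes QC and its mean >= level_threshold.  Runs
    of qualifying bins may bridge up to ``max_gap_bins`` consecutive
    non-qualifying (or non-adjacent) bins; a run is kept when it contains at
    least ``min_bins`` qualifying bins.  The reported interval spans the
    first to the last qualifying bin of the run.  This is an explicit
    re-implementation of hypermethylated-region calling as configurable
    segmentation (validated against brute-force enumeration in the tests).
    """
    out = []
    bm = sort_intervals(binmeth).reset_index(drop=True)
    for chrom, sub in bm.groupby("chrom", sort=True):
        sub = sub.reset_index(drop=True)
        qual = (sub["qc_pass"] & (sub["mean_5mc"] >= level_threshold)).to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        run: list[int] = []   # indices of qualifying bins in the current run
        gap = 0
        for i in range(len(sub)):
            if run and starts[i] != ends[i - 1]:
                # non-adjacent bin breaks the run unconditionally
                if len(run) >= min_bins:
                    out.append((chrom, starts[run[0]], ends[run[-1]]))
                run, gap = [], 0
            if qual[i]:
                run.append(i)
                gap = 0
            elif run:
                gap += 1
                if gap > max_gap_bins:
                    if len(run) >= min_bins:
                        out.append((chrom, starts[run[0]], ends[run[-1]]))
                    run, gap = [], 0
        if len(run) >= min_bins:
            out.append((chrom, starts[run[0]], ends[run[-1]]))
    regions = pd.DataFrame(out, columns=INTERVAL_COLS)
    return merge_intervals(regions) if len(regions) else regions


def escapee_overlap_composition(sets: dict[str, pd.DataFrame],
                                annotation: GenomeAnnotation,
                                extra_classes: dict[str, pd.DataFrame] | None = None
                                ) -> dict[str, pd.DataFrame]:
    """Overlap counts between escapee sets plus per-set class composition.

    Overlap counting uses >= 1 bp intersection.  Composition reports, per
    repeat/element class, both the fraction of escapee bases and the fraction
    of escapee regions hitting the class; base fraction is the primary
    readout and an ``other`` row completes base fractions to 1.
    """
    if not sets:
        raise ValueError("at least one escapee set required")
    from .intervals import intersect_length, overlaps_any, total_length

    names = list(sets)
    pair_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            hits_ab = overlaps_any(sets[a], sets[b])
            hits_ba = overlaps_any(sets[b], sets[a])
            pair_rows.append((a, b, int(hits_ab.sum()), int((~hits_ab).sum()),
                              int(hits_ba.sum()), int((~hits_ba).sum())))
    pairwise = pd.DataFrame(pair_rows, columns=[
        "set_a", "set_b", "a_common", "a_specific", "b_common", "b_specific"])

    classes: dict[str, pd.DataFrame] = {}
    if len(annotation.repeats):
        for rclass, sub in annotation.repeats.groupby("repeat_class"):
            classes[f"repeat_{rclass}"] = sub[INTERVAL_COLS]
    if extra_classes:
        classes.update(extra_classes)
    comp_rows = []
    for name in names:
        regions = merge_intervals(sets[name])
        base_total = total_length(regions)
        covered = 0
        for label, ivs in classes.items():
            bases = intersect_length(regions, ivs)
            covered += bases
            n_hit = int(overlaps_any(regions, ivs).sum())
            comp_rows.append((name, label,
                              bases / base_total if base_total else np.nan,
                              n_hit, len(regions)))
        # classes may overlap each other; clamp the remainder at 0
        other = max(base_total - covered, 0)
        comp_rows.append((name, "other",
                          other / base_total if base_total else np.nan,
                          np.nan, len(regions)))
    composition = pd.DataFrame(comp_rows, columns=[
        "set", "element_class", "base_fraction", "n_regions_hit", "n_regions"])
    return {"pairwise": pairwise, "composition": composition}
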