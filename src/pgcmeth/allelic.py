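"""Xa/Xi assignment, allelic methylation summaries, X-gene classes, allele usage.

The active X (Xa) is recognised from allele-resolved methylation of chrX
phasing blocks: on blocks that contain promoters or CpG islands, Xa is the
allele whose pooled promoter+CGI 5mC is at most half the other allele's
("lower by 50%", a relative reading); on blocks with neither feature, Xa is
the allele with the *higher* genome-wide 10-kb-bin 5mC (Xi gene bodies are
hypomethylated relative to Xa).  Only blocks of at least 500 kb qualify, and
blocks meeting neither criterion stay unassigned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, MIN_PHASING_BLOCK_LEN, derive_promoters
from .intervals import INTERVAL_COLS, make_tiling_bins, merge_intervals, subtract_intervals
from .methylome import aggregate_pooled

ALLELES = ("allele1", "allele2")


def _pooled_level(calls: pd.DataFrame, intervals: pd.DataFrame,
                  min_calls: int) -> tuple[float, bool]:
    """Pooled 5mC of the calls within the (merged) interval set."""
    if len(intervals) == 0 or len(calls) == 0:
        return np.nan, False
    one = merge_intervals(intervals)
    # pool across the whole interval set: treat it as a single composite bin
    tab = aggregate_pooled(calls, one, min_calls=0)
    m = (tab["mean_5mc"].fillna(0.0) * tab["n_calls"]).sum()
    calls_total = tab["n_calls"].sum()
    if calls_total < min_calls:
        return np.nan, False
    return float(m / calls_total), True


def summarize_allelic_blocks(calls: pd.DataFrame, annotation: GenomeAnnotation,
                             promoters: pd.DataFrame | None = None,
                             bin_size: int = 10_000,
                             min_calls: int = 10) -> pd.DataFrame:
    """Per-block, per-allele pooled 5mC over promoters+CGIs and 10-kb bins.

    ``calls`` is an allele-tagged CpG call table restricted to chrX.
    Promoters and CGIs are pooled into one statistic per allele.
    """
    if promoters is None:
        promoters = derive_promoters(annotation)
    blocks = annotation.phasing_blocks
    prom_cgi = pd.concat([promoters[INTERVAL_COLS], annotation.cgis[INTERVAL_COLS]],
                         ignore_index=True) if len(annotation.cgis) else promoters[INTERVAL_COLS]
    rows = []
    for _, blk in blocks.iterrows():
        in_block = calls[(calls["chrom"] == blk["chrom"])
                         & (calls["start"] >= blk["start"])
                         & (calls["start"] < blk["end"])]
        feat = prom_cgi[(prom_cgi["chrom"] == blk["chrom"])
                        & (prom_cgi["end"] > blk["start"])
                        & (prom_cgi["start"] < blk["end"])]
        has_feat = len(feat) > 0
        bins = make_tiling_bins({blk["chrom"]: int(blk["end"])}, bin_size)
        bins = bins[bins["start"] >= blk["start"]]
        rec = {"block_id": blk["block_id"], "chrom": blk["chrom"],
               "start": blk["start"], "end": blk["end"],
               "length": blk["end"] - blk["start"],
               "has_promoter_or_cgi": has_feat}
        for allele in ALLELES:
            sub = in_block[in_block["allele"] == allele]
            pc, pc_ok = _pooled_level(sub, feat, min_calls) if has_feat else (np.nan, False)
            gw, gw_ok = _pooled_level(sub, bins, min_calls)
            rec[f"promcgi_5mc_{allele}"] = pc
            rec[f"promcgi_qc_{allele}"] = pc_ok
            rec[f"gw10kb_5mc_{allele}"] = gw
            rec[f"gw10kb_qc_{allele}"] = gw_ok
        rows.append(rec)
    return pd.DataFrame(rows)


def assign_xa_xi(block_summaries: pd.DataFrame,
                 min_block_len: int = MIN_PHASING_BLOCK_LEN) -> pd.DataFrame:
    """Xa/Xi call per phasing block.

    Returns one row per block with ``allele1_call``/``allele2_call`` in
    {Xa, Xi, unassigned}, the criterion used and a reason code for
    unassigned blocks.  Antisymmetric under allele relabelling.
    """
    rows = []
    for _, blk in block_summaries.iterrows():
        call = {a: "unassigned" for a in ALLELES}
        criterion, reason = "none", ""
        if blk["length"] < min_block_len:
            reason = "short_block"
        elif blk["has_promoter_or_cgi"]:
            criterion = "promoter_cgi"
            if not (blk["promcgi_qc_allele1"] and blk["promcgi_qc_allele2"]):
                reason = "missing_promoter_cgi_summary"
            else:
                a1, a2 = blk["promcgi_5mc_allele1"], blk["promcgi_5mc_allele2"]
                if a1 <= 0.5 * a2 and not a2 <= 0.5 * a1:
                    call = {"allele1": "Xa", "allele2": "Xi"}
                elif a2 <= 0.5 * a1 and not a1 <= 0.5 * a2:
                    call = {"allele1": "Xi", "allele2": "Xa"}
                else:
                    reason = "no_allele_meets_50pct_rule"
        else:
            criterion = "gw_10kb"
            if not (blk["gw10kb_qc_allele1"] and blk["gw10kb_qc_allele2"]):
                reason = "missing_gw10kb_summary"
            else:
                g1, g2 = blk["gw10kb_5mc_allele1"], blk["gw10kb_5mc_allele2"]
                if g1 > g2:
                    call = {"allele1": "Xa", "allele2": "Xi"}
                elif g2 > g1:
                    call = {"allele1": "Xi", "allele2": "Xa"}
                else:
                    reason = "tied_gw10kb_levels"
        rows.append({"block_id": blk["block_id"],
                     "allele1_call": call["allele1"],
                     "allele2_call": call["allele2"],
                     "criterion_used": criterion,
                     "reason": reason})
    return pd.DataFrame(rows)


X_GENE_CLASS_THRESHOLD = 50.0


def classify_x_genes(promoter_levels: pd.DataFrame,
                     threshold: float = X_GENE_CLASS_THRESHOLD) -> pd.DataFrame:
    """X-linked gene classes from promoter 5mC on Xa and Xi.

    class 1: >= 50% on both; class 2: < 50% on Xa, >= 50% on Xi;
    class 3: >= 50% on Xa, < 50% on Xi; class 4: < 50% on both.
    Genes with a missing allele level are excluded, not defaulted.
    """
    df = promoter_levels.dropna(subset=["xa_5mc", "xi_5mc"]).copy()
    hi_xa = df["xa_5mc"] >= threshold
    hi_xi = df["xi_5mc"] >= threshold
    df["x_class"] = np.select(
        [hi_xa & hi_xi, ~hi_xa & hi_xi, hi_xa & ~hi_xi],
        [1, 2, 3], default=4)
    return df.reset_index(drop=True)


def allele_usage(umis: pd.DataFrame, min_total_dataset: int = 3,
                 min_total_cell: int = 3) -> tuple[pd.DataFrame, dict]:
    """Per-gene-and-cell Xa allele usage and the group-level Xi fraction.

    Genes whose dataset-wide Xa+Xi UMI total is below ``min_total_dataset``
    are dropped; usage = umi_xa / (umi_xa + umi_xi) is computed only for
    gene x cell entries whose total exceeds 2 (i.e. >= ``min_total_cell``).
    The group Xi fraction is 1 - mean(usage), unweighted across gene x cell.
    """
    if ((umis["umi_xa"] < 0) | (umis["umi_xi"] < 0)).any():
        raise ValueError("negative UMI counts")
    totals = umis.groupby("gene_id")[["umi_xa", "umi_xi"]].sum().sum(axis=1)
    keep_genes = totals[totals >= min_total_dataset].index
    sub = umis[umis["gene_id"].isin(keep_genes)].copy()
    cell_total = sub["umi_xa"] + sub["umi_xi"]
    sub = sub[cell_total >= min_total_cell].copy()
    sub["xa_usage"] = sub["umi_xa"] / (sub["umi_xa"] + sub["umi_xi"])
    mean_usage = float(sub["xa_usage"].mean()) if len(sub) else np.nan
    summary = {"n_genes": int(sub["gene_id"].nunique()),
               "n_entries": int(len(sub)),
               "mean_xa_usage": mean_usage,
               "xi_fraction": 1.0 - mean_usage if len(sub) else np.nan}
    return sub.reset_index(drop=True), summary


def xi_reprogramming_summary(timepoint_calls: dict[str, pd.DataFrame],
                             assignments: pd.DataFrame,
                             annotation: GenomeAnnotation,
                             promoters: pd.DataFrame | None = None,
                             min_calls: int = 10,
                             resistance_tol: float = 3.0) -> pd.DataFrame:
    """Per-timepoint Xa/Xi chromosome-wide, Xi promoter and Xi CGI 5mC.

    ``timepoint_calls`` maps an ordered timepoint label to an allele-tagged
    chrX call table; ``assignments`` is the output of :func:`assign_xa_xi`.
    Unassigned blocks are excluded (their count is reported per row).  The
    ``xi_resistance`` flag is set on the final row when the Xi
    chromosome-wide level moved by less than ``resistance_tol`` percentage
    points between the last two timepoints.
    """
    if promoters is None:
        promoters = derive_promoters(annotation)
    blocks = annotation.phasing_blocks.merge(assignments, on="block_id")
    assigned = blocks[blocks["allele1_call"] != "unassigned"]
    n_excluded = len(blocks) - len(assigned)
    prom = promoters[promoters["chrom"].isin(assigned["chrom"].unique())]
    cgi_nonprom = subtract_intervals(annotation.cgis, prom) \
        if len(annotation.cgis) else annotation.cgis
    rows = []
    for tp, calls in timepoint_calls.items():
        pools: dict[str, pd.DataFrame] = {"Xa": [], "Xi": []}
        for _, blk in assigned.iterrows():
            in_block = calls[(calls["chrom"] == blk["chrom"])
                             & (calls["start"] >= blk["start"])
                             & (calls["start"] < blk["end"])]
            for allele in ALLELES:
                role = blk[f"{allele}_call"]
                pools[role].append(in_block[in_block["allele"] == allele])
        xa = pd.concat(pools["Xa"], ignore_index=True) if pools["Xa"] else calls.iloc[:0]
        xi = pd.concat(pools["Xi"], ignore_index=True) if pools["Xi"] else calls.iloc[:0]
        chrom_ivs = pd.DataFrame(
            [(c, 0, s) for c, s in annotation.chrom_sizes.items() if c == "chrX"],
            columns=INTERVAL_COLS)
        xa_level, _ = _pooled_level(xa, chrom_ivs, min_calls)
        xi_level, _ = _pooled_level(xi, chrom_ivs, min_calls)
        xi_prom, _ = _pooled_level(xi, prom[INTERVAL_COLS], min_calls)
        xi_cgi, _ = _pooled_level(xi, cgi_nonprom, min_calls) \
            if len(cgi_nonprom) else (np.nan, False)
        rows.append({"timepoint": tp, "xa_5mc": xa_level, "xi_5mc": xi_level,
                     "xi_promoter_5mc": xi_prom, "xi_nonprom_cgi_5mc": xi_cgi,
                     "n_blocks_excluded": n_excluded})
    out = pd.DataFrame(rows)
    out["xi_resistance"] = False
    if len(out) >= 2:
        delta = abs(out["xi_5mc"].iloc[-1] - out["xi_5mc"].iloc[-2])
        out.loc[out.index[-1], "xi_resistance"] = bool(delta < resistance_tol)
    return out
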