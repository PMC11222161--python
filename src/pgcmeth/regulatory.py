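"""Regulatory-element categorization, enhancer-gene links, WT/TET1-KO statistics.

Open chromatin sites carry a signal vector of 20 x 200-bp bins (±2 kb of the
summit) per histone mark, as log2 enrichment over input.  Categories are
assigned by explicit mark-threshold rules: active = high H3K4me3 and
H3K27ac; bivalent = high H3K4me3 and H3K27me3; poised = high H3K4me1 with
neither previous rule firing; otherwise silent, with precedence
active > bivalent > poised.  Promoters inherit the category of overlapping
open sites; open sites not overlapping a promoter are enhancers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import INTERVAL_COLS, build_trees
from .methylome import MismatchedBinsError, NoPairedBinsError, average_replicates

MARKS = ("H3K4me3", "H3K27ac", "H3K27me3", "H3K4me1")
N_SIGNAL_BINS = 20  # 20 x 200 bp = +/- 2 kb around the summit
CATEGORIES = ("active", "bivalent", "poised", "silent")
CATEGORY_PRECEDENCE = {"active": 0, "bivalent": 1, "poised": 2, "silent": 3}


class MissingMarkError(ValueError):
    """An element lacks one of the four required mark signals."""


def categorize_open_sites(signals: pd.DataFrame, high_threshold: float = 1.0,
                          central_bins: slice = slice(8, 12)) -> pd.DataFrame:
    """Category per element from its mark signal vectors.

    ``signals`` is long-form: element_id, mark, then 20 bin columns (or a
    single ``signal`` list column).  A mark is "high" when its mean over the
    central bins exceeds ``high_threshold`` (log2 enrichment over input; the
    threshold is declared configuration, not a reconstruction).
    """
    bin_cols = [c for c in signals.columns if c.startswith("bin")]
    if len(bin_cols) != N_SIGNAL_BINS:
        raise ValueError(f"expected {N_SIGNAL_BINS} signal bins, found {len(bin_cols)}")
    rows = []
    for element_id, sub in signals.groupby("element_id", sort=False):
        present = set(sub["mark"])
        missing = [m for m in MARKS if m not in present]
        if missing:
            raise MissingMarkError(f"element {element_id} missing marks {missing}")
        high = {}
        for mark in MARKS:
            vec = sub.loc[sub["mark"] == mark, bin_cols].to_numpy(dtype=float)[0]
            high[mark] = vec[central_bins].mean() > high_threshold
        if high["H3K4me3"] and high["H3K27ac"]:
            cat = "active"
        elif high["H3K4me3"] and high["H3K27me3"]:
            cat = "bivalent"
        elif high["H3K4me1"]:
            cat = "poised"
        else:
            cat = "silent"
        rows.append((element_id, cat))
    return pd.DataFrame(rows, columns=["element_id", "category"])


def label_promoters_enhancers(open_sites: pd.DataFrame,
                              promoters: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split categorized open sites into promoter and enhancer calls.

    A promoter takes the category of any overlapping open site (>= 1 bp);
    on conflicts the precedence is active > bivalent > poised > silent.
    Promoters with no overlapping open site are silent promoters.  Open
    sites overlapping no promoter are enhancers of their own category.
    """
    prom = promoters.reset_index(drop=True).copy()
    sites = open_sites.reset_index(drop=True).copy()
    trees = build_trees(sites)
    prom_cat = ["silent"] * len(prom)
    site_hits_promoter = np.zeros(len(sites), dtype=bool)
    for k, (chrom, s, e) in enumerate(zip(prom["chrom"], prom["start"], prom["end"])):
        tree = trees.get(chrom)
        if tree is None:
            continue
        best = None
        for hit in tree.overlap(int(s), int(e)):
            site_hits_promoter[hit.data] = True
            cat = sites.at[hit.data, "category"]
            if best is None or CATEGORY_PRECEDENCE[cat] < CATEGORY_PRECEDENCE[best]:
                best = cat
        if best is not None:
            prom_cat[k] = best
    prom["category"] = prom_cat
    prom["role"] = "promoter"
    enh = sites[~site_hits_promoter].copy()
    enh["role"] = "enhancer"
    return prom, enh.reset_index(drop=True)


def link_enhancer_genes(enhancers: pd.DataFrame, genes: pd.DataFrame,
                        window: int = 10_000) -> pd.DataFrame:
    """Gene-enhancer pairs with the TSS within ±window of the enhancer."""
    rows = []
    for _, enh in enhancers.iterrows():
        lo = enh["start"] - window
        hi = enh["end"] + window
        hits = genes[(genes["chrom"] == enh["chrom"])
                     & (genes["tss"] >= lo) & (genes["tss"] < hi)]
        for _, g in hits.iterrows():
            rows.append((enh.get("element_id", f"{enh['chrom']}:{enh['start']}"),
                         g["gene_id"], enh["chrom"], enh["start"], enh["end"], g["tss"]))
    return pd.DataFrame(rows, columns=["element_id", "gene_id", "chrom",
                                       "enh_start", "enh_end", "tss"])


def compare_wt_ko_bins(wt: pd.DataFrame, ko_replicates: list[pd.DataFrame],
                       delta: float = 30.0,
                       class_masks: dict[str, np.ndarray] | None = None) -> dict:
    """WT vs KO per-bin 5mC comparison (KO = mean of replicate lines).

    Counts bins with WT - KO >= delta and KO - WT >= delta over bins passing
    QC in WT and every KO replicate; also reports the pooled
    (call-weighted) genome-wide levels/difference and, per optional boolean
    class mask over bins, the per-class pooled difference.
    """
    ko = average_replicates(ko_replicates)
    if len(wt) != len(ko) or not (
        wt[INTERVAL_COLS].reset_index(drop=True)
        .equals(ko[INTERVAL_COLS].reset_index(drop=True))
    ):
        raise MismatchedBinsError("WT and KO tables must share a bin set")
    wt = wt.reset_index(drop=True)
    ok = (wt["qc_pass"] & ko["qc_pass"]).to_numpy()
    if not ok.any():
        raise NoPairedBinsError("no bin passes QC in WT and all KO replicates")
    wt_m = wt["mean_5mc"].to_numpy(dtype=float)
    ko_m = ko["mean_5mc"].to_numpy(dtype=float)
    diff = wt_m - ko_m

    def pooled(mask: np.ndarray) -> tuple[float, float]:
        w = wt["n_calls"].to_numpy(dtype=float)[mask]
        return (float(np.average(wt_m[mask], weights=w)),
                float(np.average(ko_m[mask], weights=w)))

    pw, pk = pooled(ok)
    result = {
        "n_bins": int(ok.sum()),
        "n_wt_higher": int(((diff >= delta) & ok).sum()),
        "n_ko_higher": int(((-diff >= delta) & ok).sum()),
        "pooled_wt": pw,
        "pooled_ko": pk,
        "pooled_delta": pk - pw,   # positive when KO is hypermethylated
        "per_bin": pd.DataFrame({"chrom": wt["chrom"], "start": wt["start"],
                                 "end": wt["end"], "wt_5mc": wt_m, "ko_5mc": ko_m,
                                 "delta": ko_m - wt_m, "qc_pass": ok}),
    }
    if class_masks:
        rows = []
        for label, mask in class_masks.items():
            sel = ok & np.asarray(mask, dtype=bool)
            if sel.any():
                w, k = pooled(sel)
                rows.append((label, k - w, int(sel.sum())))
        result["per_class"] = pd.DataFrame(rows, columns=["element_class", "delta_5mc", "n_bins"])
    return result


def enrichment_odds(foreground: set, universe: set,
                    classes: dict[str, set], fdr_method: str = "fdr_bh") -> pd.DataFrame:
    """Fisher's exact enrichment of the foreground in each class.

    2x2 per class: membership in the foreground x membership in the class,
    over the universe.  Odds ratios of degenerate tables (an empty margin)
    are reported as NaN (undefined), never 0.  q values are BH-adjusted
    across classes.
    """
    fg = set(foreground)
    uni = set(universe)
    if not fg <= uni:
        raise ValueError("foreground must be a subset of the universe")
    rows = []
    for label, members in classes.items():
        cls = set(members) & uni
        a = len(fg & cls)
        b = len(fg - cls)
        c = len(cls - fg)
        d = len(uni) - a - b - c
        table = np.array([[a, b], [c, d]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            odds, p = np.nan, 1.0
        else:
            p = stats.fisher_exact(table, alternative="two-sided")[1]
            odds = (a * d) / (b * c) if b * c > 0 else np.nan
        rows.append((label, a, b, c, d, odds, p))
    out = pd.DataFrame(rows, columns=["class", "n_fg_in", "n_fg_out",
                                      "n_bg_in", "n_bg_out", "odds_ratio", "p_value"])
    out["q_value"] = multipletests(out["p_value"], method=fdr_method)[1]
    return out


def classify_deg_enrichment(deg_up: set, deg_down: set, universe: set,
                            promoter_categories: dict[str, str],
                            er_genes: set) -> dict[str, pd.DataFrame]:
    """Enrichment of promoter categories (and ER genes) in up-/down-DEG sets."""
    classes: dict[str, set] = {
        cat: {g for g, c in promoter_categories.items() if c == cat}
        for cat in CATEGORIES
    }
    classes["er"] = set(er_genes)
    return {
        "up": enrichment_odds(set(deg_up), universe, classes),
        "down": enrichment_odds(set(deg_down), universe, classes),
    }
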