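"""Element categorization, enhancer links, WT/KO statistics, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from pgcmeth.intervals import INTERVAL_COLS
from pgcmeth.methylome import NoPairedBinsError
from pgcmeth.regulatory import (
    MissingMarkError,
    categorize_open_sites,
    classify_deg_enrichment,
    compare_wt_ko_bins,
    enrichment_odds,
    label_promoters_enhancers,
    link_enhancer_genes,
)

BIN_COLS = [f"bin{i:02d}" for i in range(20)]


def signal_table(element_id, high_marks, high=2.0, low=0.1):
    rows = []
    for mark in ("H3K4me3", "H3K27ac", "H3K27me3", "H3K4me1"):
        level = high if mark in high_marks else low
        rows.append({"element_id": element_id, "mark": mark,
                     **{c: level for c in BIN_COLS}})
    return pd.DataFrame(rows)


class TestCategorize:
    @pytest.mark.parametrize("high_marks,expected", [
        (("H3K4me3", "H3K27ac"), "active"),
        (("H3K4me3", "H3K27me3"), "bivalent"),
        (("H3K4me1",), "poised"),
        ((), "silent"),
        (("H3K4me3", "H3K27ac", "H3K27me3"), "active"),   # precedence
        (("H3K4me3", "H3K27me3", "H3K4me1"), "bivalent"),  # precedence
    ])
    def test_rules(self, high_marks, expected):
        out = categorize_open_sites(signal_table("e", high_marks))
        assert out.loc[0, "category"] == expected

    def test_missing_mark_rejected(self):
        sig = signal_table("e", ("H3K4me3",))
        with pytest.raises(MissingMarkError):
            categorize_open_sites(sig[sig["mark"] != "H3K4me1"])

    def test_total_and_deterministic(self):
        rng = np.random.default_rng(0)
        tables = []
        for i in range(30):
            rows = []
            for mark in ("H3K4me3", "H3K27ac", "H3K27me3", "H3K4me1"):
                rows.append({"element_id": f"e{i}", "mark": mark,
                             **{c: rng.normal(0.8, 1.0) for c in BIN_COLS}})
            tables.append(pd.DataFrame(rows))
        sig = pd.concat(tables, ignore_index=True)
        a = categorize_open_sites(sig)
        b = categorize_open_sites(sig)
        assert a["category"].isin(["active", "bivalent", "poised", "silent"]).all()
        assert len(a) == 30
        assert a.equals(b)


class TestLabelPromotersEnhancers:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=[*INTERVAL_COLS, "element_id", "category"])

    def test_promoter_inherits_category(self):
        prom = pd.DataFrame([("chr1", 1_000, 2_300, "gA")],
                            columns=[*INTERVAL_COLS, "gene_id"])
        sites = self._sites([("chr1", 2_200, 2_800, "e1", "bivalent")])
        pcalls, ecalls = label_promoters_enhancers(sites, prom)
        assert pcalls.loc[0, "category"] == "bivalent"
        assert len(ecalls) == 0  # the site overlapped a promoter

    def test_promoter_without_site_is_silent(self):
        prom = pd.DataFrame([("chr1", 1_000, 2_300, "gA")],
                            columns=[*INTERVAL_COLS, "gene_id"])
        pcalls, _ = label_promoters_enhancers(self._sites([]), prom)
        assert pcalls.loc[0, "category"] == "silent"

    def test_site_over_two_promoters_labels_both(self):
        prom = pd.DataFrame([("chr1", 1_000, 2_000, "gA"),
                             ("chr1", 1_900, 3_000, "gB")],
                            columns=[*INTERVAL_COLS, "gene_id"])
        sites = self._sites([("chr1", 1_950, 1_990, "e1", "poised")])
        pcalls, _ = label_promoters_enhancers(sites, prom)
        assert list(pcalls["category"]) == ["poised", "poised"]

    def test_conflicting_sites_take_precedence(self):
        prom = pd.DataFrame([("chr1", 1_000, 3_000, "gA")],
                            columns=[*INTERVAL_COLS, "gene_id"])
        sites = self._sites([("chr1", 1_100, 1_200, "e1", "poised"),
                             ("chr1", 2_100, 2_200, "e2", "active")])
        pcalls, _ = label_promoters_enhancers(sites, prom)
        assert pcalls.loc[0, "category"] == "active"

    def test_distal_site_becomes_enhancer(self):
        prom = pd.DataFrame([("chr1", 1_000, 2_300, "gA")],
                            columns=[*INTERVAL_COLS, "gene_id"])
        sites = self._sites([("chr1", 50_000, 50_600, "e1", "active")])
        _, ecalls = label_promoters_enhancers(sites, prom)
        assert list(ecalls["category"]) == ["active"]
        assert list(ecalls["role"]) == ["enhancer"]


class TestLinkEnhancerGenes:
    def _genes(self, tss_list):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(tss_list))],
                             "chrom": "chr1", "tss": tss_list})

    @pytest.mark.parametrize("tss,linked", [
        (12_000, True),   # 6.8 kb from the enhancer end
        (16_000, False),  # beyond the 10-kb window
        (5_100, True),    # TSS inside the enhancer
    ])
    def test_window_rule(self, tss, linked):
        enh = pd.DataFrame([("chr1", 5_000, 5_200, "e1")],
                           columns=[*INTERVAL_COLS, "element_id"])
        out = link_enhancer_genes(enh, self._genes([tss]))
        assert (len(out) == 1) == linked


def _binmeth(levels, qc=True, n_calls=100):
    n = len(levels)
    df = pd.DataFrame({"chrom": "chr1",
                       "start": np.arange(n) * 2_000,
                       "end": (np.arange(n) + 1) * 2_000})
    df["mean_5mc"] = levels
    df["n_sites"] = 10
    df["n_calls"] = n_calls
    df["qc_pass"] = qc
    return df


class TestCompareWtKo:
    def test_threshold_counting(self):
        wt = _binmeth([10.0, 40.0, 50.0])
        ko = _binmeth([45.0, 69.0, 50.0])   # deltas +35, +29, 0
        res = compare_wt_ko_bins(wt, [ko])
        assert res["n_ko_higher"] == 1
        assert res["n_wt_higher"] == 0

    def test_identical_tables_zero_counts(self):
        wt = _binmeth([10.0, 40.0])
        res = compare_wt_ko_bins(wt, [wt.copy()])
        assert res["n_ko_higher"] == 0 and res["n_wt_higher"] == 0
        assert res["pooled_delta"] == pytest.approx(0.0)

    def test_ko_is_replicate_mean(self):
        wt = _binmeth([10.0])
        ko1, ko2 = _binmeth([50.0]), _binmeth([30.0])  # mean 40 -> delta 30
        res = compare_wt_ko_bins(wt, [ko1, ko2])
        assert res["n_ko_higher"] == 1

    def test_swap_exchangeability(self):
        rng = np.random.default_rng(2)
        wt = _binmeth(rng.uniform(0, 100, 50))
        ko = _binmeth(rng.uniform(0, 100, 50))
        fwd = compare_wt_ko_bins(wt, [ko])
        rev = compare_wt_ko_bins(ko, [wt])
        assert fwd["n_ko_higher"] == rev["n_wt_higher"]
        assert fwd["n_wt_higher"] == rev["n_ko_higher"]

    def test_no_shared_qc_bins_rejected(self):
        wt = _binmeth([10.0], qc=False)
        with pytest.raises(NoPairedBinsError):
            compare_wt_ko_bins(wt, [_binmeth([10.0])])


class TestEnrichmentOdds:
    def test_cross_product_example(self):
        # 2x2 table [[10, 90], [5, 895]] -> OR = (10*895)/(90*5)
        uni = set(range(1_000))
        fg = set(range(100))
        cls = set(range(10)) | set(range(100, 105))
        out = enrichment_odds(fg, uni, {"c": cls})
        assert out.loc[0, "odds_ratio"] == pytest.approx(10 * 895 / (90 * 5))

    def test_foreground_equals_universe_undefined(self):
        uni = set(range(50))
        out = enrichment_odds(uni, uni, {"c": set(range(10))})
        assert np.isnan(out.loc[0, "odds_ratio"])

    def test_foreground_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment_odds({"z"}, {"a", "b"}, {"c": {"a"}})

    @pytest.mark.parametrize("seed", range(5))
    def test_p_matches_hypergeometric_enumeration(self, seed):
        """Two-sided exact significance equals summing hypergeometric point
        probabilities <= the observed one (margins <= 30)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 31))
        uni = set(range(n))
        fg = set(rng.choice(n, int(rng.integers(1, n)), replace=False).tolist())
        cls = set(rng.choice(n, int(rng.integers(1, n)), replace=False).tolist())
        out = enrichment_odds(fg, uni, {"c": cls})
        K, f = len(cls), len(fg)
        a_obs = len(fg & cls)
        pmf = hypergeom(n, K, f).pmf(np.arange(0, min(K, f) + 1))
        p_expected = pmf[pmf <= pmf[a_obs] * (1 + 1e-9)].sum()
        assert out.loc[0, "p_value"] == pytest.approx(p_expected, rel=1e-6)

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(9)
        uni = set(range(500))
        fg = set(rng.choice(500, 80, replace=False).tolist())
        classes = {f"c{i}": set(rng.choice(500, 60, replace=False).tolist())
                   for i in range(6)}
        out = enrichment_odds(fg, uni, classes).sort_values("p_value")
        assert (np.diff(out["q_value"]) >= -1e-12).all()
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()


class TestDegEnrichment:
    def test_bivalent_enriched_degs(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(2_000)]
        cats = {g: ("bivalent" if i % 4 == 0 else "active" if i % 4 == 1
                    else "poised" if i % 4 == 2 else "silent")
                for i, g in enumerate(genes)}
        bivalent = [g for g in genes if cats[g] == "bivalent"]
        others = [g for g in genes if cats[g] != "bivalent"]
        up = set(rng.choice(bivalent, 150, replace=False)) | \
            set(rng.choice(others, 50, replace=False))
        down = set(rng.choice(genes, 200, replace=False))
        out = classify_deg_enrichment(up, down, set(genes), cats, er_genes=set())
        tab = out["up"].set_index("class")
        assert tab.loc["bivalent", "odds_ratio"] > 3
        assert tab.loc["bivalent", "q_value"] < 0.01
        null = out["down"].set_index("class")
        assert abs(np.log(null.loc["bivalent", "odds_ratio"])) < np.log(2)

    def test_er_down_direction_only(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(1_000)]
        er = set(genes[:100])
        down = set(genes[:80]) | set(rng.choice(genes[100:], 40, replace=False))
        up = set(rng.choice(genes[100:], 120, replace=False))
        cats = {g: "active" for g in genes}
        out = classify_deg_enrichment(up, down, set(genes), cats, er)
        assert out["down"].set_index("class").loc["er", "odds_ratio"] > 5
        up_er = out["up"].set_index("class").loc["er", "odds_ratio"]
        assert not (up_er > 1.5)
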