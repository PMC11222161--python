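"""Xa/Xi assignment, X-gene classes, allele usage, Xi reprogramming summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgcmeth.allelic import (
    allele_usage,
    assign_xa_xi,
    classify_x_genes,
    summarize_allelic_blocks,
    xi_reprogramming_summary,
)
from pgcmeth.simulate import ScenarioConfig, simulate_allelic_methylome


def block_row(promcgi=(np.nan, np.nan), gw=(np.nan, np.nan), has_feat=True,
              length=600_000, qc=True):
    return {
        "block_id": "b0", "length": length, "has_promoter_or_cgi": has_feat,
        "promcgi_5mc_allele1": promcgi[0], "promcgi_5mc_allele2": promcgi[1],
        "promcgi_qc_allele1": qc and not np.isnan(promcgi[0]),
        "promcgi_qc_allele2": qc and not np.isnan(promcgi[1]),
        "gw10kb_5mc_allele1": gw[0], "gw10kb_5mc_allele2": gw[1],
        "gw10kb_qc_allele1": not np.isnan(gw[0]) if gw[0] == gw[0] else False,
        "gw10kb_qc_allele2": not np.isnan(gw[1]) if gw[1] == gw[1] else False,
    }


class TestAssignXaXi:
    def test_promoter_cgi_rule(self):
        out = assign_xa_xi(pd.DataFrame([block_row(promcgi=(20.0, 80.0))]))
        assert out.loc[0, "allele1_call"] == "Xa"
        assert out.loc[0, "allele2_call"] == "Xi"
        assert out.loc[0, "criterion_used"] == "promoter_cgi"

    def test_gw_fallback_without_features(self):
        out = assign_xa_xi(pd.DataFrame([
            block_row(gw=(70.0, 60.0), has_feat=False)]))
        assert out.loc[0, "allele1_call"] == "Xa"
        assert out.loc[0, "criterion_used"] == "gw_10kb"

    def test_threshold_not_met_unassigned(self):
        out = assign_xa_xi(pd.DataFrame([block_row(promcgi=(45.0, 50.0))]))
        assert out.loc[0, "allele1_call"] == "unassigned"
        assert out.loc[0, "reason"] == "no_allele_meets_50pct_rule"

    def test_feature_block_never_falls_back_to_gw(self):
        # features present but inconclusive: the 10-kb rule must NOT rescue it
        out = assign_xa_xi(pd.DataFrame([
            block_row(promcgi=(45.0, 50.0), gw=(80.0, 40.0), has_feat=True)]))
        assert out.loc[0, "allele1_call"] == "unassigned"

    def test_short_block_unassigned(self):
        out = assign_xa_xi(pd.DataFrame([
            block_row(promcgi=(20.0, 80.0), length=400_000)]))
        assert out.loc[0, "reason"] == "short_block"

    def test_missing_summary_unassigned_with_reason(self):
        out = assign_xa_xi(pd.DataFrame([block_row(promcgi=(20.0, np.nan))]))
        assert out.loc[0, "allele1_call"] == "unassigned"
        assert out.loc[0, "reason"] == "missing_promoter_cgi_summary"

    @given(a1=st.floats(0, 100), a2=st.floats(0, 100),
           g1=st.floats(0, 100), g2=st.floats(0, 100),
           has_feat=st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_under_allele_swap(self, a1, a2, g1, g2, has_feat):
        fwd = assign_xa_xi(pd.DataFrame([
            block_row(promcgi=(a1, a2), gw=(g1, g2), has_feat=has_feat)]))
        rev = assign_xa_xi(pd.DataFrame([
            block_row(promcgi=(a2, a1), gw=(g2, g1), has_feat=has_feat)]))
        assert fwd.loc[0, "allele1_call"] == rev.loc[0, "allele2_call"]
        assert fwd.loc[0, "allele2_call"] == rev.loc[0, "allele1_call"]


class TestClassifyXGenes:
    @pytest.mark.parametrize("xa,xi,cls", [
        (60.0, 70.0, 1), (20.0, 80.0, 2), (80.0, 20.0, 3), (10.0, 10.0, 4),
        (50.0, 50.0, 1),   # boundary: >= 50 counts as high
    ])
    def test_class_rules(self, xa, xi, cls):
        df = pd.DataFrame({"gene_id": ["g"], "xa_5mc": [xa], "xi_5mc": [xi]})
        assert classify_x_genes(df).loc[0, "x_class"] == cls

    def test_missing_allele_excluded(self):
        df = pd.DataFrame({"gene_id": ["g1", "g2"],
                           "xa_5mc": [60.0, np.nan], "xi_5mc": [70.0, 80.0]})
        out = classify_x_genes(df)
        assert list(out["gene_id"]) == ["g1"]


class TestAlleleUsage:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "cell_id", "umi_xa", "umi_xi"])

    def test_usage_ratio(self):
        umis = self._table([("g", "c", 3, 1)])
        per, summary = allele_usage(umis)
        assert per.loc[0, "xa_usage"] == pytest.approx(0.75)
        assert summary["xi_fraction"] == pytest.approx(0.25)

    def test_total_two_not_computed(self):
        umis = self._table([("g", "c1", 1, 1), ("g", "c2", 2, 1)])
        per, _ = allele_usage(umis)
        assert list(per["cell_id"]) == ["c2"]

    def test_all_xi_zero_usage(self):
        per, _ = allele_usage(self._table([("g", "c", 0, 5)]))
        assert per.loc[0, "xa_usage"] == 0.0

    def test_dataset_total_filter(self):
        umis = self._table([("lowgene", "c1", 1, 1), ("lowgene", "c2", 0, 0),
                            ("kept", "c1", 5, 5)])
        per, _ = allele_usage(umis)
        assert set(per["gene_id"]) == {"kept"}

    def test_binomial_recovery(self):
        """Usage of a gene simulated at Xi fraction f converges to f."""
        rng = np.random.default_rng(8)
        f = 0.3
        totals = rng.poisson(8, 3_000) + 3
        xi = rng.binomial(totals, f)
        umis = pd.DataFrame({"gene_id": "g", "cell_id": np.arange(3_000),
                             "umi_xa": totals - xi, "umi_xi": xi})
        _, summary = allele_usage(umis)
        assert summary["xi_fraction"] == pytest.approx(f, abs=0.02)


class TestAssignmentRecovery:
    def test_recovers_generator_truth_on_all_qualifying_blocks(self, annotation):
        snap = simulate_allelic_methylome(annotation, seed=21)
        summaries = summarize_allelic_blocks(snap["calls"], annotation)
        merged = assign_xa_xi(summaries).merge(snap["xa_truth"], on="block_id")
        qualifying = merged[merged["allele1_call"] != "unassigned"]
        assert len(qualifying) > 0
        called = np.where(qualifying["allele1_call"] == "Xa", "allele1", "allele2")
        assert (called == qualifying["xa_allele"]).all()


class TestXiReprogramming:
    def _run(self, annotation, timepoints):
        sc = ScenarioConfig()
        first = simulate_allelic_methylome(annotation, sc, seed=timepoints[0][1])
        calls = {timepoints[0][0]: first["calls"]}
        for tp, seed in timepoints[1:]:
            # later timepoints share the physical allele identity of the first
            snap = simulate_allelic_methylome(annotation, sc, seed=seed,
                                              xa_truth=first["xa_truth"])
            calls[tp] = snap["calls"]
        summaries = summarize_allelic_blocks(first["calls"], annotation)
        assignments = assign_xa_xi(summaries)
        return xi_reprogramming_summary(calls, assignments, annotation)

    def test_single_timepoint_no_flag(self, annotation):
        out = self._run(annotation, [("t0", 21)])
        assert len(out) == 1
        assert not out["xi_resistance"].any()

    def test_resistant_promoters_stay_high(self, annotation):
        out = self._run(annotation, [("t0", 21), ("t1", 22)])
        # generator keeps Xi promoters/CGIs hypermethylated across snapshots
        assert (out["xi_promoter_5mc"] > 70).all()
        # Xi chromosome-wide stalls between identical-condition snapshots
        assert bool(out["xi_resistance"].iloc[-1])
        # Xa runs well below Xi on promoters; chromosome-wide Xa is higher
        assert (out["xa_5mc"] > out["xi_5mc"]).all()
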