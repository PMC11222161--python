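"""Aggregation rules, element summaries, demethylation rates, escapee calling."""

import numpy as np
import pandas as pd
import pytest

from pgcmeth.intervals import INTERVAL_COLS, make_tiling_bins
from pgcmeth.methylome import (
    EmptyBinsError,
    MismatchedBinsError,
    NoPairedBinsError,
    aggregate_cpg_bins,
    aggregate_pooled,
    average_replicates,
    call_hypermethylated_regions,
    demethylation_rate_by_interval,
    escapee_overlap_composition,
    make_call_table,
    summarize_elements,
)


def bins_df(*triples):
    return pd.DataFrame(triples, columns=INTERVAL_COLS)


ONE_BIN = bins_df(("chr1", 0, 1_000))


def calls_at(percents, depth=10, start=0, step=10):
    pos = start + np.arange(len(percents)) * step
    m = (np.asarray(percents) / 100 * depth).astype(int)
    return make_call_table(["chr1"] * len(pos), pos, m, depth - m)


class TestAggregateCpgBins:
    def test_mean_of_site_percents(self):
        out = aggregate_cpg_bins(calls_at([100, 50, 0, 50]), ONE_BIN)
        assert out.loc[0, "mean_5mc"] == pytest.approx(50.0)
        assert bool(out.loc[0, "qc_pass"])

    def test_three_sites_fail_qc(self):
        out = aggregate_cpg_bins(calls_at([100, 50, 0]), ONE_BIN)
        assert not out.loc[0, "qc_pass"]

    def test_fully_unmethylated(self):
        out = aggregate_cpg_bins(calls_at([0, 0, 0, 0]), ONE_BIN)
        assert out.loc[0, "mean_5mc"] == 0.0

    def test_low_depth_sites_dropped(self):
        shallow = calls_at([100] * 4, depth=3)
        deep = calls_at([0] * 4, depth=4, start=500)
        out = aggregate_cpg_bins(pd.concat([shallow, deep]), ONE_BIN)
        assert out.loc[0, "mean_5mc"] == 0.0
        assert out.loc[0, "n_sites"] == 4

    def test_empty_bins_rejected(self):
        with pytest.raises(EmptyBinsError):
            aggregate_cpg_bins(calls_at([50]), ONE_BIN.iloc[:0])


class TestAggregatePooled:
    def test_pooled_ratio(self):
        calls = make_call_table(["chr1"] * 2, [0, 10], [5, 0], [0, 5])
        out = aggregate_pooled(calls, ONE_BIN)
        assert out.loc[0, "mean_5mc"] == pytest.approx(50.0)

    def test_nine_calls_fail_qc(self):
        calls = make_call_table(["chr1"], [0], [2], [7])
        out = aggregate_pooled(calls, ONE_BIN)
        assert not out.loc[0, "qc_pass"]

    def test_zero_level(self):
        calls = make_call_table(["chr1"], [0], [0], [100])
        out = aggregate_pooled(calls, ONE_BIN)
        assert out.loc[0, "mean_5mc"] == 0.0

    def test_agrees_with_per_site_mean_at_uniform_depth(self):
        calls = calls_at([100, 50, 0, 50, 80, 20], depth=10)
        a = aggregate_cpg_bins(calls, ONE_BIN)
        b = aggregate_pooled(calls, ONE_BIN)
        assert a.loc[0, "mean_5mc"] == pytest.approx(b.loc[0, "mean_5mc"])


class TestAverageReplicates:
    def _table(self, mean, qc=True):
        df = ONE_BIN.copy()
        df["mean_5mc"] = mean
        df["n_sites"] = 5
        df["n_calls"] = 50
        df["qc_pass"] = qc
        return df

    def test_mean_of_replicates(self):
        out = average_replicates([self._table(50.0), self._table(60.0)])
        assert out.loc[0, "mean_5mc"] == pytest.approx(55.0)

    def test_one_failing_replicate_fails_the_bin(self):
        out = average_replicates([self._table(50.0), self._table(60.0, qc=False)])
        assert not out.loc[0, "qc_pass"]

    def test_single_replicate_identity(self):
        out = average_replicates([self._table(42.0)])
        assert out.loc[0, "mean_5mc"] == pytest.approx(42.0)

    def test_mismatched_bins_rejected(self):
        other = self._table(50.0)
        other.loc[0, "start"] = 500
        with pytest.raises(MismatchedBinsError):
            average_replicates([self._table(50.0), other])


class TestSummarizeElements:
    def test_fully_methylated_genome(self, annotation):
        cp = annotation.cpg_positions
        calls = make_call_table(cp["chrom"], cp["pos"],
                                np.full(len(cp), 10), np.zeros(len(cp), dtype=int))
        out = summarize_elements(calls, annotation)
        assert (out["mean_5mc"] == 100.0).all()

    def test_imprint_only_signal_weighted_mean(self, annotation):
        cp = annotation.cpg_positions.reset_index(drop=True)
        from pgcmeth.intervals import assign_points
        hits = {i for i, _ in assign_points(cp, annotation.imprint_dmrs, "pos")}
        m = np.array([5 if i in hits else 0 for i in range(len(cp))])
        calls = make_call_table(cp["chrom"], cp["pos"], m, 10 - m)
        out = summarize_elements(calls, annotation).set_index("element_class")
        assert out.loc["imprint_dmr", "mean_5mc"] == pytest.approx(50.0, abs=1e-9)
        # genome-wide value equals the call-weighted mean computed by hand
        expected = 100.0 * m.sum() / (10 * len(cp))
        assert out.loc["genome", "mean_5mc"] == pytest.approx(expected)

    def test_unknown_class_rejected(self, annotation):
        calls = make_call_table(["chr1"], [100], [1], [1])
        with pytest.raises(KeyError):
            summarize_elements(calls, annotation, classes=["no_such_class"])

    def test_empty_class_absent_not_zero(self, tiny_annotation):
        # calls only inside the CGI; imprint class has no data and no row
        calls = make_call_table(["chr1"] * 2, [1_850, 1_900], [5, 5], [5, 5])
        out = summarize_elements(calls, tiny_annotation)
        assert "imprint_dmr" not in set(out["element_class"])

    def test_partition_conservation(self, annotation):
        """Genome-wide pooled 5mC = call-weighted mean over a genome partition."""
        rng = np.random.default_rng(5)
        cp = annotation.cpg_positions
        m = rng.integers(0, 11, len(cp))
        calls = make_call_table(cp["chrom"], cp["pos"], m, 10 - m)
        partition = make_tiling_bins(annotation.chrom_sizes, 100_000)
        parts = aggregate_pooled(calls, partition, min_calls=0)
        covered = parts["n_calls"] > 0
        weighted = np.average(parts.loc[covered, "mean_5mc"],
                              weights=parts.loc[covered, "n_calls"])
        genome = 100.0 * m.sum() / (10 * len(cp))
        assert weighted == pytest.approx(genome, abs=1e-9)


class TestDemethylationRates:
    def _tables(self, pairs):
        start = bins_df(*[("chr1", i * 1000, (i + 1) * 1000) for i in range(len(pairs))])
        end = start.copy()
        for df, col in ((start, 0), (end, 1)):
            df["mean_5mc"] = [p[col] for p in pairs]
            df["n_sites"] = 10
            df["n_calls"] = 100
            df["qc_pass"] = True
        return start, end

    def test_rate_formula_and_grouping(self):
        start, end = self._tables([(80, 40), (50, 50), (60, 75), (10, 5)])
        per_bin, per_interval = demethylation_rate_by_interval(start, end)
        rates = dict(zip(per_bin["m_start"], per_bin["rate"]))
        assert rates[80] == pytest.approx(0.5)
        assert rates[50] == pytest.approx(0.0)
        assert rates[60] == pytest.approx(-0.25)  # gain retained with sign
        tab = per_interval.set_index("initial_interval")
        # half-open banding: 60 falls in (40,60], 80 in (60,80]
        assert tab.loc["(40, 60]", "n_bins"] == 2
        assert tab.loc["(40, 60]", "mean_rate"] == pytest.approx(-0.125)
        assert tab.loc["(60, 80]", "n_bins"] == 1
        assert tab.loc["(0, 20]", "mean_rate"] == pytest.approx(0.5)

    def test_zero_start_bins_excluded(self):
        start, end = self._tables([(0, 0), (80, 40)])
        per_bin, _ = demethylation_rate_by_interval(start, end)
        assert len(per_bin) == 1

    def test_no_paired_bins_rejected(self):
        start, end = self._tables([(80, 40)])
        start["qc_pass"] = False
        with pytest.raises(NoPairedBinsError):
            demethylation_rate_by_interval(start, end)

    def test_escapees_lower_high_interval_rate(self):
        """Uniform retention gives a flat rate profile; escapees at high
        initial levels depress the (80,100] interval specifically."""
        rng = np.random.default_rng(7)
        init = rng.uniform(5, 100, 200)
        uniform = [(m, m * 0.5) for m in init]                       # retention 0.5
        with_esc = [(m, m * (1.0 if m > 85 and i % 2 else 0.5))     # escapees keep
                    for i, m in enumerate(init)]
        _, flat = demethylation_rate_by_interval(*self._tables(uniform))
        assert flat["mean_rate"].std() == pytest.approx(0.0, abs=1e-12)
        _, esc = demethylation_rate_by_interval(*self._tables(with_esc))
        tab = esc.set_index("initial_interval")["mean_rate"]
        assert tab["(80, 100]"] < tab["(60, 80]"]


def _binmeth_from(levels, qc=None, chrom="chr1", bin_size=1000):
    n = len(levels)
    df = bins_df(*[(chrom, i * bin_size, (i + 1) * bin_size) for i in range(n)])
    df["mean_5mc"] = levels
    df["n_sites"] = 10
    df["n_calls"] = 100
    df["qc_pass"] = True if qc is None else qc
    return df


def brute_force_regions(levels, qc, threshold, max_gap, min_bins, bin_size=1000):
    """Independent oracle: group qualifying bins by pairwise gap, then filter."""
    qual = [i for i, (v, ok) in enumerate(zip(levels, qc)) if ok and v >= threshold]
    groups, current = [], []
    for i in qual:
        if current and i - current[-1] - 1 > max_gap:
            groups.append(current)
            current = []
        current.append(i)
    if current:
        groups.append(current)
    return [(g[0] * bin_size, (g[-1] + 1) * bin_size)
            for g in groups if len(g) >= min_bins]


class TestEscapeeCaller:
    def test_single_stretch(self):
        levels = [10] * 5 + [80] * 5 + [10] * 5
        out = call_hypermethylated_regions(_binmeth_from(levels))
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (5_000, 10_000)

    def test_uniform_low_genome_empty(self):
        out = call_hypermethylated_regions(_binmeth_from([10] * 20))
        assert len(out) == 0

    def test_large_gap_splits_regions(self):
        levels = [80] * 4 + [10] * 3 + [80] * 4
        out = call_hypermethylated_regions(_binmeth_from(levels))
        assert len(out) == 2

    def test_small_gap_bridged(self):
        levels = [80] * 2 + [10] + [80] * 2
        out = call_hypermethylated_regions(_binmeth_from(levels))
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (0, 5_000)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 100))
        levels = rng.uniform(0, 100, n)
        qc = rng.random(n) > 0.15
        threshold, max_gap, min_bins = 50.0, int(rng.integers(0, 3)), int(rng.integers(1, 5))
        got = call_hypermethylated_regions(_binmeth_from(levels, qc),
                                           threshold, max_gap, min_bins)
        expected = brute_force_regions(levels, qc, threshold, max_gap, min_bins)
        assert list(zip(got["start"], got["end"])) == expected


class TestEscapeeOverlap:
    def test_identical_sets_all_common(self, annotation):
        regions = bins_df(("chr1", 0, 5_000), ("chr2", 0, 3_000))
        out = escapee_overlap_composition({"a": regions, "b": regions.copy()},
                                          annotation)
        row = out["pairwise"].iloc[0]
        assert row["a_common"] == 2 and row["a_specific"] == 0
        assert row["b_common"] == 2 and row["b_specific"] == 0

    def test_disjoint_sets_zero_common(self, annotation):
        a = bins_df(("chr1", 0, 1_000))
        b = bins_df(("chr1", 5_000, 6_000))
        out = escapee_overlap_composition({"a": a, "b": b}, annotation)
        assert out["pairwise"].iloc[0]["a_common"] == 0

    def test_base_fraction_oracle(self, tiny_annotation):
        # escapee [5500, 6500) overlaps LINE_young [6000, 6400) by 400 bp
        regions = bins_df(("chr1", 5_500, 6_500))
        out = escapee_overlap_composition({"s": regions}, tiny_annotation)
        comp = out["composition"].set_index("element_class")
        assert comp.loc["repeat_LINE_young", "base_fraction"] == pytest.approx(0.4)
        assert comp.loc["other", "base_fraction"] == pytest.approx(0.6)
        fracs = out["composition"]["base_fraction"]
        assert fracs.sum() == pytest.approx(1.0, abs=1e-9)
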