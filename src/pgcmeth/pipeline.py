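"""End-to-end pipeline over the default synthetic scenario.

Stages run in order (simulate -> aggregate -> elements -> rates -> escapees
-> allelic -> dosage/ER -> KO comparison), each writing one TSV under the
configured output directory plus a run manifest (config hash, seed,
version).  Deterministic given identical configuration: a rerun reproduces
identical result files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .allelic import allele_usage, assign_xa_xi, summarize_allelic_blocks
from .config import PipelineConfig
from .dilution import cohens_d, estimate_per_cycle_rate
from .dosage import classify_er_genes, xa_ratio
from .genome import build_element_class_map, derive_promoters
from .intervals import make_tiling_bins
from .io import write_bed, write_meth_coverage, write_result_tsv
from .methylome import (
    aggregate_cpg_bins,
    call_hypermethylated_regions,
    demethylation_rate_by_interval,
    escapee_overlap_composition,
    summarize_elements,
)
from .regulatory import compare_wt_ko_bins
from .simulate import (
    ScenarioConfig,
    build_toy_genome,
    simulate_allelic_methylome,
    simulate_allelic_umis,
    simulate_cpa_bins,
    simulate_er_dataset,
    simulate_expression,
    simulate_methylome_timecourse,
    simulate_wt_ko_scenario,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def run_pipeline(config: PipelineConfig,
                 scenario: ScenarioConfig | None = None) -> dict:
    """Execute every stage on the synthetic scenario; return the manifest."""
    cfg = config
    scenario = scenario or ScenarioConfig()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {k: v for k, v in cfg.to_dict().items() if k != "outdir"}
    manifest: dict = {
        "stages": [],
        "seed": cfg.seed,
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(thresholds, sort_keys=True).encode()).hexdigest(),
    }

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - abort names the stage
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(name)
        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        state["ann"] = build_toy_genome(scenario, seed=cfg.seed)
        tc = simulate_methylome_timecourse(state["ann"], scenario,
                                           condition=cfg.condition, seed=cfg.seed)
        state["tc"] = tc
        t0, t1 = sorted(tc["calls"])
        write_meth_coverage(tc["calls"][t0], outdir / "calls_start.cov.tsv")
        write_meth_coverage(tc["calls"][t1], outdir / "calls_end.cov.tsv")
        write_result_tsv(tc["truth"], outdir / "truth_trajectory.tsv", thresholds)

    @stage("aggregate")
    def _aggregate():
        ann = state["ann"]
        bins = make_tiling_bins(ann.chrom_sizes, cfg.bin_size_genome)
        t0, t1 = sorted(state["tc"]["calls"])
        state["bm_start"] = aggregate_cpg_bins(
            state["tc"]["calls"][t0], bins, cfg.min_depth, cfg.min_cpgs)
        state["bm_end"] = aggregate_cpg_bins(
            state["tc"]["calls"][t1], bins, cfg.min_depth, cfg.min_cpgs)
        write_result_tsv(state["bm_end"], outdir / "binned_5mc_end.tsv", thresholds)

    @stage("elements")
    def _elements():
        ann = state["ann"]
        state["class_map"] = build_element_class_map(ann)
        t0, t1 = sorted(state["tc"]["calls"])
        summ = summarize_elements(state["tc"]["calls"][t1], ann,
                                  class_map=state["class_map"],
                                  min_calls=cfg.min_calls)
        write_result_tsv(summ, outdir / "element_summary_end.tsv", thresholds)

    @stage("rates")
    def _rates():
        per_bin, per_interval = demethylation_rate_by_interval(
            state["bm_start"], state["bm_end"])
        write_result_tsv(per_interval, outdir / "demethylation_rates.tsv", thresholds)
        spec = (ScenarioConfig().conditions[cfg.condition]
                if cfg.condition in ScenarioConfig().conditions else None)
        if spec is not None:
            qc = state["bm_start"]["qc_pass"] & state["bm_end"]["qc_pass"]
            rate = estimate_per_cycle_rate(
                float(state["bm_start"].loc[qc, "mean_5mc"].mean()),
                float(state["bm_end"].loc[qc, "mean_5mc"].mean()), spec.clock)
            write_result_tsv(pd.DataFrame([{
                "condition": cfg.condition,
                "linear_pct_per_cycle": rate.linear_pct_per_cycle,
                "geometric_retention": rate.geometric_retention,
                "n_cycles": rate.n_cycles}]),
                outdir / "per_cycle_rate.tsv", thresholds)

    @stage("escapees")
    def _escapees():
        regions = call_hypermethylated_regions(
            state["bm_end"], cfg.escapee_level_threshold,
            cfg.escapee_max_gap_bins, cfg.escapee_min_bins)
        state["escapees"] = regions
        write_bed(regions, outdir / "escapees.bed")
        if len(regions):
            comp = escapee_overlap_composition({"end": regions}, state["ann"])
            write_result_tsv(comp["composition"], outdir / "escapee_composition.tsv",
                             thresholds)

    @stage("allelic")
    def _allelic():
        ann = state["ann"]
        snap = simulate_allelic_methylome(ann, ScenarioConfig(), seed=cfg.seed)
        summaries = summarize_allelic_blocks(snap["calls"], ann,
                                             min_calls=cfg.min_calls)
        assignments = assign_xa_xi(summaries)
        state["assignments"] = assignments
        write_result_tsv(assignments.merge(snap["xa_truth"], on="block_id"),
                         outdir / "xa_xi_assignments.tsv", thresholds)
        umis = simulate_allelic_umis(200, 500, ScenarioConfig().xi_transcript_fraction,
                                     seed=cfg.seed)
        _, usage = allele_usage(umis)
        write_result_tsv(pd.DataFrame([usage]), outdir / "allele_usage.tsv", thresholds)

    @stage("dosage_er")
    def _dosage():
        sc = ScenarioConfig()
        rows = []
        for stage_name, scale in sc.xa_scales.items():
            expr, meta = simulate_expression(5_000, 300, scale, seed=cfg.seed)
            res = xa_ratio(expr, meta, expr_cutoff=cfg.expression_cutoff)
            rows.append({"stage": stage_name, "configured_scale": scale, **res})
        write_result_tsv(pd.DataFrame(rows), outdir / "xa_ratios.tsv", thresholds)
        er = simulate_er_dataset(seed=cfg.seed)
        calls = classify_er_genes(er["stage_means"], er["promoter_5mc"],
                                  cfg.er_min_fold, cfg.er_demeth_fraction)
        write_result_tsv(calls, outdir / "er_calls.tsv", thresholds, index=True)

    @stage("ko_compare")
    def _ko():
        sim = simulate_wt_ko_scenario(ScenarioConfig(), seed=cfg.seed)
        from .methylome import aggregate_pooled
        wt = aggregate_pooled(sim["wt_calls"], sim["bins"], cfg.min_calls)
        kos = [aggregate_pooled(k, sim["bins"], cfg.min_calls)
               for k in sim["ko_calls"]]
        res = compare_wt_ko_bins(wt, kos, delta=cfg.ko_delta,
                                 class_masks=sim["class_masks"])
        summary = pd.DataFrame([{
            "pooled_delta": res["pooled_delta"],
            "n_wt_higher": res["n_wt_higher"],
            "n_ko_higher": res["n_ko_higher"],
            "n_bins": res["n_bins"]}])
        write_result_tsv(summary, outdir / "ko_comparison.tsv", thresholds)
        write_result_tsv(res["per_class"], outdir / "ko_per_class.tsv", thresholds)
        cpa = simulate_cpa_bins(ScenarioConfig(), seed=cfg.seed)
        d = cohens_d(cpa["bmp_minus"], cpa["bmp_plus"])
        write_result_tsv(pd.DataFrame([{"cohens_d_cpa": d}]),
                         outdir / "cpa_effect_size.tsv", thresholds)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
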