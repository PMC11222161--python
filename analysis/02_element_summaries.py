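"""Per-element-class 5mC summaries at the start and end of differentiation.

Reads the simulated BMP/M1 time course (run 01 first), aggregates CpG calls
into 10-kb bins and per region class (HCP/ICP/LCP promoters, CGIs, exons,
introns, intergenes, repeat classes, imprint DMRs), and writes the summary
tables that correspond to per-element violin-plot panels.
"""

from pathlib import Path

from pgcmeth.genome import build_element_class_map
from pgcmeth.intervals import make_tiling_bins
from pgcmeth.io import read_meth_coverage, write_result_tsv
from pgcmeth.methylome import aggregate_cpg_bins, summarize_elements
from pgcmeth.simulate import ScenarioConfig, build_toy_genome

OUT = Path("results/analysis")
SEED = 20240501


def main() -> None:
    scenario = ScenarioConfig()
    ann = build_toy_genome(scenario, seed=SEED)
    class_map = build_element_class_map(ann)
    bins = make_tiling_bins(ann.chrom_sizes, 10_000)
    for label, tp in (("start", 0), ("end", 8)):
        calls = read_meth_coverage(OUT / f"bmp_m1_t{tp}.cov.tsv")
        binned = aggregate_cpg_bins(calls, bins)
        write_result_tsv(binned, OUT / f"binned_10kb_{label}.tsv",
                         {"bin_size": 10_000, "min_depth": 4, "min_cpgs": 4})
        summary = summarize_elements(calls, ann, class_map=class_map)
        write_result_tsv(summary, OUT / f"element_summary_{label}.tsv")
        gw = summary.set_index("element_class").loc["genome", "mean_5mc"]
        print(f"{label}: genome-wide {gw:.1f}%; "
              + "; ".join(f"{r.element_class} {r.mean_5mc:.0f}%"
                          for r in summary.itertuples()
                          if r.element_class in ("promoter_HCP", "cgi",
                                                 "imprint_dmr",
                                                 "repeat_LINE_young")))


if __name__ == "__main__":
    main()
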