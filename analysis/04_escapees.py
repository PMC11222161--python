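"""Call demethylation escapees and profile their repeat composition.

Segments hypermethylated regions from the end-of-differentiation binned
methylome for two conditions, counts common/specific regions between them
and decomposes escapee bases over repeat classes: the surviving regions
should be dominated by the young-retrotransposon and satellite classes the
generator protected from dilution.
"""

from pathlib import Path

from pgcmeth.io import read_result_tsv, write_bed, write_result_tsv
from pgcmeth.methylome import call_hypermethylated_regions, escapee_overlap_composition
from pgcmeth.intervals import make_tiling_bins
from pgcmeth.methylome import aggregate_cpg_bins
from pgcmeth.io import read_meth_coverage
from pgcmeth.simulate import ScenarioConfig, build_toy_genome

OUT = Path("results/analysis")
SEED = 20240501


def main() -> None:
    scenario = ScenarioConfig()
    ann = build_toy_genome(scenario, seed=SEED)
    bins = make_tiling_bins(ann.chrom_sizes, 2_000)
    sets = {}
    for condition, end_tp in (("bmp_m1", 24), ("bmp_f2", 24)):
        calls = read_meth_coverage(OUT / f"{condition}_t{end_tp}.cov.tsv")
        binned = aggregate_cpg_bins(calls, bins, min_depth=4, min_cpgs=2)
        regions = call_hypermethylated_regions(binned, 50.0, 1, 3)
        sets[condition] = regions
        write_bed(regions, OUT / f"escapees_{condition}.bed")
        print(f"{condition}: {len(regions)} escapee regions")
    res = escapee_overlap_composition(sets, ann)
    write_result_tsv(res["pairwise"], OUT / "escapee_overlap.tsv")
    write_result_tsv(res["composition"], OUT / "escapee_composition.tsv")
    comp = res["composition"]
    for name in sets:
        sub = comp[(comp["set"] == name) & (comp["element_class"] != "other")]
        top = sub.sort_values("base_fraction", ascending=False).iloc[0]
        print(f"{name}: top class {top['element_class']} "
              f"({100*top['base_fraction']:.0f}% of escapee bases)")


if __name__ == "__main__":
    main()
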