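import numpy as np
import pandas as pd
import pytest

from pgcmeth.genome import GenomeAnnotation
from pgcmeth.simulate import ScenarioConfig, build_toy_genome


def small_scenario() -> ScenarioConfig:
    """A reduced genome keeping every annotation layer, for fast tests."""
    return ScenarioConfig(
        chrom_sizes={"chr1": 500_000, "chr2": 400_000,
                     "chr10": 300_000, "chrX": 1_300_000},
        phasing_block_len=600_000,
        par_len=50_000,
        mean_cpg_spacing=300,
    )


@pytest.fixture(scope="session")
def scenario() -> ScenarioConfig:
    return small_scenario()


@pytest.fixture(scope="session")
def annotation(scenario) -> GenomeAnnotation:
    return build_toy_genome(scenario, seed=11)


@pytest.fixture()
def tiny_annotation() -> GenomeAnnotation:
    """Hand-built two-gene annotation with exactly known coordinates."""
    genes = pd.DataFrame({
        "gene_id": ["gA", "gB"],
        "chrom": ["chr1", "chr1"],
        "start": [2_000, 10_000],
        "end": [5_000, 13_000],
        "tss": [2_000, 12_999],
        "strand": ["+", "-"],
        "x_linked": [False, False],
        "par": [False, False],
    })
    return GenomeAnnotation(
        chrom_sizes={"chr1": 20_000},
        genes=genes,
        cgis=pd.DataFrame({"chrom": ["chr1"], "start": [1_800], "end": [2_600]}),
        repeats=pd.DataFrame({"chrom": ["chr1"], "start": [6_000], "end": [6_400],
                              "repeat_class": ["LINE_young"]}),
        cpg_positions=pd.DataFrame({"chrom": "chr1",
                                    "pos": np.arange(0, 20_000, 100)}),
    )
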