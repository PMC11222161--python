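"""Annotated toy-genome data model and derived region classes.

The genome is carried as a :class:`GenomeAnnotation`: chromosome sizes plus
BED-style feature tables (genes with TSS/strand, CpG islands, repeats with a
class label, imprint DMRs, open chromatin sites, chrX phasing blocks, PARs).
From the raw features the module derives the region classes used by every
downstream summary: promoters (TSS −900/+400 by strand), intergenes
(gene-free, retrotransposon-free pieces of 500 bp–10 kb) and promoter CpG
density classes (HCP/ICP/LCP).

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    INTERVAL_COLS,
    complement_intervals,
    merge_intervals,
    sort_intervals,
    subtract_intervals,
    validate_intervals,
)

PROMOTER_UPSTREAM = 900
PROMOTER_DOWNSTREAM = 400
INTERGENE_MIN_LEN = 500
INTERGENE_MAX_LEN = 10_000
MIN_PHASING_BLOCK_LEN = 500_000

#: repeat classes counted as retrotransposons (excluded from intergenes)
RETROTRANSPOSON_CLASSES = frozenset({"LINE_young", "SVA", "Alu_old"})

#: closed vocabulary of region-class labels
REGION_CLASS_LABELS = (
    "promoter_HCP",
    "promoter_ICP",
    "promoter_LCP",
    "cgi",
    "exon",
    "intron",
    "intergenic",
    "imprint_dmr",
    "open_site",
    "background",
)


class StrandError(ValueError):
    """Unknown strand symbol (must be '+' or '-')."""


@dataclass
class GenomeAnnotation:
    """Feature catalogue for a (toy) genome.

    genes carries one row per gene: ``gene_id, chrom, start, end, tss,
    strand, x_linked, par``.  Interval tables follow the BED convention.
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame
    cgis: pd.DataFrame = field(default_factory=pd.DataFrame)
    repeats: pd.DataFrame = field(default_factory=pd.DataFrame)
    imprint_dmrs: pd.DataFrame = field(default_factory=pd.DataFrame)
    open_sites: pd.DataFrame = field(default_factory=pd.DataFrame)
    phasing_blocks: pd.DataFrame = field(default_factory=pd.DataFrame)
    pars: pd.DataFrame = field(default_factory=pd.DataFrame)
    exons: pd.DataFrame = field(default_factory=pd.DataFrame)
    cpg_positions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for name in ("cgis", "repeats", "imprint_dmrs", "open_sites",
                     "phasing_blocks", "pars", "exons"):
            df = getattr(self, name)
            if len(df):
                validate_intervals(df, self.chrom_sizes)
        if len(self.genes):
            for _, g in self.genes.iterrows():
                if not (0 <= g["tss"] < self.chrom_sizes[g["chrom"]]):
                    raise ValueError(f"TSS of {g['gene_id']} outside chromosome bounds")

    def x_linked_genes(self) -> pd.DataFrame:
        """X-linked genes, PAR genes excluded."""
        g = self.genes
        return g[g["x_linked"] & ~g["par"]].reset_index(drop=True)

    def usable_phasing_blocks(self) -> pd.DataFrame:
        """Phasing blocks long enough for allelic assignment (>= 500 kb)."""
        b = self.phasing_blocks
        if len(b) == 0:
            return b
        keep = (b["end"] - b["start"]) >= MIN_PHASING_BLOCK_LEN
        return b[keep].reset_index(drop=True)


def derive_promoters(annotation: GenomeAnnotation) -> pd.DataFrame:
    """Promoter intervals per gene: [TSS-900, TSS+400) on '+', mirrored on '-'.

    Clipped to chromosome bounds.  Raises StrandError on an unknown strand.
    """
    rows = []
    for _, g in annotation.genes.iterrows():
        tss = int(g["tss"])
        strand = g["strand"]
        if strand == "+":
            s, e = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
        elif strand == "-":
            s, e = tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM
        else:
            raise StrandError(f"unknown strand {strand!r} for gene {g['gene_id']}")
        size = annotation.chrom_sizes[g["chrom"]]
        rows.append((g["chrom"], max(0, s), min(size, e), g["gene_id"]))
    return pd.DataFrame(rows, columns=[*INTERVAL_COLS, "gene_id"])


def derive_intergenes(annotation: GenomeAnnotation) -> pd.DataFrame:
    """Gene-free regions minus retrotransposons, kept when 500 bp <= length <= 10 kb."""
    gene_bodies = annotation.genes[["chrom", "start", "end"]]
    gaps = complement_intervals(gene_bodies, annotation.chrom_sizes)
    rep = annotation.repeats
    if len(rep):
        retro = rep[rep["repeat_class"].isin(RETROTRANSPOSON_CLASSES)]
        gaps = subtract_intervals(gaps, retro)
    if len(gaps) == 0:
        return gaps
    length = gaps["end"] - gaps["start"]
    keep = (length >= INTERGENE_MIN_LEN) & (length <= INTERGENE_MAX_LEN)
    return sort_intervals(gaps[keep])


def classify_promoter_cpg_density(
    promoters: pd.DataFrame,
    cpg_positions: pd.DataFrame,
    gc_content: float | pd.Series = 0.5,
    hcp_oe: float = 0.75,
    hcp_gc: float = 0.55,
    lcp_oe: float = 0.48,
) -> pd.DataFrame:
    """Label promoters HCP/ICP/LCP from CpG observed/expected ratio and GC content.

    o/e is computed as observed CpG count over the count expected at the
    given GC content, ``(gc/2)^2 * length``.  The thresholds are configuration
    approximating the commonly used high/intermediate/low CpG promoter
    classification: o/e >= hcp_oe and GC >= hcp_gc -> HCP; o/e < lcp_oe ->
    LCP; otherwise ICP.  A promoter with zero CpGs is LCP by construction.
    """
    if len(promoters) and ((promoters["end"] - promoters["start"]) <= 0).any():
        raise ValueError("promoter with zero or negative length")
    gc = np.broadcast_to(np.asarray(gc_content, dtype=float), (len(promoters),)) \
        if np.isscalar(gc_content) else np.asarray(gc_content, dtype=float)
    labels = []
    oes = []
    for k, (_, p) in enumerate(promoters.iterrows()):
        sub = cpg_positions[(cpg_positions["chrom"] == p["chrom"])
                            & (cpg_positions["pos"] >= p["start"])
                            & (cpg_positions["pos"] < p["end"])]
        length = p["end"] - p["start"]
        expected = (gc[k] / 2.0) ** 2 * length
        oe = len(sub) / expected if expected > 0 else 0.0
        oes.append(oe)
        if len(sub) == 0:
            labels.append("LCP")
        elif oe >= hcp_oe and gc[k] >= hcp_gc:
            labels.append("HCP")
        elif oe < lcp_oe:
            labels.append("LCP")
        else:
            labels.append("ICP")
    out = promoters.copy()
    out["cpg_oe"] = oes
    out["cpg_class"] = labels
    return out


def build_element_class_map(
    annotation: GenomeAnnotation,
    promoters: pd.DataFrame | None = None,
    gc_content: float | pd.Series = 0.5,
) -> dict[str, pd.DataFrame]:
    """Interval set per region-class label, derived from the raw features.

    Overlapping annotations are allowed; each label is summarised
    independently downstream (no precedence hierarchy).  Repeat classes are
    emitted as ``repeat_<class>`` labels.
    """
    if promoters is None:
        promoters = derive_promoters(annotation)
    classed = classify_promoter_cpg_density(
        promoters, annotation.cpg_positions, gc_content=gc_content)
    out: dict[str, pd.DataFrame] = {}
    for label in ("HCP", "ICP", "LCP"):
        sub = classed[classed["cpg_class"] == label][INTERVAL_COLS]
        out[f"promoter_{label}"] = sub.reset_index(drop=True)
    if len(annotation.cgis):
        out["cgi"] = annotation.cgis[INTERVAL_COLS].reset_index(drop=True)
    if len(annotation.exons):
        out["exon"] = annotation.exons[INTERVAL_COLS].reset_index(drop=True)
        introns = subtract_intervals(
            annotation.genes[INTERVAL_COLS], annotation.exons)
        out["intron"] = introns
    out["intergenic"] = derive_intergenes(annotation)
    if len(annotation.repeats):
        for rclass, sub in annotation.repeats.groupby("repeat_class"):
            out[f"repeat_{rclass}"] = sub[INTERVAL_COLS].reset_index(drop=True)
    if len(annotation.imprint_dmrs):
        out["imprint_dmr"] = annotation.imprint_dmrs[INTERVAL_COLS].reset_index(drop=True)
    if len(annotation.open_sites):
        out["open_site"] = annotation.open_sites[INTERVAL_COLS].reset_index(drop=True)
    # background: everything outside genes, promoters and open sites
    covered = pd.concat(
        [annotation.genes[INTERVAL_COLS], promoters[INTERVAL_COLS]]
        + ([annotation.open_sites[INTERVAL_COLS]] if len(annotation.open_sites) else []),
        ignore_index=True)
    out["background"] = complement_intervals(
        merge_intervals(covered), annotation.chrom_sizes)
    return out
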