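"""Synthetic genomes, methylomes, allelic UMI tables and expression tables.

The generators emulate the statistical structure of the study every other
module assumes: a toy annotated genome; bulk CpG methylomes evolving under
the replication-dilution model with escapee, imprint-DMR and Xi-resistance
overrides and binomial sequencing observation; allele-split chrX coverage;
overdispersed single-cell allelic UMI counts; and log-normal expression
tables with X-linked dosage scaling and progressively upregulated ER genes.

Scenario defaults mirror the reported magnitudes of the system being
emulated (iPSC autosomes ~85% 5mC decaying to ~10%; per-cycle losses of
1.0/4.9/7.6 percentage points under no-BMP/BMP/fast-female conditions; Xi
promoters/CGIs retaining ~44%/65%; imprint DMRs at 50%; ~25% Xi transcript
fraction; X:A scale factors 0.9/0.7/0.8; TET1-KO hypermethylation of ~4
points genome-wide, ~2 on the background and >10 on bivalent/poised
elements).  They are defaults describing the simulated conditions, not
claims about real data.  Every generator is deterministic given its seed
and writes/returns truth tables usable as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dilution import CultureClock, DilutionParams, params_for_linear_rate
from .genome import GenomeAnnotation
from .intervals import INTERVAL_COLS, build_trees, make_tiling_bins
from .methylome import CALL_COLS, make_call_table


@dataclass
class ConditionSpec:
    """One culture condition: start level, printed per-cycle loss, clock."""

    label: str
    initial_level: float
    rate_per_cycle: float            # absolute percentage points of 5mC per cycle
    clock: CultureClock

    def dilution_params(self) -> DilutionParams:
        return params_for_linear_rate(self.initial_level, self.rate_per_cycle,
                                      self.clock.n_cycles)


def _default_conditions() -> dict[str, ConditionSpec]:
    # 22 days of culture from hPGCLC isolation to c32; doubling times chosen
    # so the clocks are consistent with both the per-cycle losses and the
    # c32 endpoint levels (~45% with BMP, ~63% without).
    return {
        "bmp_m1": ConditionSpec("bmp_m1", 85.0, 4.9, CultureClock([(22.0, 2.75)])),
        "no_bmp": ConditionSpec("no_bmp", 85.0, 1.0, CultureClock([(22.0, 1.0)])),
        "bmp_f2": ConditionSpec("bmp_f2", 85.0, 7.6, CultureClock([(22.0, 2.75)])),
    }


@dataclass
class TetKoSpec:
    """TET1-KO c12 comparison: class weights, WT levels and hypermethylation.

    The bivalent/poised delta is solved from the genome-wide aggregate
    constraint: sum(weight * delta) = genome_wide_delta.
    """

    genome_wide_delta: float = 4.0
    weights: dict[str, float] = field(default_factory=lambda: {
        "intergenic_nre": 0.55, "genic_nre": 0.25,
        "other_re": 0.12, "bivalent_poised_re": 0.08})
    deltas: dict[str, float] = field(default_factory=lambda: {
        "intergenic_nre": 2.0, "genic_nre": 3.0, "other_re": 7.0})
    wt_levels: dict[str, float] = field(default_factory=lambda: {
        "intergenic_nre": 62.0, "genic_nre": 64.0,
        "other_re": 50.0, "bivalent_poised_re": 35.0})

    def solved_deltas(self) -> dict[str, float]:
        fixed = sum(self.weights[c] * d for c, d in self.deltas.items())
        solved = dict(self.deltas)
        solved["bivalent_poised_re"] = (
            (self.genome_wide_delta - fixed) / self.weights["bivalent_poised_re"])
        return solved


@dataclass
class ScenarioConfig:
    """Parameters of the default synthetic scenario."""

    # genome layout
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {
        "chr1": 3_000_000, "chr2": 2_000_000, "chr10": 1_500_000, "chrX": 3_000_000})
    n_genes_per_mb: float = 10.0
    cgi_fraction_of_promoters: float = 0.6
    repeat_density: float = 1.0      # 0 disables every repeat class
    phasing_block_len: int = 600_000
    par_len: int = 100_000
    mean_cpg_spacing: int = 150

    # methylome trajectories
    conditions: dict[str, ConditionSpec] = field(default_factory=_default_conditions)
    escapee_repeat_classes: tuple[str, ...] = (
        "LINE_young", "SVA", "satellite_centromeric", "satellite_telomeric")
    escapee_initial_level: float = 85.0
    imprint_dmr_initial: float = 50.0
    # Xi structure: promoters/CGIs hypermethylated and resistant; chrX
    # background lower on Xi than Xa (gene-body hypomethylation of Xi)
    xi_promoter_initial: float = 87.0
    xi_cgi_initial: float = 93.0
    xi_background_initial: float = 65.0
    xa_promoter_initial: float = 15.0
    depth_mean: float = 15.0
    allele_depth_fraction: float = 0.4

    # single-cell allelic usage
    xi_transcript_fraction: float = 0.25
    umi_mean: float = 6.0
    umi_dispersion: float = 2.0      # NB shape; smaller = more overdispersed

    # expression / dosage
    xa_scales: dict[str, float] = field(default_factory=lambda: {
        "iPSC": 0.9, "male_late": 0.7, "female_late": 0.8})
    expr_log_mean: float = 8.0
    expr_log_sd: float = 1.5
    expressed_fraction: float = 0.9
    sample_log_jitter: float = 0.1

    # CpA de novo readout (equilibrium of the CpA dilution process)
    cpa_p_maint: float = 0.10
    cpa_p_denovo_no_bmp: float = 0.025
    cpa_p_denovo_bmp: float = 0.015

    tet_ko: TetKoSpec = field(default_factory=TetKoSpec)


# ---------------------------------------------------------------------------
# toy genome
# ---------------------------------------------------------------------------

def build_toy_genome(config: ScenarioConfig | None = None, seed: int = 0) -> GenomeAnnotation:
    """Deterministic toy genome with all annotation layers."""
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    genes, cgis, repeats, dmrs, opens, exons = [], [], [], [], [], []
    imprint_names = ["KCNQ1OT1", "H19", "SNRPN", "MEG3", "PEG3", "MEST"]
    repeat_cycle = ["LINE_young", "SVA", "Alu_old"]
    repeat_lens = {"LINE_young": 1200, "SVA": 800, "Alu_old": 300}
    gid = 0
    for chrom, size in cfg.chrom_sizes.items():
        n_genes = int(cfg.n_genes_per_mb * size / 1e6)
        # genes laid head-to-tail with random gaps; gene body 5 kb
        pos = 5_000
        for k in range(n_genes):
            gap = int(rng.integers(2_000, 25_000))
            start = pos + gap
            end = start + 5_000
            if end > size - 5_000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            par = chrom == "chrX" and (start < cfg.par_len or end > size - cfg.par_len)
            genes.append((f"g{gid:04d}", chrom, start, end, tss, strand,
                          chrom == "chrX", par))
            # 5 exons of 400 bp separated by introns
            for x in range(5):
                es = start + x * 1_000
                exons.append((chrom, es, es + 400))
            if rng.random() < cfg.cgi_fraction_of_promoters:
                cgis.append((chrom, max(0, tss - 500), min(size, tss + 500)))
            gid += 1
            pos = end
        # retrotransposons and satellites in the remaining space
        n_rep = int(cfg.repeat_density * size / 40_000)
        for k in range(n_rep):
            rclass = repeat_cycle[k % len(repeat_cycle)]
            length = repeat_lens[rclass]
            s = int(rng.integers(0, size - length))
            repeats.append((chrom, s, s + length, rclass))
        if cfg.repeat_density > 0:
            mid = size // 2
            repeats.append((chrom, mid, mid + 10_000, "satellite_centromeric"))
            repeats.append((chrom, 0, 5_000, "satellite_telomeric"))
            repeats.append((chrom, size - 5_000, size, "satellite_telomeric"))
        # a couple of orphan CGIs per chromosome
        for _ in range(3):
            s = int(rng.integers(0, size - 1_000))
            cgis.append((chrom, s, s + 1_000))
    # imprint DMRs on autosomes (overlap with other layers is allowed)
    auto = [c for c in cfg.chrom_sizes if c != "chrX"]
    for i, name in enumerate(imprint_names):
        chrom = auto[i % len(auto)]
        s = int(np.random.default_rng(seed + 1000 + i).integers(
            0, cfg.chrom_sizes[chrom] - 1_500))
        dmrs.append((chrom, s, s + 1_500, name))

    genes_df = pd.DataFrame(genes, columns=[
        "gene_id", "chrom", "start", "end", "tss", "strand", "x_linked", "par"])
    # open sites: one per promoter for 70% of genes + distal sites
    for _, g in genes_df.iterrows():
        if rng.random() < 0.7:
            summit = int(g["tss"])
            opens.append((g["chrom"], max(0, summit - 300),
                          min(cfg.chrom_sizes[g["chrom"]], summit + 300), summit))
    for chrom, size in cfg.chrom_sizes.items():
        for _ in range(int(size / 100_000)):
            summit = int(rng.integers(2_000, size - 2_000))
            opens.append((chrom, summit - 300, summit + 300, summit))

    # chrX phasing blocks tile the chromosome
    xsize = cfg.chrom_sizes["chrX"]
    block_starts = np.arange(0, xsize, cfg.phasing_block_len)
    blocks = pd.DataFrame({
        "chrom": "chrX", "start": block_starts,
        "end": np.minimum(block_starts + cfg.phasing_block_len, xsize)})
    from .genome import MIN_PHASING_BLOCK_LEN
    blocks = blocks[(blocks["end"] - blocks["start"])
                    >= MIN_PHASING_BLOCK_LEN].reset_index(drop=True)
    blocks["block_id"] = [f"blk{i:02d}" for i in range(len(blocks))]
    pars = pd.DataFrame({"chrom": ["chrX", "chrX"],
                         "start": [0, xsize - cfg.par_len],
                         "end": [cfg.par_len, xsize]})

    # CpG positions: baseline spacing genome-wide, densified inside CGIs
    cpg_rows = []
    cgis_df = pd.DataFrame(cgis, columns=INTERVAL_COLS)
    for chrom, size in cfg.chrom_sizes.items():
        n = int(2 * size / cfg.mean_cpg_spacing)
        steps = rng.integers(cfg.mean_cpg_spacing // 2, cfg.mean_cpg_spacing * 3 // 2, n)
        pos = np.cumsum(steps)
        pos = pos[pos < size]
        cpg_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
        for _, c in cgis_df[cgis_df["chrom"] == chrom].iterrows():
            dense = np.arange(c["start"], c["end"], 15)
            cpg_rows.append(pd.DataFrame({"chrom": chrom, "pos": dense}))
    cpgs = (pd.concat(cpg_rows, ignore_index=True)
            .drop_duplicates().sort_values(["chrom", "pos"]).reset_index(drop=True))

    return GenomeAnnotation(
        chrom_sizes=dict(cfg.chrom_sizes),
        genes=genes_df,
        cgis=cgis_df,
        repeats=pd.DataFrame(repeats, columns=[*INTERVAL_COLS, "repeat_class"]),
        imprint_dmrs=pd.DataFrame(dmrs, columns=[*INTERVAL_COLS, "locus"]),
        open_sites=pd.DataFrame(opens, columns=[*INTERVAL_COLS, "summit"]),
        phasing_blocks=blocks,
        pars=pars,
        exons=pd.DataFrame(exons, columns=INTERVAL_COLS),
        cpg_positions=cpgs,
    )


# ---------------------------------------------------------------------------
# methylome time course
# ---------------------------------------------------------------------------

def _site_masks(annotation: GenomeAnnotation, cfg: ScenarioConfig,
                chrom: np.ndarray, pos: np.ndarray) -> dict[str, np.ndarray]:
    """Boolean site masks for the trajectory-defining region classes."""
    def mask_from(intervals: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(pos), dtype=bool)
        trees = build_trees(intervals)
        for i in range(len(pos)):
            tree = trees.get(chrom[i])
            if tree is not None and tree[int(pos[i])]:
                out[i] = True
        return out

    rep = annotation.repeats
    escapee = rep[rep["repeat_class"].isin(cfg.escapee_repeat_classes)]
    from .genome import derive_promoters
    promoters = derive_promoters(annotation)
    prom_cgi = pd.concat([promoters[INTERVAL_COLS],
                          annotation.cgis[INTERVAL_COLS]], ignore_index=True)
    return {
        "escapee": mask_from(escapee[INTERVAL_COLS]),
        "imprint": mask_from(annotation.imprint_dmrs[INTERVAL_COLS]),
        "prom_cgi": mask_from(prom_cgi),
        "x": chrom == "chrX",
    }


def simulate_methylome_timecourse(
        annotation: GenomeAnnotation, scenario: ScenarioConfig,
        condition: str = "bmp_m1",
        timepoints: tuple[int, ...] | None = None,
        seed: int = 0) -> dict:
    """Bulk CpG call tables per timepoint for one culture condition.

    Autosomal/Xa sites start at the condition's initial level and decay by
    per-site binary dilution; escapee repeats and imprint DMRs get their
    class-specific starting levels (escapees retain with p_maint = 1); chrX
    is emitted allele-tagged with Xi promoters/CGIs resistant and a lower Xi
    background.  Observed counts are binomial at Poisson-distributed
    per-site depths.  Returns ``{"calls": {tp: MethCallTable},
    "truth": DataFrame, "xa_truth": DataFrame}``.
    """
    cfg = scenario
    spec = cfg.conditions[condition]
    params = spec.dilution_params()
    if timepoints is None:
        timepoints = (0, params.n_cycles)
    n_cycles = max(timepoints)
    rng = np.random.default_rng(seed)

    sites = annotation.cpg_positions
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    masks = _site_masks(annotation, cfg, chrom, pos)
    n = len(sites)

    # per-site initial level and maintenance for the unphased/Xa lineage
    init = np.full(n, spec.initial_level / 100.0)
    pm = np.full(n, params.p_maint)
    init[masks["imprint"]] = cfg.imprint_dmr_initial / 100.0
    init[masks["escapee"]] = cfg.escapee_initial_level / 100.0
    pm[masks["escapee"]] = 1.0

    # Xi lineage: resistant promoters/CGIs, lower decaying background
    xi_init = init.copy()
    xi_pm = pm.copy()
    x_bg = masks["x"] & ~masks["prom_cgi"] & ~masks["escapee"]
    x_pc = masks["x"] & masks["prom_cgi"]
    xi_init[x_bg] = cfg.xi_background_initial / 100.0
    xi_init[x_pc] = cfg.xi_promoter_initial / 100.0
    xi_pm[x_pc] = 1.0
    xa_init = init.copy()
    xa_init[x_pc] = cfg.xa_promoter_initial / 100.0

    def evolve(initial, maint):
        states = rng.random(n) < initial
        traj = {0: states.copy()}
        for t in range(1, n_cycles + 1):
            keep = rng.random(n) < maint
            gain = rng.random(n) < params.p_denovo
            states = np.where(states, keep, gain)
            if t in timepoints:
                traj[t] = states.copy()
        return traj

    bulk = evolve(init, pm)        # autosomes (used off chrX)
    xa = evolve(xa_init, pm)       # chrX active allele
    xi = evolve(xi_init, xi_pm)    # chrX inactive allele

    # truth: which physical allele label is Xa, per phasing block
    blocks = annotation.phasing_blocks
    xa_is_allele1 = rng.random(len(blocks)) < 0.5
    xa_truth = pd.DataFrame({"block_id": blocks["block_id"],
                             "xa_allele": np.where(xa_is_allele1, "allele1", "allele2")})
    block_of_site = np.full(n, -1)
    bstart = blocks["start"].to_numpy()
    bend = blocks["end"].to_numpy()
    xmask = masks["x"]
    for bi in range(len(blocks)):
        block_of_site[xmask & (pos >= bstart[bi]) & (pos < bend[bi])] = bi

    calls_by_tp = {}
    truth_rows = []
    for tp in sorted(set(timepoints)):
        auto_sel = ~xmask
        depth = rng.poisson(cfg.depth_mean, auto_sel.sum())
        state = bulk[tp][auto_sel]
        tables = [make_call_table(chrom[auto_sel], pos[auto_sel],
                                  np.where(state, depth, 0),
                                  np.where(state, 0, depth))]
        # chrX: one record per allele; physical labels follow the block truth
        xsel = np.where(xmask & (block_of_site >= 0))[0]
        for allele_label in ("allele1", "allele2"):
            is_xa = (xa_truth["xa_allele"].to_numpy()[block_of_site[xsel]]
                     == allele_label)
            state_x = np.where(is_xa, xa[tp][xsel], xi[tp][xsel])
            depth_x = rng.poisson(cfg.depth_mean * cfg.allele_depth_fraction,
                                  len(xsel))
            tables.append(make_call_table(
                chrom[xsel], pos[xsel],
                np.where(state_x, depth_x, 0), np.where(state_x, 0, depth_x),
                allele=allele_label))
        calls = pd.concat(tables, ignore_index=True)[CALL_COLS]
        covered = (calls["count_meth"] + calls["count_unmeth"]) > 0
        calls_by_tp[tp] = calls[covered].sort_values(
            ["chrom", "start", "allele"], kind="mergesort").reset_index(drop=True)
        truth_rows.append({
            "timepoint": tp,
            "expected_background": 100 * float(
                params.expected_trajectory(n_cycles)[tp]),
            "mean_true_background": 100 * float(bulk[tp][~xmask & ~masks["escapee"]
                                                         & ~masks["imprint"]].mean()),
            "mean_true_escapee": 100 * float(bulk[tp][masks["escapee"] & ~xmask].mean()),
            "mean_true_imprint": 100 * float(bulk[tp][masks["imprint"]].mean()),
            "mean_true_xi_promcgi": 100 * float(xi[tp][x_pc].mean()),
        })
    return {"calls": calls_by_tp, "truth": pd.DataFrame(truth_rows),
            "xa_truth": xa_truth, "params": params}


# ---------------------------------------------------------------------------
# allelic snapshot for Xa/Xi assignment
# ---------------------------------------------------------------------------

def simulate_allelic_methylome(annotation: GenomeAnnotation,
                               scenario: ScenarioConfig | None = None,
                               seed: int = 0,
                               depth: float = 12.0,
                               xa_truth: pd.DataFrame | None = None) -> dict:
    """One allele-tagged chrX snapshot with known Xa/Xi identity per block.

    Xi promoters/CGIs are hypermethylated (>= 2x Xa); the Xi 10-kb background
    is hypomethylated relative to Xa.  Observed counts are binomial around
    fractional bulk levels so every qualifying block is recoverable at
    moderate depth.  Returns ``{"calls", "xa_truth"}``.
    """
    cfg = scenario or ScenarioConfig()
    rng = np.random.default_rng(seed)
    sites = annotation.cpg_positions
    xmask = sites["chrom"].to_numpy() == "chrX"
    chrom = sites["chrom"].to_numpy()[xmask]
    pos = sites["pos"].to_numpy()[xmask]
    masks = _site_masks(annotation, cfg, chrom, pos)
    pc = masks["prom_cgi"]
    p_levels = {
        "Xa": np.where(pc, cfg.xa_promoter_initial, 85.0) / 100.0,
        "Xi": np.where(pc, cfg.xi_promoter_initial, cfg.xi_background_initial) / 100.0,
    }
    blocks = annotation.phasing_blocks
    if xa_truth is None:
        xa_is_allele1 = rng.random(len(blocks)) < 0.5
        xa_truth = pd.DataFrame({"block_id": blocks["block_id"],
                                 "xa_allele": np.where(xa_is_allele1,
                                                       "allele1", "allele2")})
    else:
        xa_truth = blocks[["block_id"]].merge(xa_truth, on="block_id")
    block_of_site = np.full(len(pos), -1)
    for bi, (s, e) in enumerate(zip(blocks["start"], blocks["end"])):
        block_of_site[(pos >= s) & (pos < e)] = bi
    keep = block_of_site >= 0
    tables = []
    for allele_label in ("allele1", "allele2"):
        is_xa = xa_truth["xa_allele"].to_numpy()[block_of_site[keep]] == allele_label
        p = np.where(is_xa, p_levels["Xa"][keep], p_levels["Xi"][keep])
        d = rng.poisson(depth, keep.sum())
        m = rng.binomial(d, p)
        tables.append(make_call_table(chrom[keep], pos[keep], m, d - m,
                                      allele=allele_label))
    calls = pd.concat(tables, ignore_index=True)
    return {"calls": calls, "xa_truth": xa_truth}


# ---------------------------------------------------------------------------
# allelic UMIs
# ---------------------------------------------------------------------------

def simulate_allelic_umis(n_genes: int, n_cells: int, xi_fraction: float,
                          umi_mean: float = 6.0, umi_dispersion: float = 2.0,
                          seed: int = 0) -> pd.DataFrame:
    """Gene x cell allelic UMI table with negative-binomial totals.

    Totals are NB(shape=umi_dispersion, mean=umi_mean); Xi counts are
    binomial with probability ``xi_fraction`` given the total.
    """
    if not (0.0 <= xi_fraction <= 1.0):
        raise ValueError("xi_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = np.repeat([f"xg{i:04d}" for i in range(n_genes)], n_cells)
    cells = np.tile([f"c{i:04d}" for i in range(n_cells)], n_genes)
    r = umi_dispersion
    p = r / (r + umi_mean)
    totals = rng.negative_binomial(r, p, n_genes * n_cells)
    xi = rng.binomial(totals, xi_fraction)
    return pd.DataFrame({"gene_id": genes, "cell_id": cells,
                         "umi_xa": totals - xi, "umi_xi": xi})


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def simulate_expression(n_autosomal: int, n_x: int, x_scale: float,
                        n_samples: int = 3, n_par: int = 10,
                        scenario: ScenarioConfig | None = None,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample RPM table with X genes scaled in log2(RPM+1) space.

    Expressed genes (a configurable fraction) draw log2(RPM+1) from a
    normal law well above the expression cutoff; X-linked expressed genes
    (PAR genes exempt) are multiplied by ``x_scale`` in log space.  About a
    tenth of the autosomal genes sit on chr10 as the control chromosome.
    Returns (expr, gene_meta).
    """
    cfg = scenario or ScenarioConfig()
    rng = np.random.default_rng(seed)
    ids, chroms, par_flags, base = [], [], [], []
    for i in range(n_autosomal):
        ids.append(f"a{i:05d}")
        chroms.append("chr10" if i % 10 == 0 else f"chr{1 + i % 9}")
        par_flags.append(False)
    for i in range(n_x + n_par):
        ids.append(f"x{i:05d}")
        chroms.append("chrX")
        par_flags.append(i >= n_x)
    n_total = len(ids)
    expressed = rng.random(n_total) < cfg.expressed_fraction
    log_base = np.where(
        expressed,
        rng.normal(cfg.expr_log_mean, cfg.expr_log_sd, n_total),
        rng.uniform(0.0, 2.0, n_total))
    log_base = np.clip(log_base, 0.0, None)
    is_x = (np.array(chroms) == "chrX") & ~np.array(par_flags)
    scale = np.where(is_x & expressed, x_scale, 1.0)
    log_scaled = log_base * scale
    cols = {}
    for s in range(n_samples):
        jitter = rng.normal(0.0, cfg.sample_log_jitter, n_total)
        cols[f"s{s}"] = np.maximum(2.0 ** (log_scaled + jitter) - 1.0, 0.0)
    expr = pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))
    meta = pd.DataFrame({"chrom": chroms, "par": par_flags},
                        index=expr.index)
    return expr, meta


def simulate_er_dataset(n_genes: int = 300, n_er: int = 40,
                        stages: tuple[str, ...] = ("iPSC", "early", "mid", "late"),
                        seed: int = 0, true_er: set[str] | None = None) -> dict:
    """Stage-mean expression and promoter 5mC with a known ER gene set.

    ER genes rise monotonically (total fold >= 4) and demethylate their
    promoters by >70%; the rest stay flat (small jitter) with partial
    demethylation below the 50% criterion.  Passing ``true_er`` pins the ER
    gene identities (two differentiation systems sharing the same biology).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    er = set(true_er) if true_er is not None \
        else set(rng.choice(genes, n_er, replace=False))
    means = np.empty((n_genes, len(stages)))
    m_start = np.empty(n_genes)
    m_end = np.empty(n_genes)
    for i, g in enumerate(genes):
        if g in er:
            base = rng.uniform(0.5, 2.0)
            fold_per_stage = rng.uniform(1.7, 2.5)
            means[i] = base * fold_per_stage ** np.arange(len(stages))
            m_start[i] = rng.uniform(70, 95)
            m_end[i] = m_start[i] * rng.uniform(0.05, 0.25)
        else:
            base = rng.uniform(1.0, 50.0)
            means[i] = base * (1.0 + rng.uniform(0, 0.02, len(stages)).cumsum())
            m_start[i] = rng.uniform(40, 95)
            m_end[i] = m_start[i] * rng.uniform(0.65, 1.0)
    stage_means = pd.DataFrame(means, index=pd.Index(genes, name="gene_id"),
                               columns=list(stages))
    promoter = pd.DataFrame({"m_start": m_start, "m_end": m_end},
                            index=stage_means.index)
    return {"stage_means": stage_means, "promoter_5mc": promoter, "true_er": er}


# ---------------------------------------------------------------------------
# TET1-KO comparison scenario
# ---------------------------------------------------------------------------

def simulate_wt_ko_scenario(scenario: ScenarioConfig | None = None,
                            n_bins: int = 8_000, bin_size: int = 2_000,
                            sites_per_bin: int = 10, depth: int = 20,
                            seed: int = 0) -> dict:
    """Paired WT and two-replicate-KO methylomes over a 2-kb bin grid.

    Bins belong to four element classes in the configured genome
    proportions; per bin the WT bulk level is jittered around its class
    mean and the KO level adds the class hypermethylation delta (the
    bivalent/poised delta being solved from the genome-wide aggregate).
    Observed counts are binomial around fractional bulk levels.  Returns
    call tables, the bin grid, boolean class masks and the truth deltas.
    """
    cfg = (scenario or ScenarioConfig()).tet_ko
    rng = np.random.default_rng(seed)
    deltas = cfg.solved_deltas()
    labels = list(cfg.weights)
    counts = {c: int(round(cfg.weights[c] * n_bins)) for c in labels}
    counts[labels[0]] += n_bins - sum(counts.values())  # rounding remainder
    bin_class = np.concatenate([np.full(counts[c], i) for i, c in enumerate(labels)])
    rng.shuffle(bin_class)
    chrom_size = n_bins * bin_size
    bins = make_tiling_bins({"chrK": chrom_size}, bin_size)
    wt_level = np.empty(n_bins)
    ko_level = np.empty(n_bins)
    for i, c in enumerate(labels):
        sel = bin_class == i
        base = np.clip(rng.normal(cfg.wt_levels[c], 5.0, sel.sum()), 2.0, 95.0)
        wt_level[sel] = base
        ko_level[sel] = np.clip(base + deltas[c], 0.0, 100.0)

    def observe(levels: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
        pos = np.repeat(bins["start"].to_numpy(), sites_per_bin) + \
            np.tile(np.arange(sites_per_bin) * (bin_size // sites_per_bin), n_bins)
        p = np.repeat(levels / 100.0, sites_per_bin)
        d = rng.poisson(depth, len(pos))
        m = rng.binomial(d, p)
        return make_call_table(np.full(len(pos), "chrK"), pos, m, d - m)

    result = {
        "bins": bins,
        "wt_calls": observe(wt_level, rng),
        "ko_calls": [observe(ko_level, rng), observe(ko_level, rng)],
        "class_masks": {c: bin_class == i for i, c in enumerate(labels)},
        "true_deltas": deltas,
        "true_genome_delta": float(np.mean(ko_level - wt_level)),
    }
    return result


def simulate_cpa_bins(scenario: ScenarioConfig | None = None,
                      n_bins: int = 2_000, calls_per_bin: int = 250,
                      seed: int = 0) -> dict:
    """Bin-level CpA methylation for BMP+ and BMP- c32 conditions.

    Bin values are pooled binomial draws around the equilibrium CpA level of
    the CpA dilution process, which is lower under BMP because de novo
    activity is reduced.  Returns the two value arrays and the equilibria.
    """
    cfg = scenario or ScenarioConfig()
    rng = np.random.default_rng(seed)
    out = {}
    for label, p_denovo in (("bmp_plus", cfg.cpa_p_denovo_bmp),
                            ("bmp_minus", cfg.cpa_p_denovo_no_bmp)):
        eq = DilutionParams(p_maint=cfg.cpa_p_maint, p_denovo=p_denovo).equilibrium
        m = rng.binomial(calls_per_bin, eq, n_bins)
        out[label] = 100.0 * m / calls_per_bin
        out[f"{label}_equilibrium"] = 100.0 * eq
    return out
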