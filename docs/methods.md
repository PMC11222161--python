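# Methods

`pgcmeth` re-implements, as a tested library plus analysis drivers, the
bespoke computations behind the epigenetic-reprogramming analysis of
BMP-driven human PGC-like cell (hPGCLC) differentiation: methylome
aggregation and element summaries, a replication-coupled passive
demethylation model with per-cell-cycle rate estimation, demethylation
escapee calling, allele-resolved Xa/Xi analysis and X-chromosome
reactivation statistics, X:A dosage compensation, ER-gene classification,
regulatory-element categorization and WT-vs-TET1-KO comparison statistics.
Because the real measurements live on deposited sequencing data at a scale
far beyond a desk run, every statistic is exercised end-to-end on synthetic
data whose generating parameters are set to the magnitudes reported for
the system, and validated by parameter recovery and by independent oracles.

## The dilution model

Each CpG site carries a binary methylation state per cell lineage.  At every
cell cycle a methylated site stays methylated with probability `p_maint`
(maintenance methyltransferase activity at the replication fork) and an
unmethylated site gains methylation with probability `p_denovo`.  The bulk
level on the [0,1] scale obeys

    m_{t+1} = m_t · p_maint + (1 − m_t) · p_denovo

with closed form `m_t = e + (m_0 − e)(p_maint − p_denovo)^t` and equilibrium
`e = p_denovo / (1 − p_maint + p_denovo)`.  Per-site states are binary;
fractional bulk levels arise only from averaging over sites, which is the
cleanest testable interpretation and what the trajectory oracle checks.

**Per-cycle rate.**  The primary readout is the *linear* absolute loss,
`(m_start − m_end) / n_cycles`, in percentage points of 5mC per cell cycle —
the scale on which the conditions of interest lose about 1.0 (no BMP), 4.9
(BMP, M1 line) and 7.6 (F2 line) points per cycle.  The geometric
per-cycle retention `(m_end/m_start)^{1/n}` is reported alongside, since
the two readouts diverge over long cultures.  Cell-cycle counts always come
from a culture clock of per-passage-interval doubling times
(`CultureClock`), never from a hard-coded constant.  The default clocks
(22 days at 2.75-day doubling for the BMP conditions, 22 days at 1.0-day
doubling without BMP) make the configured rates consistent with the
condition endpoints (≈45% with BMP at the first landmark, ≈63% without,
from an 85% start).  `params_for_linear_rate` inverts the closed form to
the `p_maint` whose endpoint realises a configured linear rate, with
`p_denovo = 0`.

## Aggregation rules

Two aggregation flavours are used throughout, and they agree exactly
whenever every site has the same depth:

* **per-site averaging** (`aggregate_cpg_bins`): mean of per-site %mC over
  CpGs with depth ≥ 4, requiring ≥ 4 qualifying CpGs per bin (default bins:
  10 kb genome-wide, 2 kb for the KO comparison);
* **pooled counting** (`aggregate_pooled`): `100·ΣM/(ΣM+ΣU)` with at least
  10 calls — used for CpA and for sparse allele-split data.

Replicate averaging takes the mean of replicate bin means and fails a bin
that fails depth QC in any replicate.  Bins failing QC carry
`qc_pass=False` and are excluded from every downstream statistic; "missing"
is never coerced to zero.

## Region classes and coordinates

All coordinates are 0-based half-open (BED convention).  Promoters span
TSS −900/+400 by strand, clipped to chromosome bounds.  Intergenes are the
complement of gene bodies minus retrotransposons, keeping pieces of
500 bp–10 kb.  Promoter CpG-density classes (HCP/ICP/LCP) use thresholds on
the CpG observed/expected ratio and GC content (defaults: o/e ≥ 0.75 and
GC ≥ 0.55 → HCP; o/e < 0.48 → LCP; else ICP).  These thresholds are
declared configuration approximating the commonly used classification, not
a reconstruction — the original class definitions are external.
Overlapping annotations are allowed and each class is summarised
independently; there is no precedence hierarchy among element summaries.

## Escapee calling

Demethylation escapees are segmented from a binned table by an explicit
threshold+gap rule: maximal runs of QC-passing bins with mean 5mC ≥ 50%,
bridging at most one failing bin, kept at ≥ 3 qualifying bins.  This is a
deliberate re-implementation of hypermethylated-region calling as
configurable segmentation (the study used an external HMM-based caller);
it is validated against a brute-force run enumeration on instances up to
100 bins, and on synthetic genomes where the protected classes (young
retrotransposons: LINE_young/SVA; centromeric and telomeric satellites)
are known.  Escapee composition is reported both as base fraction
(primary) and as region-hit counts, since the counting convention is
otherwise ambiguous; overlap between escapee sets counts any ≥ 1 bp
intersection.

## Xa/Xi assignment and allelic statistics

On phasing blocks of at least 500 kb, the active X is the allele whose
pooled promoter+CGI 5mC is at most half of the other allele's ("lower by
50%" read as a relative ratio — the inactive X of the studied iPSC lines is
markedly hypermethylated at promoters and CGIs, so an absolute-difference
reading would be both weaker and inconsistent with the observed
separation).  Blocks without any promoter or CGI fall back to the
genome-wide 10-kb-bin level, where the *higher* allele is Xa (Xi gene
bodies are hypomethylated).  Blocks with features where neither allele
meets the 50% rule stay unassigned — the fallback is restricted to
feature-free blocks by design.  Promoters and CGIs are pooled into one
statistic per allele (a separate evaluation is available through the
summary table).  The assignment is antisymmetric under allele relabelling,
which is property-tested.

X-linked genes are classified from allelic promoter 5mC at a 50% threshold:
class 1 high/high, class 2 low-Xa/high-Xi, class 3 high-Xa/low-Xi, class 4
low/low; genes missing an allele are excluded, not defaulted.

Allele usage from single-cell UMIs drops genes with a dataset-wide Xa+Xi
total below 3, computes `umi_xa/(umi_xa+umi_xi)` only where the per-gene-
and-cell total exceeds 2, and reports the group Xi fraction as
`1 − mean(usage)` with an unweighted mean over gene×cell observations
(the weighting convention is otherwise unspecified; unweighted is the
simplest defensible choice).

## X:A dosage compensation

A gene is expressed when its maximum log2(RPM+1) over the analysed samples
exceeds 3.  The X:A ratio is the 75th percentile (linear interpolation —
stated because percentile conventions differ across ecosystems) of
log2(RPM+1) over expressed X-linked genes, PARs excluded, divided by the
same statistic over expressed autosomal genes; chr10 against all autosomes
is the negative control.  The synthetic generator scales expressed X genes
in log space by a configured factor (0.9 iPSC-like, 0.7 male late-stage,
0.8 female late-stage plateau), and recovery within ±0.03 is the test.

## ER genes

"Progressive upregulation" is operationalised as non-decreasing stage means
(strict by default; a relative dip tolerance is configurable) with a
final/initial fold of at least 2 on RPM+1; promoter demethylation requires
a ≥ 50% *relative* reduction, `(m_start − m_end)/m_start ≥ 0.5` — relative,
not absolute percentage points, consistent with "reduction from" the
starting state.  Genes with a zero starting level are excluded with a
reason.  The redefined ER set is the intersection of the calls from two
differentiation systems, with an early/late split by the stage at which the
cumulative fold first reaches the threshold.

## Regulatory elements and the TET1-KO comparison

Open sites carry 20 × 200-bp signal bins (±2 kb of the summit) per mark as
log2 enrichment over input.  Categories follow explicit threshold rules —
active = high H3K4me3 ∧ H3K27ac; bivalent = high H3K4me3 ∧ H3K27me3;
poised = high H3K4me1 with neither prior rule firing; otherwise silent —
with precedence active > bivalent > poised.  A mark is "high" when its
mean over the central four bins exceeds a configured threshold (default
1.0).  This rule set replaces an embedding+clustering workflow whose
clusters were identified by visual inspection; the rules encode the
clusters' own descriptions, and the thresholds are declared configuration
calibrated on the synthetic generator.  Promoters inherit the category of
overlapping open sites (≥ 1 bp; precedence on conflicts), promoters without
open sites are silent, non-promoter open sites are enhancers, and genes
link to enhancers when the TSS lies within ±10 kb.

The WT/KO comparison aligns 2-kb bins, takes the KO value as the mean of
the replicate KO lines, counts bins beyond a ±30-point threshold per
direction (exchangeable under swapping WT and KO), and reports pooled
call-weighted levels per element class.  Enrichment uses Fisher's exact
test on in/out × in/out tables with Benjamini–Hochberg adjustment across
classes ("q value" without a named method is taken as BH); degenerate
tables report an undefined (NaN) odds ratio, never 0.

## The synthetic scenario

`ScenarioConfig` fixes the study conditions the generators emulate:

| parameter | default | meaning |
|---|---|---|
| initial autosome 5mC | 85% | pluripotent starting methylome |
| per-cycle losses | 1.0 / 4.9 / 7.6 %/cycle | no-BMP, BMP/M1, F2 conditions |
| escapee classes | LINE_young, SVA, satellites | retention `p_maint = 1` at 85% |
| imprint DMRs | 50% start | erased by dilution like background |
| Xi promoters / CGIs | 87% / 93%, resistant | demethylation resistance on Xi |
| Xi background | 65% | below Xa — basis of the 10-kb fallback |
| Xi transcript fraction | 25% | post-reactivation allele usage |
| X:A scales | 0.9 / 0.7 / 0.8 | iPSC, male late, female plateau |
| KO deltas | 2 / 3 / 7 points + solved | background, genic, other-RE classes |
| KO genome-wide target | 4.0 points | solves the bivalent/poised delta (16.375) |
| CpA equilibria | 2.7% vs 1.6% | de novo activity with/without BMP |
| depth | Poisson(15), 0.4×/allele | sequencing observation |
| UMI totals | NB(mean 6, shape 2) | overdispersed 10x-like counts |

The toy genome (9.5 Mb over chr1, chr2, chr10, chrX; ~10 genes/Mb; CGIs at
60% of promoters; 600-kb phasing blocks; 100-kb PARs) is small enough that
the full pipeline runs in seconds yet carries every annotation layer.  The
time-course generator keeps binary per-site states (one lineage per site),
so observed per-site %mC is exactly 0 or 100 and bin means carry
site-sampling variance; the KO-comparison and allelic-snapshot generators
instead draw per-site *bulk proportions* with binomial observation, because
their statistics compare small mean shifts where lineage-level Bernoulli
noise would be the dominant error term rather than the quantity of
interest.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: read-level artefacts (mapping bias, incomplete
conversion), genome-scale linkage between element classes, cell-type
heterogeneity within a bulk sample, real repeat sequence structure (repeat
classes enter as annotation labels only), copy-number and imprinting
aberrations of real iPSC lines, and the HMM behaviour of the original
escapee caller.  Recovery results certify the estimators and rule
implementations, not the biology.

## Numerical choices and degenerate inputs

Sub-seeds for multi-part simulations are derived arithmetically from the
user seed and stay below 2^31.  Ties in the 10-kb Xa/Xi fallback leave the
block unassigned; `m_start = 0` bins are excluded from demethylation rates
(undefined ratio) and from the ER demethylation criterion; zero pooled SD
raises for Cohen's d unless the groups are identical (d = 0); empty bin
sets, mismatched replicate bins, unknown strands, unknown class labels and
negative counts raise named errors.  Methylation-gain bins keep their
negative rate rather than being clipped.  Problem sizes in the acceptance
script (50,000 dilution sites × 3 seeds; 500 cells × 200 genes; 5,000+300
expression genes; 8,000 2-kb KO bins; 2,000 CpA bins) are chosen so
Monte-Carlo error sits well inside each stated tolerance while the whole
script completes in seconds.

## Known limitations

The escapee caller is a threshold segmentation, not an HMM, so region
boundaries on real, noisy data would differ from the original caller's.
HCP/ICP/LCP thresholds and mark-high thresholds are declared defaults, not
inferred from data.  The early/late ER split depends on the configured
stage cut.  The Xi-resistance flag is a plateau heuristic
(|Δ| < 3 points between the last two timepoints), not a changepoint test.
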