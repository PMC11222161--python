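"""X:A dosage-compensation statistic and ER-gene classification.

The X:A ratio compares the 75th percentile of log2(RPM+1) of expressed
X-linked genes (pseudo-autosomal regions excluded) to the same statistic
over expressed autosomal genes; a gene counts as expressed when its maximum
log2(RPM+1) across the analysed samples exceeds 3.  Chromosome 10 against
the remaining autosomes serves as the negative control.

ER (epigenetic-reprogramming-activated) genes are genes showing progressive
upregulation across ordered differentiation stages together with a >= 50%
relative reduction of promoter 5mC between the first and last stage; the
"redefined" ER set is the intersection of the calls from two independent
differentiation systems.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EXPRESSION_CUTOFF = 3.0  # on log2(RPM + 1), max across analysed samples


class EmptyGeneSetError(ValueError):
    """No expressed genes on a chromosome group required for the ratio."""


def _pct75(values: np.ndarray) -> float:
    # linear-interpolation percentile, stated because conventions differ
    return float(np.percentile(values, 75, method="linear"))


def xa_ratio(expr: pd.DataFrame, gene_meta: pd.DataFrame,
             samples: list[str] | None = None,
             expr_cutoff: float = EXPRESSION_CUTOFF,
             x_chrom: str = "chrX", control_chrom: str = "chr10") -> dict:
    """X:A and chr10:A expression ratios for one sample group.

    ``expr`` is a gene x sample RPM matrix (genes on the index); ``gene_meta``
    carries ``chrom`` and ``par`` per gene.  The ratio is computed from the
    75th percentile of log2(RPM+1) values pooled over the group's samples.
    """
    if samples is None:
        samples = list(expr.columns)
    log = np.log2(expr[samples] + 1.0)
    expressed = log.max(axis=1) > expr_cutoff
    meta = gene_meta.reindex(expr.index)
    is_x = (meta["chrom"] == x_chrom) & ~meta["par"].astype(bool)
    is_auto = ~(meta["chrom"] == x_chrom)
    is_ctrl = meta["chrom"] == control_chrom
    groups = {
        "x": expressed & is_x,
        "autosome": expressed & is_auto,
        "control": expressed & is_ctrl,
    }
    for name in ("x", "autosome"):
        if not groups[name].any():
            raise EmptyGeneSetError(f"no expressed {name} genes")
    reps = {}
    for name, mask in groups.items():
        if mask.any():
            reps[name] = _pct75(log[mask].to_numpy().ravel())
    out = {
        "x_a_ratio": reps["x"] / reps["autosome"],
        "n_x": int(groups["x"].sum()),
        "n_autosome": int(groups["autosome"].sum()),
    }
    if "control" in reps:
        out["chr10_a_ratio"] = reps["control"] / reps["autosome"]
        out["n_control"] = int(groups["control"].sum())
    return out


def classify_er_genes(stage_means: pd.DataFrame, promoter_5mc: pd.DataFrame,
                      min_fold: float = 2.0, demeth_fraction: float = 0.5,
                      monotone_tol: float = 0.0) -> pd.DataFrame:
    """ER calls for one differentiation condition.

    ``stage_means`` is a gene x ordered-stage matrix of mean RPM values
    (columns in stage order, >= 3 stages); ``promoter_5mc`` has ``m_start``
    and ``m_end`` columns (percent, QC-passed at both ends).  A gene passes
    upregulation when its stage means are non-decreasing (within
    ``monotone_tol`` relative dips) and the final/initial fold on RPM+1 is at
    least ``min_fold``; it passes demethylation when the relative reduction
    (m_start - m_end)/m_start is at least ``demeth_fraction``.  Genes with
    m_start = 0 are excluded with a reason, not defaulted.
    """
    if stage_means.shape[1] < 3:
        raise ValueError("need >= 3 ordered stages")
    vals = stage_means.to_numpy(dtype=float) + 1.0
    diffs = np.diff(vals, axis=1)
    floor = -monotone_tol * vals[:, :-1]
    non_decreasing = (diffs >= floor).all(axis=1)
    fold = vals[:, -1] / vals[:, 0]
    up_pass = non_decreasing & (fold >= min_fold)
    out = pd.DataFrame(index=stage_means.index)
    out["upregulation_pass"] = up_pass
    out["fold_change"] = fold
    pm = promoter_5mc.reindex(stage_means.index)
    m0 = pm["m_start"].to_numpy(dtype=float)
    m1 = pm["m_end"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        reduction = (m0 - m1) / m0
    excluded = (m0 == 0) | np.isnan(m0) | np.isnan(m1)
    out["demeth_reduction"] = np.where(excluded, np.nan, reduction)
    out["promoter_demeth_pass"] = ~excluded & (reduction >= demeth_fraction)
    out["excluded"] = excluded
    out["exclusion_reason"] = np.where(m0 == 0, "zero_start_level",
                                       np.where(excluded, "missing_promoter_level", ""))
    out["er_status"] = out["upregulation_pass"] & out["promoter_demeth_pass"] & ~excluded
    return out


def intersect_er(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                 stage_means: pd.DataFrame | None = None,
                 min_fold: float = 2.0, early_stage_cut: int = 1) -> pd.DataFrame:
    """Redefined ER genes (ER in both conditions) with an early/late split.

    A gene is "early" when its cumulative fold over the first stage reaches
    ``min_fold`` at or before stage index ``early_stage_cut`` (0-based, on
    the columns of ``stage_means``); otherwise "late".  Without stage means
    the timing column is left empty.
    """
    genes = calls_a.index.intersection(calls_b.index)
    both = calls_a.loc[genes, "er_status"] & calls_b.loc[genes, "er_status"]
    out = pd.DataFrame(index=genes)
    out["redefined_er"] = both
    out["timing"] = ""
    if stage_means is not None:
        vals = stage_means.reindex(genes).to_numpy(dtype=float) + 1.0
        fold_by_stage = vals / vals[:, :1]
        crossed = fold_by_stage >= min_fold
        first = np.where(crossed.any(axis=1), crossed.argmax(axis=1), -1)
        timing = np.where(first < 0, "never",
                          np.where(first <= early_stage_cut, "early", "late"))
        out.loc[both, "timing"] = timing[both.to_numpy()]
    return out
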