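"""Readers and writers for the pipeline's plain-text formats.

Methylation calls travel as Bismark-coverage-style TSV (chrom, start, end,
percent, count_meth, count_unmeth, plus optional context and allele
columns); intervals as BED with an optional name column; tabular results as
TSV whose header comment lines echo the thresholds that produced them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .intervals import INTERVAL_COLS
from .methylome import CALL_COLS

COVERAGE_COLS = ["chrom", "start", "end", "percent", "count_meth", "count_unmeth"]


class CoverageFormatError(ValueError):
    """Malformed methylation-coverage row (carries the 1-based line number)."""


def read_meth_coverage(path: str | Path) -> pd.DataFrame:
    """Parse a coverage-style TSV into a methylation call table.

    Counts are authoritative; the percent column is ignored.  Optional 7th
    and 8th columns are context and allele.  Malformed rows or negative
    counts raise CoverageFormatError naming the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise CoverageFormatError(f"line {lineno}: expected >= 6 columns")
            try:
                start = int(parts[1])
                m = int(parts[4])
                u = int(parts[5])
            except ValueError as exc:
                raise CoverageFormatError(f"line {lineno}: {exc}") from exc
            if m < 0 or u < 0:
                raise CoverageFormatError(f"line {lineno}: negative count")
            context = parts[6] if len(parts) > 6 else "CpG"
            allele = parts[7] if len(parts) > 7 else "unphased"
            rows.append((parts[0], start, context, m, u, allele))
    return pd.DataFrame(rows, columns=CALL_COLS)


def write_meth_coverage(calls: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            depth = row.count_meth + row.count_unmeth
            pct = 100.0 * row.count_meth / depth if depth else 0.0
            fh.write(f"{row.chrom}\t{row.start}\t{row.start + 1}\t{pct:.6g}\t"
                     f"{row.count_meth}\t{row.count_unmeth}\t{row.context}\t{row.allele}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = [*INTERVAL_COLS, "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + [f"extra{i}" for i in range(df.shape[1] - len(cols))]
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path,
              name_col: str | None = None) -> None:
    cols = list(INTERVAL_COLS) + ([name_col] if name_col else [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def write_result_tsv(df: pd.DataFrame, path: str | Path,
                     params: dict | None = None, index: bool = False) -> None:
    """TSV with '# key=value' header lines echoing producing thresholds."""
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_result_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
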