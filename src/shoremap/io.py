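"""Readers and writers for the plain-text formats the pipeline touches.

All intervals are 0-based, half-open. BED is tab-separated BED3/BED6;
bedGraph is 4-column with a numeric value; count tables are TSV with a
header ``chrom  start  end  count``.
"""

from __future__ import annotations

import pandas as pd

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    """A malformed line in an input file; message names the line number."""


def _read_tsv_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame with half-open intervals."""
    rows = []
    ncols = None
    for lineno, fields in _read_tsv_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(fields)}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        if start < 0 or start >= end:
            raise FormatError(f"{path}:{lineno}: require 0 <= start < end, got {start},{end}")
        if ncols is None:
            ncols = min(len(fields), 6)
        row = [fields[0], start, end]
        if ncols > 3:
            row += fields[3:ncols] + [None] * (ncols - len(fields))
        rows.append(row)
    df = pd.DataFrame(rows, columns=BED_COLS[: ncols or 3])
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph (chrom, start, end, value)."""
    rows = []
    for lineno, fields in _read_tsv_lines(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
        try:
            rows.append([fields[0], int(fields[1]), int(fields[2]), float(fields[3])])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric bedGraph fields") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path, value_col: str = "value") -> None:
    out = df[["chrom", "start", "end", value_col]]
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_counts(path) -> pd.DataFrame:
    """Read a per-tile count table (TSV with header chrom/start/end/count)."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "count"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: count table must have columns {sorted(need)}")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "count"]].to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path) -> dict:
    sizes = {}
    for lineno, fields in _read_tsv_lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected chrom<TAB>size")
        sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")
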