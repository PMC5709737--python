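"""Genome tiling, tile filters, read counting and log2 ChIP enrichment.

The genome is partitioned into fixed-width (default 1-kb) tiles. Tiles
overlapping blacklisted intervals, with mappability below 0.5 or with
insufficient bisulfite coverage (<= 50% of tile CpGs covered at 10x)
are removed. ChIP enrichment is the log2 ratio of IP over input after
scaling both libraries to their common mean size, regularized by a
constant pseudocount of 8 to damp sampling noise at low counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentTrack:
    """Per-tile log2 enrichment of an IP library over its input."""

    values: np.ndarray
    pseudocount: float
    ip_library_size: float
    input_library_size: float


def make_tiles(chrom_sizes: dict, width: int = 1000) -> pd.DataFrame:
    """Partition chromosomes into fixed-width tiles.

    Each chromosome contributes floor(size / width) contiguous tiles
    starting at 0; a trailing fragment shorter than ``width`` is dropped
    so every tile has identical width.
    """
    if width <= 0:
        raise ValueError(f"tile width must be positive, got {width}")
    frames = []
    for chrom, size in chrom_sizes.items():
        n = int(size) // width
        starts = np.arange(n, dtype=np.int64) * width
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def _overlaps_any(tiles: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask of tiles overlapping any interval by >= 1 bp."""
    hit = np.zeros(len(tiles), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return hit
    for chrom, sub in intervals.groupby("chrom", sort=False):
        mask = (tiles["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        ts = tiles.loc[mask, "start"].to_numpy()
        te = tiles.loc[mask, "end"].to_numpy()
        local = np.zeros(mask.sum(), dtype=bool)
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            local |= (ts < e) & (te > s)
        hit[mask] = local
    return hit


def cpg_covered_fraction(
    tiles: pd.DataFrame, cpg_coverage: pd.DataFrame, min_cov: int = 10
) -> np.ndarray:
    """Per-tile fraction of CpGs covered at least ``min_cov`` times.

    ``cpg_coverage`` needs columns chrom/pos/total (unfiltered calls).
    Tiles without any CpG get NaN: the coverage filter is vacuous there.
    Assumes the contiguous fixed-width tile frame from :func:`make_tiles`.
    """
    width = int(tiles["end"].iloc[0] - tiles["start"].iloc[0]) if len(tiles) else 1
    frac = np.full(len(tiles), np.nan)
    tile_index = {
        chrom: (np.flatnonzero((tiles["chrom"] == chrom).to_numpy()))
        for chrom in tiles["chrom"].unique()
    }
    for chrom, sub in cpg_coverage.groupby("chrom", sort=False):
        idx = tile_index.get(chrom)
        if idx is None:
            continue
        pos = sub["pos"].to_numpy()
        covered = (sub["total"].to_numpy() >= min_cov).astype(float)
        t = pos // width
        ok = t < len(idx)
        tot = np.bincount(t[ok], minlength=len(idx)).astype(float)
        cov = np.bincount(t[ok], weights=covered[ok], minlength=len(idx))
        with np.errstate(invalid="ignore", divide="ignore"):
            f = cov / tot
        frac[idx] = np.where(tot > 0, f, np.nan)
    return frac


def filter_tiles(
    tiles: pd.DataFrame,
    blacklist: pd.DataFrame | None = None,
    mappability_min: float = 0.5,
    meth_cov_min: float = 0.5,
) -> pd.DataFrame:
    """Remove blacklisted, low-mappability and poorly covered tiles.

    Blacklist removal uses any-overlap (>= 1 bp). Mappability (column
    ``mappability``) must be >= ``mappability_min``; the bisulfite
    coverage rule (column ``cpg_covered_fraction``) requires strictly
    more than ``meth_cov_min`` of a tile's CpGs covered, and is only
    applied where the column is present and finite. Removal counts per
    reason are logged and stored in ``df.attrs['filter_log']``.
    """
    keep = np.ones(len(tiles), dtype=bool)
    log = {}
    bl = _overlaps_any(tiles, blacklist)
    log["blacklist"] = int(bl.sum())
    keep &= ~bl
    if "mappability" in tiles.columns:
        low = tiles["mappability"].to_numpy() < mappability_min
        log["mappability"] = int((low & keep).sum())
        keep &= ~low
    if "cpg_covered_fraction" in tiles.columns:
        frac = tiles["cpg_covered_fraction"].to_numpy(dtype=float)
        bad = np.isfinite(frac) & ~(frac > meth_cov_min)
        log["meth_coverage"] = int((bad & keep).sum())
        keep &= ~bad
    out = tiles.loc[keep].reset_index(drop=True)
    out.attrs["filter_log"] = log
    if len(out) == 0:
        logger.warning("all tiles removed by filters: %s", log)
    else:
        logger.info("tile filters removed %s; %d tiles retained", log, len(out))
    return out


def count_track(reads: pd.DataFrame, tiles: pd.DataFrame, track: str) -> pd.DataFrame:
    """Count reads per tile by 5' start position.

    A read is assigned to the tile containing its 5'-most base (the
    ``start`` field, or ``end - 1`` for minus-strand reads). Reads on
    chromosomes absent from the tile frame, or beyond the last full
    tile, are ignored and tallied in ``attrs['ignored_reads']``.
    Requires the contiguous grid produced by :func:`make_tiles`.
    """
    out = tiles.copy()
    width = int(tiles["end"].iloc[0] - tiles["start"].iloc[0]) if len(tiles) else 1
    counts = np.zeros(len(tiles), dtype=np.int64)
    ignored = 0
    tile_index = {
        chrom: np.flatnonzero((tiles["chrom"] == chrom).to_numpy())
        for chrom in tiles["chrom"].unique()
    }
    for chrom, sub in reads.groupby("chrom", sort=False):
        idx = tile_index.get(chrom)
        if idx is None:
            logger.warning("reads on %s skipped: chromosome absent from tile frame", chrom)
            ignored += len(sub)
            continue
        pos = sub["start"].to_numpy(dtype=np.int64)
        if "strand" in sub.columns:
            minus = (sub["strand"] == "-").to_numpy()
            pos = np.where(minus, sub["end"].to_numpy(dtype=np.int64) - 1, pos)
        t = pos // width
        ok = (t >= 0) & (t < len(idx))
        ignored += int((~ok).sum())
        counts[idx] += np.bincount(t[ok], minlength=len(idx))
    out[track] = counts
    out.attrs["ignored_reads"] = ignored
    return out


def log2_enrichment(
    ip: np.ndarray,
    input_counts: np.ndarray,
    pseudocount: float = 8.0,
    ip_library_size: float | None = None,
    input_library_size: float | None = None,
) -> EnrichmentTrack:
    """log2((IP_norm + c) / (input_norm + c)) per tile.

    Both tracks are scaled to the mean of the two library sizes before
    the pseudocount ``c`` is added, keeping values on a count-like scale
    so that c = 8 retains its meaning.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    ip = np.asarray(ip, dtype=float)
    inp = np.asarray(input_counts, dtype=float)
    ls_ip = float(ip.sum()) if ip_library_size is None else float(ip_library_size)
    ls_in = float(inp.sum()) if input_library_size is None else float(input_library_size)
    if ls_ip <= 0 or ls_in <= 0:
        raise ValueError("library sizes must be positive")
    target = 0.5 * (ls_ip + ls_in)
    e = np.log2((ip * target / ls_ip + pseudocount) / (inp * target / ls_in + pseudocount))
    return EnrichmentTrack(e, pseudocount, ls_ip, ls_in)


def cross_correlation(tracks: dict, pseudocount: float = 8.0) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2-transformed tile counts.

    Counts are offset by the pseudocount before the log2 transform.
    Constant tracks have undefined correlation and are reported as NaN
    (not 0); the diagonal is exactly 1.
    """
    names = list(tracks)
    if len(names) < 2:
        raise ValueError("cross_correlation needs at least two tracks")
    X = np.column_stack([np.log2(np.asarray(tracks[n], dtype=float) + pseudocount) for n in names])
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)
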