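"""Anchored meta-profiles, signal clustering, binding dynamics and
promoter-class enrichment.

Profiles allocate per-tile counts into fixed-width bins around anchor
points (or length-scaled gene bodies) by fractional overlap, assuming
reads are uniform within a tile; rows are strand-flipped so column 0
is always 5', and normalized to reads per bin per 1e7 library reads.
UMR rows are clustered with k-means on log2(signal + 8). ES-to-NP
binding dynamics are pseudocounted log2 fold changes per tile, and
class enrichment of deregulated genes uses the upper-tail
hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score  # noqa: F401  (re-exported convenience)

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Anchors x position-bins matrix of library-normalized signal."""

    matrix: np.ndarray
    bin_edges: np.ndarray        # relative bp (anchor profiles) or bin index (scaled)
    anchors: pd.DataFrame
    track: str
    norm: float
    library_size: float

    def column_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)


@dataclass
class ClusterResult:
    labels: np.ndarray           # -1 for rows excluded as incomplete
    centroids: np.ndarray
    k: int
    seed: int
    inertia: float
    row_mask: np.ndarray


class _TileSignal:
    """Piecewise-constant read density from a fixed-width tile grid."""

    def __init__(self, tiles: pd.DataFrame, count_col: str = "count"):
        self.width = int(tiles["end"].iloc[0] - tiles["start"].iloc[0])
        self.chrom = {}
        for chrom, sub in tiles.groupby("chrom", sort=False):
            idx = sub["start"].to_numpy() // self.width
            arr = np.zeros(int(idx.max()) + 1)
            arr[idx] = sub[count_col].to_numpy(dtype=float)
            self.chrom[chrom] = np.concatenate([[0.0], np.cumsum(arr)])
        self.library_size = float(tiles[count_col].sum())

    def interval_sums(self, chrom: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Signal mass in [a, b) assuming uniform reads within tiles."""
        cum = self.chrom.get(chrom)
        if cum is None:
            return np.zeros(len(a))
        w = self.width
        span = (len(cum) - 1) * w

        def F(x):
            x = np.clip(x, 0, span)
            t = (x // w).astype(np.int64)
            t = np.minimum(t, len(cum) - 2)
            counts = cum[t + 1] - cum[t]
            return cum[t] + counts * (x - t * w) / w

        return F(np.asarray(b, dtype=float)) - F(np.asarray(a, dtype=float))


def anchor_profile(
    tiles: pd.DataFrame,
    anchors: pd.DataFrame,
    flank_bp: int,
    bin_bp: int,
    track: str = "signal",
    count_col: str = "count",
    chrom_sizes: dict | None = None,
    library_size: float | None = None,
    norm: float = 1e7,
) -> ProfileMatrix:
    """Binned signal around anchor points, strand-flipped and normalized.

    ``anchors`` needs chrom/pos (+ optional strand). Bins cover
    [-flank, +flank) in steps of ``bin_bp``; minus-strand rows are
    reversed so the first column is always 5' of the anchor. Windows
    running past a chromosome end are NaN-padded and excluded from
    column means.
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be divisible by bin_bp")
    sig = _TileSignal(tiles, count_col)
    lib = sig.library_size if library_size is None else float(library_size)
    n_bins = 2 * flank_bp // bin_bp
    edges = -flank_bp + np.arange(n_bins + 1) * bin_bp
    M = np.empty((len(anchors), n_bins))
    scale = norm / lib
    for r, (_, a) in enumerate(anchors.iterrows()):
        lo = a.pos + edges[:-1]
        hi = a.pos + edges[1:]
        row = sig.interval_sums(a.chrom, lo, hi) * scale
        size = None if chrom_sizes is None else chrom_sizes.get(a.chrom)
        if size is not None:
            row = np.where((lo >= 0) & (hi <= size), row, np.nan)
        if a.get("strand", "+") == "-":
            row = row[::-1]
        M[r] = row
    return ProfileMatrix(M, edges, anchors.reset_index(drop=True), track, norm, lib)


def scaled_gene_profile(
    tiles: pd.DataFrame,
    genes: pd.DataFrame,
    n_body_bins: int = 20,
    flank_bp: int = 2000,
    bin_bp: int = 500,
    track: str = "signal",
    count_col: str = "count",
    library_size: float | None = None,
    norm: float = 1e7,
) -> ProfileMatrix:
    """Meta-gene profile: fixed flanks plus a length-scaled gene body.

    Overlapping genes are dropped (logged), as are genes shorter than
    ``n_body_bins`` bp. Rows are strand-oriented 5'->3'. Body bins are
    rescaled to equal signal density units (mass per bin scaled by the
    bin's bp width) so a spatially constant track stays flat across
    the flank/body boundary.
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be divisible by bin_bp")
    keep = _drop_overlapping(genes)
    n_dropped = len(genes) - keep.sum()
    if n_dropped:
        logger.info("scaled_gene_profile: dropped %d overlapping genes", n_dropped)
    genes = genes[keep]
    long_enough = (genes["end"] - genes["start"]) >= n_body_bins
    if (~long_enough).any():
        logger.info("scaled_gene_profile: dropped %d genes shorter than %d bp",
                    int((~long_enough).sum()), n_body_bins)
    genes = genes[long_enough].reset_index(drop=True)

    sig = _TileSignal(tiles, count_col)
    lib = sig.library_size if library_size is None else float(library_size)
    n_flank = flank_bp // bin_bp
    n_bins = 2 * n_flank + n_body_bins
    M = np.empty((len(genes), n_bins))
    scale = norm / lib
    for r, (_, g) in enumerate(genes.iterrows()):
        up = g.start + np.arange(-n_flank, 1) * bin_bp
        body = g.start + np.round(np.linspace(0, g.end - g.start, n_body_bins + 1)).astype(int)
        down = g.end + np.arange(0, n_flank + 1) * bin_bp
        vals = np.concatenate([
            sig.interval_sums(g.chrom, up[:-1], up[1:]),
            sig.interval_sums(g.chrom, body[:-1], body[1:])
            * (bin_bp / np.maximum(np.diff(body), 1)),  # rescale body bins to flank density units
            sig.interval_sums(g.chrom, down[:-1], down[1:]),
        ]) * scale
        if g.get("strand", "+") == "-":
            vals = vals[::-1]
        M[r] = vals
    return ProfileMatrix(M, np.arange(n_bins + 1), genes, track, norm, lib)


def _drop_overlapping(genes: pd.DataFrame) -> np.ndarray:
    keep = np.ones(len(genes), dtype=bool)
    g = genes.reset_index(drop=True)
    for chrom, sub in g.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if s[b] < e[a] and e[b] > s[a]:
                    keep[idx[a]] = keep[idx[b]] = False
    return keep


def cluster_umrs(
    profile: ProfileMatrix,
    k: int = 5,
    seed: int = 0,
    pseudocount: float = 8.0,
    n_init: int = 10,
) -> ClusterResult:
    """k-means clustering of profile rows on log2(signal + pseudocount).

    Rows containing missing values are excluded (label -1). Uses
    k-means++ initialization with ``n_init`` restarts keeping the
    lowest inertia; the seed is recorded in the result.
    """
    mask = np.isfinite(profile.matrix).all(axis=1)
    X = np.log2(profile.matrix[mask] + pseudocount)
    if X.shape[0] < k:
        raise ValueError(f"only {X.shape[0]} complete rows for k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    fitted = km.fit(X)
    labels = np.full(len(mask), -1, dtype=np.int64)
    labels[mask] = fitted.labels_
    return ClusterResult(labels, fitted.cluster_centers_, k, seed, float(fitted.inertia_), mask)


def differential_binding(
    es_counts: np.ndarray,
    np_counts: np.ndarray,
    pseudocount: float = 8.0,
    es_library_size: float | None = None,
    np_library_size: float | None = None,
    restrict: np.ndarray | None = None,
) -> np.ndarray:
    """Per-tile log2 fold change of NP over ES binding.

    Both libraries are scaled to their mean size and regularized by the
    pseudocount, so identical libraries give exactly 0 and swapping
    conditions flips the sign. ``restrict`` masks tiles outside the
    analysis set (e.g. H3K27me3-positive in either condition) to NaN.
    """
    es = np.asarray(es_counts, dtype=float)
    npc = np.asarray(np_counts, dtype=float)
    if es.shape != npc.shape:
        raise ValueError("ES and NP tracks must share a tile frame")
    ls_es = float(es.sum()) if es_library_size is None else float(es_library_size)
    ls_np = float(npc.sum()) if np_library_size is None else float(np_library_size)
    target = 0.5 * (ls_es + ls_np)
    fc = np.log2((npc * target / ls_np + pseudocount) / (es * target / ls_es + pseudocount))
    if restrict is not None:
        fc = np.where(restrict, fc, np.nan)
    return fc


def ranked_window_medians(
    values: np.ndarray, rank_key: np.ndarray, block: int = 500
) -> pd.DataFrame:
    """Block medians of ``values`` over windows ranked by ``rank_key``.

    Tiles are sorted by the key (ascending, stable) and cut into
    consecutive non-overlapping blocks of ``block`` tiles; a final
    short block is kept on its own if it holds at least half a block,
    otherwise merged into the previous one. Returns per-block median
    value and mean rank key.
    """
    values = np.asarray(values, dtype=float)
    rank_key = np.asarray(rank_key, dtype=float)
    if values.shape != rank_key.shape:
        raise ValueError("values and rank_key must be aligned")
    n = len(values)
    if n < (block + 1) // 2:
        raise ValueError(f"need at least {(block + 1) // 2} windows for block size {block}")
    order = np.argsort(rank_key, kind="mergesort")
    bounds = list(range(0, n, block)) + [n]
    if len(bounds) >= 3 and bounds[-1] - bounds[-2] < (block + 1) // 2:
        del bounds[-2]  # merge the short tail into the previous block
    rows = []
    for b, (i0, i1) in enumerate(zip(bounds[:-1], bounds[1:])):
        idx = order[i0:i1]
        rows.append((b, float(np.mean(rank_key[idx])), float(np.median(values[idx])), i1 - i0))
    return pd.DataFrame(rows, columns=["block", "mean_rank_key", "median_value", "n"])


def promoter_class_enrichment(
    up_genes: set, class_membership: dict, universe: set
) -> pd.DataFrame:
    """Fraction and hypergeometric p of deregulated genes per class.

    For each class C: fraction = |up & C| / |C| and p is the upper
    tail P(X >= |up & C|) of a hypergeometric draw of |C| genes from
    the universe containing |up| successes. Empty classes are skipped
    with a warning; significance is reported at p < 0.05.
    """
    up_genes = set(up_genes)
    universe = set(universe)
    if not up_genes <= universe:
        raise ValueError("up_genes must be a subset of the universe")
    M, n_up = len(universe), len(up_genes)
    rows = []
    for name, members in class_membership.items():
        members = set(members) & universe
        if not members:
            logger.warning("promoter class %r is empty; skipped", name)
            continue
        N = len(members)
        k = len(up_genes & members)
        p = float(stats.hypergeom.sf(k - 1, M, n_up, N))
        rows.append((name, N, k, k / N, p, p < 0.05))
    return pd.DataFrame(
        rows, columns=["class", "n_class", "n_up", "fraction", "p_value", "significant"]
    )
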