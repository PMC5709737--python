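"""CpG island detection, promoter linkage, bivalency classes and shores.

Islands are detected by distance clustering: consecutive CpGs whose
spacing is at most the chromosome-wide median inter-CpG distance merge
into clusters, retained as islands if they hold enough CpGs and span
at least 200 bp. Promoter-overlapping islands are linked to a gene,
classified as unmethylated (< 20% mean m-CpG) or methylated, and
unmethylated islands are binned as bivalent when both H3K4me3 and
H3K27me3 tile enrichments exceed a cutoff. Shores are fixed-width
windows immediately flanking the island, oriented by gene strand.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .methylome import regions_methylation

logger = logging.getLogger(__name__)


def detect_islands(cpg_positions: pd.DataFrame, min_len: int = 200, min_cpgs: int = 10) -> pd.DataFrame:
    """Cluster CpGs into islands by the median-gap rule.

    ``cpg_positions`` needs chrom/pos columns, sorted per chromosome.
    Cluster bounds are the outermost member CpGs (end exclusive at the
    last CpG + 1); clusters shorter than ``min_len`` bp or with fewer
    than ``min_cpgs`` CpGs are discarded.
    """
    rows = []
    for chrom, sub in cpg_positions.groupby("chrom", sort=False):
        pos = np.sort(sub["pos"].to_numpy())
        if len(pos) < 2:
            logger.warning("detect_islands: %s has < 2 CpGs, no islands", chrom)
            continue
        gaps = np.diff(pos)
        med = np.median(gaps)
        breaks = np.flatnonzero(gaps > med)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for i0, i1 in zip(starts, ends):
            n = i1 - i0
            span = pos[i1 - 1] - pos[i0] + 1
            if n >= min_cpgs and span >= min_len:
                rows.append((chrom, int(pos[i0]), int(pos[i1 - 1]) + 1, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs"])


def link_promoters(islands: pd.DataFrame, promoters: pd.DataFrame) -> pd.DataFrame:
    """Keep promoter-overlapping islands and attach the linked gene.

    Any overlap (>= 1 bp) counts. When an island overlaps several
    promoters it is linked to the one with the largest overlap, ties
    going to the promoter with the genomically 5'-most (smallest) TSS.
    """
    proms = promoters.copy()
    if "tss" not in proms.columns:
        proms["tss"] = np.where(proms["strand"] == "-", proms["end"] - 1, proms["start"])
    out = []
    for _, isl in islands.iterrows():
        cand = proms[(proms["chrom"] == isl.chrom)
                     & (proms["start"] < isl.end) & (proms["end"] > isl.start)]
        if len(cand) == 0:
            continue
        ov = np.minimum(cand["end"], isl.end) - np.maximum(cand["start"], isl.start)
        cand = cand.assign(ov=ov).sort_values(["ov", "tss"], ascending=[False, True],
                                              kind="mergesort")
        best = cand.iloc[0]
        row = isl.to_dict()
        row["gene"] = best["name"]
        row["strand"] = best["strand"]
        out.append(row)
    return pd.DataFrame(out).reset_index(drop=True)


def classify_islands(
    islands: pd.DataFrame,
    calls: pd.DataFrame,
    tiles: pd.DataFrame,
    k4_col: str = "H3K4me3",
    k27_col: str = "H3K27me3",
    e_min: float = 1.0,
    meth_threshold: float = 20.0,
) -> pd.DataFrame:
    """Attach methylation and chromatin classes to promoter islands.

    Mean m-CpG below ``meth_threshold`` percent makes an island
    unmethylated. Among unmethylated islands, overlap-weighted mean
    log2 enrichment over the island's filtered tiles decides the
    chromatin class: bivalent when both H3K4me3 and H3K27me3 means are
    >= ``e_min``; H3K27me3-negative when only H3K4me3 passes; else
    unclassified. Islands without any overlapping filtered tile stay
    unclassified (logged).
    """
    out = islands.copy()
    out["meth_pct"] = regions_methylation(out, calls)
    out["meth_class"] = np.where(out["meth_pct"] < meth_threshold, "unmethylated", "methylated")

    k4 = np.full(len(out), np.nan)
    k27 = np.full(len(out), np.nan)
    for chrom, sub in out.groupby("chrom", sort=False):
        t = tiles[tiles["chrom"] == chrom]
        ts, te = t["start"].to_numpy(), t["end"].to_numpy()
        v4 = t[k4_col].to_numpy(dtype=float)
        v27 = t[k27_col].to_numpy(dtype=float)
        for i, isl in sub.iterrows():
            ov = np.minimum(te, isl.end) - np.maximum(ts, isl.start)
            w = np.clip(ov, 0, None).astype(float)
            if w.sum() == 0:
                logger.info("island %s:%d-%d has no filtered tile; unclassified",
                            isl.chrom, isl.start, isl.end)
                continue
            k4[out.index.get_loc(i)] = np.average(v4, weights=w)
            k27[out.index.get_loc(i)] = np.average(v27, weights=w)
    out["k4_enrichment"] = k4
    out["k27_enrichment"] = k27

    cls = np.array(["unclassified"] * len(out), dtype=object)
    unmeth = out["meth_class"].to_numpy() == "unmethylated"
    cls[unmeth & (k4 >= e_min) & (k27 >= e_min)] = "bivalent"
    cls[unmeth & (k4 >= e_min) & ~(k27 >= e_min)] = "H3K27me3-negative"
    out["chrom_class"] = cls
    return out


def define_shores(
    islands: pd.DataFrame, width: int = 2000, chrom_sizes: dict | None = None
) -> pd.DataFrame:
    """Fixed-width shore intervals flanking each island.

    The left shore is [start - width, start) and the right shore
    [end, end + width), clipped at chromosome bounds (flagged). 5'/3'
    labels follow the linked gene strand: for plus-strand genes the
    left shore is 5'.
    """
    rows = []
    for i, isl in islands.iterrows():
        size = None if chrom_sizes is None else chrom_sizes.get(isl.chrom)
        strand = isl.get("strand", "+")
        for side_geom, s, e in (("left", isl.start - width, isl.start),
                                ("right", isl.end, isl.end + width)):
            cs, ce = max(s, 0), e if size is None else min(e, size)
            clipped = (cs, ce) != (s, e)
            if ce <= cs:
                continue
            if strand == "+":
                label = "5p" if side_geom == "left" else "3p"
            else:
                label = "3p" if side_geom == "left" else "5p"
            rows.append((isl.chrom, int(cs), int(ce), label, isl.get("gene", "."),
                         strand, clipped, i))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "side", "gene", "strand", "clipped", "island_index"]
    )
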