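"""Bisulfite-call aggregation and UMR/LMR/FMR methylome segmentation.

Per-CpG calls are coverage-filtered (strictly >10x for WGBS, >20x for
RRBS) and SNP-masked CpGs removed. The methylome is segmented into
unmethylated (UMR), low-methylated (LMR) and fully methylated (FMR)
regions by a run-based rule: per-CpG fractions are smoothed with a
3-CpG running mean, maximal runs of at least 4 consecutive CpGs with
smoothed fraction <= 0.5 (and inter-CpG gaps within a cap) become
hypomethylated segments, split into UMRs (>= 30 CpGs) and LMRs; the
remaining covered runs are FMRs. UMR borders are taken from the end
and start of the flanking FMRs and oriented by the linked gene.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SegmentationParams
from .io import FormatError

logger = logging.getLogger(__name__)

COVERAGE_RULES = {"WGBS": 10, "RRBS": 20}  # keep CpGs with total strictly greater


def load_calls(path, assay: str = "WGBS", snp_mask: pd.DataFrame | None = None) -> pd.DataFrame:
    """Load per-CpG calls and apply coverage and SNP filters.

    Expects the 6-column text written by the fixture/pipeline
    (chrom, start, end, meth, total, percent) or any TSV with at least
    chrom/start/meth/total columns. Positions refer to the C of the
    CpG on the plus strand, 0-based.
    """
    if assay not in COVERAGE_RULES:
        raise ValueError(f"assay must be one of {sorted(COVERAGE_RULES)}")
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "meth", "total"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: per-CpG table must have columns {sorted(need)}")
    bad = df.index[df["meth"] > df["total"]]
    if len(bad):
        raise FormatError(f"{path}: line {bad[0] + 2}: methylated count exceeds total")
    n0 = len(df)
    df = df[df["total"] > COVERAGE_RULES[assay]]
    n_cov = n0 - len(df)
    n_snp = 0
    if snp_mask is not None and len(snp_mask):
        keep = np.ones(len(df), dtype=bool)
        pos = df["start"].to_numpy()
        for chrom, sub in snp_mask.groupby("chrom", sort=False):
            cmask = (df["chrom"] == chrom).to_numpy()
            for s, e in zip(sub["start"], sub["end"]):
                keep &= ~(cmask & (pos >= s) & (pos < e))
        n_snp = int((~keep).sum())
        df = df[keep]
    logger.info("load_calls: dropped %d under-covered and %d SNP-masked of %d CpGs",
                n_cov, n_snp, n0)
    out = df.rename(columns={"start": "pos"})[["chrom", "pos", "meth", "total"]].copy()
    out["frac"] = out["meth"] / out["total"]
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _calls_in(calls: pd.DataFrame, chrom, start, end) -> pd.DataFrame:
    sub = calls[calls["chrom"] == chrom]
    pos = sub["pos"].to_numpy()
    lo, hi = np.searchsorted(pos, [start, end])
    return sub.iloc[lo:hi]


def region_methylation(region, calls: pd.DataFrame) -> float:
    """Mean per-CpG methylation fraction in a region, as percent.

    Unweighted mean of the per-CpG fractions (each covered CpG counts
    once, regardless of its depth). NaN when the region has no
    retained CpG -- absence of evidence is not 0% methylation.
    """
    chrom, start, end = region
    sub = _calls_in(calls, chrom, start, end)
    if len(sub) == 0:
        return float("nan")
    return 100.0 * float(sub["frac"].mean())


def cpg_density(region, calls: pd.DataFrame) -> float:
    """Retained CpGs per 100 bp of region length."""
    chrom, start, end = region
    if end <= start:
        raise ValueError("region length must be positive")
    return 100.0 * len(_calls_in(calls, chrom, start, end)) / (end - start)


def regions_methylation(regions: pd.DataFrame, calls: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`region_methylation` over an interval frame."""
    out = np.full(len(regions), np.nan)
    regions = regions.reset_index(drop=True)
    for chrom, sub in regions.groupby("chrom", sort=False):
        c = calls[calls["chrom"] == chrom]
        pos = c["pos"].to_numpy()
        frac = c["frac"].to_numpy()
        cum = np.concatenate([[0.0], np.cumsum(frac)])
        lo = np.searchsorted(pos, sub["start"].to_numpy())
        hi = np.searchsorted(pos, sub["end"].to_numpy())
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            m = (cum[hi] - cum[lo]) / n
        out[sub.index.to_numpy()] = np.where(n > 0, 100.0 * m, np.nan)
    return out


def _smooth(frac: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean over ``window`` CpGs, truncated at the ends."""
    half = window // 2
    cum = np.concatenate([[0.0], np.cumsum(frac)])
    n = len(frac)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cum[hi] - cum[lo]) / (hi - lo)


def segment_methylome(calls: pd.DataFrame, params: SegmentationParams | None = None) -> pd.DataFrame:
    """Segment retained CpGs into UMR/LMR/FMR intervals.

    Returns a frame with chrom, start, end, seg_class, n_cpgs,
    mean_meth and the member-CpG index range [cpg_lo, cpg_hi) into the
    chromosome-sorted ``calls``. Segment bounds snap to the outermost
    member CpGs (end exclusive at last CpG + 1). Chromosomes with
    fewer CpGs than the smoothing window are skipped with a warning.
    """
    params = params or SegmentationParams()
    rows = []
    offset = 0
    for chrom, sub in calls.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        frac = sub["frac"].to_numpy()
        n = len(sub)
        if n < params.smooth_window:
            logger.warning("segment_methylome: %s skipped (%d CpGs < window)", chrom, n)
            offset += n
            continue
        sm = _smooth(frac, params.smooth_window)
        hypo = sm <= params.hypo_cutoff
        big_gap = np.concatenate([[True], np.diff(pos) > params.max_gap_bp])

        # maximal hypomethylated runs, broken at large gaps
        seg_id = np.full(n, -1, dtype=np.int64)
        next_id = 0
        i = 0
        while i < n:
            if not hypo[i]:
                i += 1
                continue
            j = i + 1
            while j < n and hypo[j] and not big_gap[j]:
                j += 1
            if j - i >= params.min_run_cpgs:
                seg_id[i:j] = next_id
                next_id += 1
            i = j
        hypo_member = seg_id >= 0

        def emit(i0, i1, cls):
            rows.append((
                chrom, int(pos[i0]), int(pos[i1 - 1]) + 1, cls, i1 - i0,
                float(frac[i0:i1].mean()), offset + i0, offset + i1,
            ))

        # hypo segments
        i = 0
        while i < n:
            if hypo_member[i]:
                j = i
                while j < n and seg_id[j] == seg_id[i]:
                    j += 1
                emit(i, j, "UMR" if j - i >= params.umr_min_cpgs else "LMR")
                i = j
            else:
                i += 1
        # complementary FMR runs, broken at hypo segments and large gaps
        i = 0
        while i < n:
            if not hypo_member[i]:
                j = i + 1
                while j < n and not hypo_member[j] and not big_gap[j]:
                    j += 1
                emit(i, j, "FMR")
                i = j
            else:
                i += 1
        offset += n
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "seg_class", "n_cpgs", "mean_meth", "cpg_lo", "cpg_hi"],
    )
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def filter_segments_for_profiles(
    segments: pd.DataFrame, min_distance: int = 6000, fmr_min_len: int = 12000
) -> pd.DataFrame:
    """Keep segments usable for non-overlapping meta-profiles.

    UMRs/LMRs within ``min_distance`` bp of another UMR/LMR are dropped
    (both members); FMRs shorter than ``fmr_min_len`` are dropped.
    """
    keep = np.ones(len(segments), dtype=bool)
    is_hypo = segments["seg_class"].isin(["UMR", "LMR"]).to_numpy()
    for chrom, sub in segments[is_hypo].groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                gap = max(starts[b], starts[a]) - min(ends[a], ends[b])
                if gap <= min_distance:
                    keep[idx[a]] = keep[idx[b]] = False
    is_fmr = (segments["seg_class"] == "FMR").to_numpy()
    short = (segments["end"] - segments["start"]).to_numpy() < fmr_min_len
    keep &= ~(is_fmr & short)
    return segments[keep].reset_index(drop=True)


def fmr_density_bins(fmrs: pd.DataFrame, calls: pd.DataFrame, n_bins: int = 3) -> np.ndarray:
    """Bin FMRs into equal-size groups by methyl-CpG density.

    Density is the number of methylated CpGs (fraction >= 0.5) per
    100 bp. FMRs are ranked by density (ties broken by genomic order)
    and split into ``n_bins`` groups, remainders going to the lowest
    bins first; labels 1..n_bins in increasing density.
    """
    if len(fmrs) < n_bins:
        raise ValueError(f"need at least {n_bins} FMRs, got {len(fmrs)}")
    dens = np.empty(len(fmrs))
    meth_calls = calls[calls["frac"] >= 0.5]
    for k, (i, r) in enumerate(fmrs.iterrows()):
        dens[k] = 100.0 * len(_calls_in(meth_calls, r.chrom, r.start, r.end)) / (r.end - r.start)
    order = np.argsort(dens, kind="mergesort")  # stable: ties stay in genomic order
    n = len(fmrs)
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    labels = np.empty(n, dtype=np.int64)
    pos = 0
    for b, size in enumerate(sizes, start=1):
        labels[order[pos : pos + size]] = b
        pos += size
    return labels


def umr_borders(
    umrs: pd.DataFrame,
    fmrs: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_flank: int = 1000,
) -> pd.DataFrame:
    """Oriented border points of promoter-linked UMRs.

    A UMR is linked to the gene whose promoter (TSS +/- flank) it
    overlaps most. Its borders are the end of the nearest preceding
    FMR and the start of the nearest following FMR; the 5'/3' side
    labels follow the linked gene's strand (minus-strand genes swap).
    Missing flanking FMRs leave that border out, logged.
    """
    proms = promoters(genes, promoter_flank)
    rows = []
    for ui, u in umrs.iterrows():
        cand = proms[(proms["chrom"] == u.chrom)
                     & (proms["start"] < u.end) & (proms["end"] > u.start)]
        if len(cand) == 0:
            continue
        ov = np.minimum(cand["end"], u.end) - np.maximum(cand["start"], u.start)
        cand = cand.assign(ov=ov).sort_values(["ov", "tss"], ascending=[False, True],
                                              kind="mergesort")
        gene = cand.iloc[0]
        fsub = fmrs[fmrs["chrom"] == u.chrom]
        prev = fsub[fsub["end"] <= u.start]
        nxt = fsub[fsub["start"] >= u.end]
        for which, side_plus in (("prev", "5p"), ("next", "3p")):
            if which == "prev":
                if len(prev) == 0:
                    logger.info("UMR %s:%d-%d has no preceding FMR", u.chrom, u.start, u.end)
                    continue
                bpos = int(prev["end"].max())
            else:
                if len(nxt) == 0:
                    logger.info("UMR %s:%d-%d has no following FMR", u.chrom, u.start, u.end)
                    continue
                bpos = int(nxt["start"].min())
            side = side_plus if gene["strand"] == "+" else ("3p" if side_plus == "5p" else "5p")
            rows.append((u.chrom, bpos, side, gene["name"], gene["strand"],
                         int(u.start), int(u.end), ui))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "side", "gene", "strand", "umr_start", "umr_end", "umr_index"]
    )


def promoters(genes: pd.DataFrame, flank: int = 1000) -> pd.DataFrame:
    """Promoter windows TSS +/- flank, strand-aware."""
    tss = np.where(genes["strand"] == "-", genes["end"].to_numpy() - 1, genes["start"].to_numpy())
    return pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": np.maximum(tss - flank, 0),
            "end": tss + flank,
            "name": genes["name"].to_numpy(),
            "strand": genes["strand"].to_numpy(),
            "tss": tss,
        }
    )
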