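"""Recovery metrics of the analysis against the synthetic ground truth.

Everything here is evaluation-only: the functions run the pipeline's
own operations on a generated fixture and score the results against
the truth ledger (planted bound tiles, island classes, UMR intervals,
border positions). Used by the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import islands as isl_mod
from . import methylome, profiles, regions, synthetic, tiles
from .config import PipelineConfig


@dataclass
class FixtureRun:
    """A fully analyzed synthetic fixture."""

    config: synthetic.SyntheticConfig
    pipe: PipelineConfig
    truth: synthetic.SyntheticTruth
    counts: dict                 # track -> per-tile count DataFrame
    calls: pd.DataFrame          # filtered CpG calls
    enrichment: dict             # track -> per-tile log2 enrichment array
    results: dict                # DNMT track -> test_track DataFrame
    bound: regions.BoundRegionSet
    segments: pd.DataFrame
    islands: pd.DataFrame        # classified promoter islands
    shores: pd.DataFrame
    borders: pd.DataFrame


DNMT_TRACKS = ("DNMT3A1", "DNMT3A2", "DNMT3B")
CHROMATIN_TRACKS = ("H3K27me3", "H3K4me3", "H3K36me3", "5hmC")


def run_fixture(config: synthetic.SyntheticConfig, pipe: PipelineConfig | None = None) -> FixtureRun:
    """Generate a fixture and run the full analysis chain on it."""
    pipe = pipe or PipelineConfig(seed=config.seed)
    truth = synthetic.generate_truth(config)
    counts = {t: synthetic.simulate_chip(truth, config, t) for t in config.fold_map}
    raw_calls = synthetic.simulate_bisulfite(truth, config)
    calls = raw_calls[raw_calls["total"] > pipe.wgbs_min_cov].copy()
    calls["frac"] = calls["meth"] / calls["total"]
    calls = calls.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    inp = counts["input"]["count"].to_numpy()
    enrichment = {
        t: tiles.log2_enrichment(counts[t]["count"].to_numpy(), inp, pipe.pseudocount).values
        for t in config.fold_map
        if t != "input"
    }
    results = {
        t: regions.test_track(counts[t]["count"].to_numpy(), inp,
                              fold_min=pipe.fold_min, padj_max=pipe.padj_max)
        for t in DNMT_TRACKS
    }
    bound = regions.call_and_partition(results, pipe.fold_min, pipe.padj_max,
                                       tile_frame=truth.tile_classes)

    segments = methylome.segment_methylome(calls, pipe.segmentation)

    detected = isl_mod.detect_islands(calls, pipe.island_min_len, pipe.island_min_cpgs)
    proms = methylome.promoters(truth.genes, pipe.promoter_flank)
    linked = isl_mod.link_promoters(detected, proms)
    tile_frame = truth.tile_classes[["chrom", "start", "end"]].copy()
    tile_frame["H3K4me3"] = enrichment["H3K4me3"]
    tile_frame["H3K27me3"] = enrichment["H3K27me3"]
    classified = isl_mod.classify_islands(linked, calls, tile_frame,
                                          e_min=pipe.e_min, meth_threshold=pipe.meth_threshold)
    shores = isl_mod.define_shores(classified, pipe.shore_width, truth.chrom_sizes)

    umrs = segments[segments["seg_class"] == "UMR"]
    fmrs = segments[segments["seg_class"] == "FMR"]
    borders = methylome.umr_borders(umrs, fmrs, truth.genes, pipe.promoter_flank)
    return FixtureRun(config, pipe, truth, counts, calls, enrichment, results, bound,
                      segments, classified, shores, borders)


def bound_tile_recovery(run: FixtureRun, track: str = "DNMT3A1") -> dict:
    """Sensitivity/precision of exclusive calls against planted tiles."""
    truth_mask = run.truth.expected_bound_tiles(track, run.config.fold_map)
    called = np.zeros(len(truth_mask), dtype=bool)
    called[run.bound.exclusive(track)] = True
    tp = int((called & truth_mask).sum())
    fp = int((called & ~truth_mask).sum())
    fn = int((truth_mask & ~called).sum())
    return {
        "sensitivity": tp / max(tp + fn, 1),
        "precision": tp / max(tp + fp, 1),
        "n_planted": int(truth_mask.sum()),
        "n_called": int(called.sum()),
    }


def _mean_linear_enrichment(run: FixtureRun, track: str, mask: np.ndarray) -> float:
    """Mean pseudocounted IP/input ratio over a tile subset."""
    c = run.pipe.pseudocount
    ip = run.counts[track]["count"].to_numpy(dtype=float)
    inp = run.counts["input"]["count"].to_numpy(dtype=float)
    target = 0.5 * (ip.sum() + inp.sum())
    ratio = (ip * target / ip.sum() + c) / (inp * target / inp.sum() + c)
    return float(ratio[mask].mean())


def shore_contrast(run: FixtureRun, track: str) -> dict:
    """Enrichment of a track at bivalent shores vs centers/active shores."""
    cls = run.truth.tile_classes["region_class"].to_numpy()
    biv_shore = np.isin(cls, ["bivalent_shore", "bivalent_border"])
    biv_center = cls == "bivalent_center"
    act_shore = np.isin(cls, ["active_shore", "active_border"])
    e_shore = _mean_linear_enrichment(run, track, biv_shore)
    e_center = _mean_linear_enrichment(run, track, biv_center)
    e_act = _mean_linear_enrichment(run, track, act_shore)
    return {
        "shore_vs_center": e_shore / e_center,
        "shore_vs_active_shore": e_shore / e_act,
        "n_shore_tiles": int(biv_shore.sum()),
    }


def umr_boundary_error(run: FixtureRun) -> dict:
    """CpG-count distance between planted and recovered UMR boundaries.

    Each planted island (its interior is the planted UMR) is matched
    to the overlapping recovered UMR; the error per side is the number
    of retained CpGs strictly between the planted edge and the
    recovered edge. Unmatched planted UMRs count as missing.
    """
    umrs = run.segments[run.segments["seg_class"] == "UMR"]
    errors = []
    missed = 0
    for _, isl in run.truth.umrs.iterrows():
        cand = umrs[(umrs["chrom"] == isl.chrom)
                    & (umrs["start"] < isl.end) & (umrs["end"] > isl.start)]
        if len(cand) == 0:
            missed += 1
            continue
        ov = np.minimum(cand["end"], isl.end) - np.maximum(cand["start"], isl.start)
        seg = cand.iloc[int(np.argmax(ov))]
        pos = run.calls.loc[run.calls["chrom"] == isl.chrom, "pos"].to_numpy()
        for planted, found in ((isl.start, seg.start), (isl.end, seg.end)):
            lo, hi = sorted((planted, found))
            errors.append(int(((pos > lo) & (pos < hi)).sum()))
    return {
        "max_error_cpgs": int(max(errors)) if errors else np.nan,
        "mean_error_cpgs": float(np.mean(errors)) if errors else np.nan,
        "n_missed": missed,
        "n_planted": len(run.truth.umrs),
    }


def bivalency_accuracy(run: FixtureRun) -> dict:
    """Agreement of island bivalency calls with planted labels."""
    truth_isl = run.truth.islands
    correct = 0
    total = 0
    for _, t in truth_isl.iterrows():
        cand = run.islands[(run.islands["chrom"] == t.chrom)
                           & (run.islands["start"] < t.end) & (run.islands["end"] > t.start)]
        if len(cand) == 0:
            total += 1  # planted island not recovered counts as wrong
            continue
        ov = np.minimum(cand["end"], t.end) - np.maximum(cand["start"], t.start)
        got = cand.iloc[int(np.argmax(ov))]["chrom_class"]
        want = "bivalent" if t.island_class == "bivalent" else "H3K27me3-negative"
        correct += int(got == want)
        total += 1
    return {"accuracy": correct / max(total, 1), "n_islands": total}


def hmc_border_profile(run: FixtureRun, flank_bp: int | None = None, bin_bp: int | None = None):
    """5-hmC meta-profile around recovered UMR borders, UMR side 3'."""
    flank = flank_bp or run.pipe.profile_flank
    binw = bin_bp or run.pipe.profile_bin
    b = run.borders
    if len(b) == 0:
        raise ValueError("no UMR borders recovered")
    anchors = pd.DataFrame({
        "chrom": b["chrom"],
        "pos": b["pos"],
        # orient so the unmethylated side is always to the right
        "strand": np.where(b["pos"] <= b["umr_start"], "+", "-"),
    })
    return profiles.anchor_profile(run.counts["5hmC"], anchors, flank, binw,
                                   track="5hmC", chrom_sizes=run.truth.chrom_sizes)


def hmc_border_peak_offset(run: FixtureRun) -> dict:
    """Bin distance from the mean 5-hmC profile peak to a planted border.

    Rows are oriented with the unmethylated region to the right, so a
    planted border sits at the anchor (offset 0) and the island's
    opposite border -- also a planted 5-hmC site -- at +UMR width. The
    offset reported is the distance from the profile peak to the
    nearest of these planted border positions.
    """
    prof = hmc_border_profile(run)
    means = prof.column_means()
    binw = int(prof.bin_edges[1] - prof.bin_edges[0])
    flank = -int(prof.bin_edges[0])
    peak = int(np.nanargmax(means))
    umr_width = float((run.borders["umr_end"] - run.borders["umr_start"]).mean())
    offsets_bp = [0.0, umr_width]
    dist = np.inf
    for o in offsets_bp:
        edge_bin = (o + flank) / binw  # border falls on the edge between two bins
        for cb in (int(np.floor(edge_bin)) - 1, int(np.floor(edge_bin))):
            if 0 <= cb < len(means):
                dist = min(dist, abs(peak - cb))
    return {"offset_bins": int(dist), "peak_bin": peak, "n_borders": prof.matrix.shape[0]}
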