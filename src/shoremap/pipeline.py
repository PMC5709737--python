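"""End-to-end pipeline: simulate -> tiles -> enrich -> call -> segment
-> islands -> profiles, writing a deterministic artifact directory.

Artifact files carry no timestamps, so two runs with the same
configuration and seed are bit-identical. Per-stage record counts are
logged to stderr.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import benchmark, io, profiles
from .config import PipelineConfig
from .synthetic import SyntheticConfig

logger = logging.getLogger(__name__)


def run_pipeline(
    syn_config: SyntheticConfig,
    pipe_config: PipelineConfig | None = None,
    outdir: str | Path = "shoremap_run",
) -> Path:
    """Run every stage on a simulated fixture and write all artifacts."""
    pipe = pipe_config or PipelineConfig(seed=syn_config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    run = benchmark.run_fixture(syn_config, pipe)
    logger.info("simulate: %d tiles, %d CpGs, %d islands planted",
                len(run.truth.tile_classes), len(run.truth.cpgs), len(run.truth.islands))

    from .synthetic import write_fixture

    write_fixture(run.truth, run.counts, run.calls, outdir / "fixture", syn_config)
    pipe.to_yaml(outdir / "config.yaml")

    tile_frame = run.truth.tile_classes[["chrom", "start", "end"]].copy()
    for track, e in run.enrichment.items():
        io.write_bedgraph(tile_frame.assign(value=np.round(e, 6)),
                          outdir / f"enrichment_{track}.bedGraph")

    from .tiles import cross_correlation

    corr = cross_correlation({t: run.counts[t]["count"].to_numpy() for t in run.counts},
                             pipe.pseudocount)
    corr.to_csv(outdir / "cross_correlation.tsv", sep="\t", float_format="%.6f")

    for track in benchmark.DNMT_TRACKS:
        res = run.results[track]
        called = tile_frame[(res["fold_change"] > pipe.fold_min)
                            & (res["padj"] < pipe.padj_max)]
        io.write_bed(called, outdir / f"called_{track}.bed")
        excl = tile_frame.iloc[run.bound.exclusive(track)]
        io.write_bed(excl, outdir / f"exclusive_{track}.bed")
        logger.info("call-regions %s: %d called, %d exclusive", track, len(called), len(excl))
    with open(outdir / "venn_partition.tsv", "w") as fh:
        fh.write("signature\tn_tiles\n")
        for sig in sorted(run.bound.partition):
            fh.write("&".join(sig) + f"\t{len(run.bound.partition[sig])}\n")

    segs = run.segments.copy()
    segs["name"] = segs["seg_class"]
    io.write_bed(segs, outdir / "segments.bed")
    logger.info("segment: %s", segs["seg_class"].value_counts().to_dict())

    from .methylome import filter_segments_for_profiles, fmr_density_bins

    prof_segs = filter_segments_for_profiles(segs, pipe.profile_min_distance, pipe.fmr_min_len)
    fmrs = prof_segs[prof_segs["seg_class"] == "FMR"].reset_index(drop=True)
    if len(fmrs) >= pipe.fmr_bins:
        fmrs["density_bin"] = fmr_density_bins(fmrs, run.calls, pipe.fmr_bins)
        fmrs[["chrom", "start", "end", "density_bin"]].to_csv(
            outdir / "fmr_density_bins.tsv", sep="\t", index=False)

    isl = run.islands.copy()
    isl["name"] = isl["gene"] + "|" + isl["meth_class"] + "|" + isl["chrom_class"]
    io.write_bed(isl.assign(score=0)[["chrom", "start", "end", "name", "score", "strand"]],
                 outdir / "islands_classified.bed")
    sh = run.shores.copy()
    sh["name"] = sh["gene"] + "|" + sh["side"]
    io.write_bed(sh.assign(score=0)[["chrom", "start", "end", "name", "score", "strand"]],
                 outdir / "shores.bed")

    b = run.borders.copy()
    b["name"] = b["gene"] + "|" + b["side"]
    io.write_bed(pd.DataFrame({"chrom": b["chrom"], "start": b["pos"], "end": b["pos"] + 1,
                               "name": b["name"], "score": 0, "strand": b["strand"]}),
                 outdir / "umr_borders.bed")

    if len(run.borders):
        prof = benchmark.hmc_border_profile(run)
        _write_profile(prof, outdir / "profile_5hmC_borders.tsv")
        umr_anchors = pd.DataFrame({
            "chrom": run.borders["chrom"],
            "pos": (run.borders["umr_start"] + run.borders["umr_end"]) // 2,
            "strand": run.borders["strand"],
        }).drop_duplicates().reset_index(drop=True)
        a1 = profiles.anchor_profile(run.counts["DNMT3A1"], umr_anchors,
                                     pipe.profile_flank, pipe.profile_bin, track="DNMT3A1",
                                     chrom_sizes=run.truth.chrom_sizes, norm=pipe.profile_norm)
        _write_profile(a1, outdir / "profile_DNMT3A1_umrs.tsv")
        if a1.matrix.shape[0] >= pipe.k_clusters:
            cr = profiles.cluster_umrs(a1, pipe.k_clusters, pipe.seed, pipe.pseudocount)
            umr_anchors.assign(cluster=cr.labels).to_csv(
                outdir / "umr_clusters.tsv", sep="\t", index=False)

    logger.info("pipeline complete: %s", outdir)
    return outdir


def _write_profile(prof: profiles.ProfileMatrix, path: Path) -> None:
    meta = (f'# {{"track": "{prof.track}", "norm": {prof.norm:g}, '
            f'"library_size": {prof.library_size:g}}}\n')
    with open(path, "w") as fh:
        fh.write(meta)
        pd.DataFrame(np.round(prof.matrix, 6)).to_csv(fh, sep="\t", index=False)
        fh.write("# column_means\t" +
                 "\t".join(f"{v:.6f}" for v in prof.column_means()) + "\n")
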