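"""Pipeline configuration.

Every numeric threshold used across the pipeline lives here with its
standard default: 1-kb tiles, a pseudocount of 8 for enrichment, a
mappability floor of 0.5, bisulfite coverage rules of >10x (WGBS) and
>20x (RRBS), a >50% per-tile CpG-coverage requirement, bound-region
thresholds of fold > 1 and adjusted p < 0.002, a 200-bp minimum CpG
island length, a 20% methylation cutoff separating unmethylated from
methylated promoter islands, 2-kb shores, >6-kb segment spacing and
>=12-kb FMRs for meta-profiles, 3 FMR density bins, k = 5 profile
clusters and 500-window blocks for ranked medians.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class SegmentationParams:
    """Parameters of the UMR/LMR/FMR methylome segmentation."""

    smooth_window: int = 3          # CpGs in the running-mean smoother
    hypo_cutoff: float = 0.5        # smoothed fraction at/below which a CpG is hypomethylated
    min_run_cpgs: int = 4           # minimum CpGs in a hypomethylated segment
    umr_min_cpgs: int = 30          # hypo segments with >= this many CpGs are UMRs, else LMRs
    max_gap_bp: int = 1000          # segments never span a larger inter-CpG gap


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis, serializable to YAML."""

    tile_width: int = 1000
    pseudocount: float = 8.0
    mappability_min: float = 0.5
    meth_cov_min: float = 0.5       # fraction of tile CpGs that must be covered >= tile_cov_depth
    tile_cov_depth: int = 10
    wgbs_min_cov: int = 10          # CpGs kept if total coverage is strictly greater
    rrbs_min_cov: int = 20
    fold_min: float = 1.0
    padj_max: float = 0.002
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    profile_min_distance: int = 6000
    fmr_min_len: int = 12000
    fmr_bins: int = 3
    island_min_len: int = 200
    island_min_cpgs: int = 10
    e_min: float = 1.0              # bivalency call: mean log2 enrichment of both marks
    meth_threshold: float = 20.0    # percent; below = unmethylated island
    shore_width: int = 2000
    promoter_flank: int = 1000
    profile_flank: int = 5000
    profile_bin: int = 500
    profile_norm: float = 1e7       # reads per bin per 1e7 library reads
    n_body_bins: int = 20
    k_clusters: int = 5
    block_size: int = 500
    seed: int = 7

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        seg = d.pop("segmentation", None)
        cfg = cls(**d)
        if seg is not None:
            cfg.segmentation = SegmentationParams(**seg)
        return cfg
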