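"""Synthetic multi-chromosome fixture generator.

Generates a small genome carrying the structure the analysis is built
to detect: CpG islands with unmethylated centers and methylated shores,
a subset of them bivalent (H3K4me3 + H3K27me3) with DNMT3A1 planted at
their shores and 5-hmC concentrated at the unmethylated-region borders;
transcribed gene bodies carrying H3K36me3 and DNMT3B; diffuse DNMT3A2;
negative-binomially dispersed ChIP tile counts and binomially sampled
bisulfite calls. A ground-truth ledger (island classes, planted UMRs,
per-tile region classes, per-CpG methylation) supports recovery tests.

One global seed fans out into named substreams (truth, one per ChIP
track, bisulfite, read expansion) so adding a track never perturbs the
draws of existing tracks.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .tiles import make_tiles

TRACKS = ("DNMT3A1", "DNMT3A2", "DNMT3B", "H3K27me3", "H3K4me3", "H3K36me3", "5hmC", "input")

# region classes in tie-break priority order (first wins on equal overlap)
REGION_PRIORITY = (
    "bivalent_center",
    "active_center",
    "bivalent_border",
    "active_border",
    "bivalent_shore",
    "active_shore",
    "lmr",
    "transcribed_body",
    "background",
)

DEFAULT_FOLD_MAP = {
    "DNMT3A1": {"bivalent_shore": 8.0, "bivalent_border": 8.0},
    "DNMT3A2": {},
    "DNMT3B": {"transcribed_body": 8.0},
    "H3K27me3": {"bivalent_center": 6.0, "bivalent_border": 4.0, "bivalent_shore": 2.0},
    "H3K4me3": {
        "bivalent_center": 6.0,
        "active_center": 6.0,
        "bivalent_border": 4.0,
        "active_border": 4.0,
    },
    "H3K36me3": {"transcribed_body": 6.0},
    "5hmC": {"bivalent_border": 6.0},
    "input": {},
}

DEFAULT_METH_LEVELS = {"UMR": 0.05, "LMR": 0.25, "shore": 0.85, "FMR": 0.80}

# mean inter-CpG gaps (bp) yielding a realistic density contrast:
# islands are ~8x denser than bulk genome
CPG_GAP_MEANS = {"island": 12.0, "lmr": 30.0, "shore": 100.0, "background": 100.0}

BORDER_HALF_WIDTH = 500  # bp on each side of an island edge forming the border zone


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic genome."""

    seed: int = 7
    n_chroms: int = 2
    chrom_length_bp: int = 5_000_000
    n_islands: int = 20
    bivalent_fraction: float = 0.5
    island_length_bp: int = 2000
    n_genes: int = 30
    transcribed_fraction: float = 0.5
    n_lmrs: int = 10
    lmr_length_bp: int = 300
    mean_tile_depth: float = 30.0
    nb_dispersion: float = 0.05
    fold_map: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FOLD_MAP.items()})
    meth_levels: dict = field(default_factory=lambda: dict(DEFAULT_METH_LEVELS))
    cpg_coverage_mean: float = 30.0
    shore_width_bp: int = 2000
    tile_width: int = 1000

    def validate(self) -> None:
        if not 0.0 <= self.bivalent_fraction <= 1.0:
            raise ValueError("bivalent_fraction must be in [0, 1]")
        if not 0.0 <= self.transcribed_fraction <= 1.0:
            raise ValueError("transcribed_fraction must be in [0, 1]")
        for track, m in self.fold_map.items():
            for cls, fold in m.items():
                if fold < 1.0:
                    raise ValueError(f"fold_map[{track}][{cls}] = {fold} < 1")
        for cls, level in self.meth_levels.items():
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"meth_levels[{cls}] = {level} outside [0, 1]")
        if self.chrom_length_bp < 50 * self.tile_width:
            raise ValueError("chrom_length_bp must be >= 50x tile width")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for the generated fixture."""

    chrom_sizes: dict
    islands: pd.DataFrame      # chrom, start, end, island_class, gene, strand
    genes: pd.DataFrame        # chrom, start, end, name, strand, transcribed
    lmrs: pd.DataFrame         # chrom, start, end
    umrs: pd.DataFrame         # planted unmethylated regions (= island intervals)
    cpgs: pd.DataFrame         # chrom, pos, true_meth
    regions: pd.DataFrame      # disjoint class regions: chrom, start, end, region_class
    tile_classes: pd.DataFrame # chrom, start, end, region_class (majority rule)

    def expected_bound_tiles(self, track: str, fold_map: dict, min_fold: float = 2.0) -> np.ndarray:
        """Tiles whose planted fold for ``track`` is >= ``min_fold``."""
        folds = self.tile_classes["region_class"].map(
            lambda c: fold_map.get(track, {}).get(c, 1.0)
        )
        return (folds.to_numpy(dtype=float) >= min_fold)


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _place_intervals(rng, length, n, size, lo, hi, min_sep, max_tries=1000):
    """Sample ``n`` non-overlapping interval starts with pairwise separation."""
    if n == 0:
        return np.array([], dtype=np.int64)
    if hi - lo < n * (size + min_sep):
        raise ValueError("placement infeasible: interval density too high for chromosome")
    for _ in range(max_tries):
        starts = np.sort(rng.integers(lo, hi - size, size=n))
        if n == 1 or np.all(np.diff(starts) >= size + min_sep):
            return starts
    raise ValueError("placement failed after bounded retries; relax density or sizes")


def _draw_positions(rng, start, end, gap_mean):
    """CpG positions in [start, end) with geometric inter-CpG gaps."""
    out = []
    pos = start
    while True:
        n = max(16, int((end - pos) / gap_mean * 1.3))
        gaps = rng.geometric(1.0 / gap_mean, size=n)
        pts = pos + np.cumsum(gaps)
        out.append(pts[pts < end])
        if len(pts) == 0 or pts[-1] >= end:
            break
        pos = int(pts[-1])
    return np.concatenate(out) if out else np.array([], dtype=np.int64)


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Lay out islands, genes, LMRs, CpGs and per-tile region classes."""
    config.validate()
    rng = _rng(config.seed, "truth")
    L = config.chrom_length_bp
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: L for c in chroms}
    ilen, sw = config.island_length_bp, config.shore_width_bp
    margin = sw + 2 * BORDER_HALF_WIDTH

    # --- islands, split evenly across chromosomes
    per_chrom = np.array_split(np.arange(config.n_islands), config.n_chroms)
    island_rows = []
    for chrom, idx in zip(chroms, per_chrom):
        starts = _place_intervals(
            rng, L, len(idx), ilen, margin, L - margin, min_sep=2 * sw + 2000
        )
        for s in starts:
            island_rows.append((chrom, int(s), int(s) + ilen))
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    n_biv = int(round(config.bivalent_fraction * config.n_islands))
    labels = np.array(["active"] * config.n_islands, dtype=object)
    labels[rng.permutation(config.n_islands)[:n_biv]] = "bivalent"
    islands["island_class"] = labels

    # --- genes: one per island (TSS at the island midpoint) plus distal extras
    gene_rows = []
    for i, isl in islands.iterrows():
        strand = "+" if rng.random() < 0.5 else "-"
        tss = (isl.start + isl.end) // 2
        glen = int(rng.integers(12000, 20001))
        if strand == "+":
            gs, ge = tss, min(tss + glen, L)
        else:
            gs, ge = max(tss + 1 - glen, 0), tss + 1
        transcribed = bool(isl.island_class == "active" and rng.random() < config.transcribed_fraction)
        gene_rows.append((isl.chrom, gs, ge, f"gene_{i}", strand, transcribed, i))
    islands["gene"] = [r[3] for r in gene_rows]
    islands["strand"] = [r[4] for r in gene_rows]

    forbidden = {c: [] for c in chroms}
    for _, isl in islands.iterrows():
        forbidden[isl.chrom].append((isl.start - margin, isl.end + margin))
    for r in gene_rows:
        forbidden[r[0]].append((r[1], r[2]))

    def _free(chrom, s, e):
        return all(e <= a or s >= b for a, b in forbidden[chrom])

    n_extra = max(0, config.n_genes - config.n_islands)
    placed = 0
    tries = 0
    while placed < n_extra:
        tries += 1
        if tries > 200 * max(1, n_extra):
            raise ValueError("extra gene placement failed after bounded retries")
        chrom = chroms[int(rng.integers(config.n_chroms))]
        glen = int(rng.integers(12000, 20001))
        s = int(rng.integers(margin, L - margin - glen))
        if not _free(chrom, s, s + glen):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        transcribed = bool(rng.random() < config.transcribed_fraction)
        gene_rows.append((chrom, s, s + glen, f"gene_{config.n_islands + placed}", strand, transcribed, -1))
        forbidden[chrom].append((s, s + glen))
        placed += 1
    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "name", "strand", "transcribed", "island"]
    )

    # --- planted low-methylated regions, distal to islands and genes
    lmr_rows = []
    placed = 0
    tries = 0
    while placed < config.n_lmrs:
        tries += 1
        if tries > 200 * max(1, config.n_lmrs):
            raise ValueError("LMR placement failed after bounded retries")
        chrom = chroms[int(rng.integers(config.n_chroms))]
        s = int(rng.integers(margin, L - margin - config.lmr_length_bp))
        if not _free(chrom, s, s + config.lmr_length_bp):
            continue
        lmr_rows.append((chrom, s, s + config.lmr_length_bp))
        forbidden[chrom].append((s, s + config.lmr_length_bp))
        placed += 1
    lmrs = pd.DataFrame(lmr_rows, columns=["chrom", "start", "end"])

    # --- disjoint region classes for the count model
    region_rows = []
    for _, isl in islands.iterrows():
        c, s, e = isl.chrom, isl.start, isl.end
        kind = isl.island_class
        b = BORDER_HALF_WIDTH
        region_rows += [
            (c, s + b, e - b, f"{kind}_center"),
            (c, s - b, s + b, f"{kind}_border"),
            (c, e - b, e + b, f"{kind}_border"),
            (c, s - sw, s - b, f"{kind}_shore"),
            (c, e + b, e + sw, f"{kind}_shore"),
        ]
    for _, g in genes.iterrows():
        if not g.transcribed:
            continue
        if g.island >= 0:
            isl = islands.loc[g.island]
            if g.strand == "+":
                bs, be = isl.end + sw, g.end
            else:
                bs, be = g.start, isl.start - sw
        else:
            bs, be = g.start, g.end
        if be > bs:
            region_rows.append((g.chrom, bs, be, "transcribed_body"))
    for _, r in lmrs.iterrows():
        region_rows.append((r.chrom, r.start, r.end, "lmr"))
    regions = pd.DataFrame(region_rows, columns=["chrom", "start", "end", "region_class"])
    regions["start"] = regions["start"].clip(lower=0)
    regions["end"] = regions["end"].clip(upper=L)
    regions = regions[regions.end > regions.start].reset_index(drop=True)

    # --- CpG positions with piecewise geometric spacing and true methylation
    cpg_frames = []
    lvl = config.meth_levels
    for chrom in chroms:
        pieces = []  # (start, end, gap_mean, meth)
        feats = []
        for _, isl in islands[islands.chrom == chrom].iterrows():
            feats.append((isl.start - sw, isl.start, "shore"))
            feats.append((isl.start, isl.end, "island"))
            feats.append((isl.end, isl.end + sw, "shore"))
        for _, r in lmrs[lmrs.chrom == chrom].iterrows():
            feats.append((r.start, r.end, "lmr"))
        feats.sort()
        cursor = 0
        meth_of = {"island": lvl["UMR"], "lmr": lvl["LMR"], "shore": lvl["shore"]}
        for s, e, kind in feats:
            if s > cursor:
                pieces.append((cursor, s, CPG_GAP_MEANS["background"], lvl["FMR"]))
            pieces.append((s, e, CPG_GAP_MEANS[kind], meth_of[kind]))
            cursor = e
        if cursor < L:
            pieces.append((cursor, L, CPG_GAP_MEANS["background"], lvl["FMR"]))
        for s, e, gap, meth in pieces:
            pos = _draw_positions(rng, s, e, gap)
            if len(pos):
                cpg_frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "true_meth": meth}))
    cpgs = pd.concat(cpg_frames, ignore_index=True)
    cpgs = cpgs.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    tile_classes = _classify_tiles(chrom_sizes, regions, config.tile_width)
    umrs = islands[["chrom", "start", "end", "island_class"]].copy()
    return SyntheticTruth(chrom_sizes, islands, genes, lmrs, umrs, cpgs, regions, tile_classes)


def _classify_tiles(chrom_sizes, regions, width):
    """Assign each tile the region class with the largest bp overlap."""
    tiles = make_tiles(chrom_sizes, width)
    overlap = {cls: np.zeros(len(tiles)) for cls in REGION_PRIORITY}
    offsets = {}
    off = 0
    for chrom, size in chrom_sizes.items():
        offsets[chrom] = off
        off += size // width
    for _, r in regions.iterrows():
        base = offsets[r.chrom]
        n_chrom = chrom_sizes[r.chrom] // width
        t0, t1 = int(r.start) // width, (int(r.end) - 1) // width
        for t in range(max(t0, 0), min(t1, n_chrom - 1) + 1):
            ov = min(r.end, (t + 1) * width) - max(r.start, t * width)
            overlap[r.region_class][base + t] += ov
    assigned = sum(overlap[c] for c in REGION_PRIORITY if c != "background")
    overlap["background"] = np.maximum(width - assigned, 0)
    mat = np.column_stack([overlap[c] for c in REGION_PRIORITY])
    tiles["region_class"] = np.array(REGION_PRIORITY, dtype=object)[mat.argmax(axis=1)]
    return tiles


def simulate_chip(truth: SyntheticTruth, config: SyntheticConfig, track: str) -> pd.DataFrame:
    """Negative-binomial per-tile counts for one ChIP track.

    Tile mean = mean_tile_depth x planted fold for the tile's region
    class (input uses fold 1 everywhere); counts are gamma-Poisson
    mixtures with the configured dispersion, or pure Poisson in the
    zero-dispersion limit. Each track draws from its own seeded
    substream.
    """
    if track not in config.fold_map:
        raise ValueError(f"unknown track {track!r}; configured: {sorted(config.fold_map)}")
    rng = _rng(config.seed, f"chip:{track}")
    folds = truth.tile_classes["region_class"].map(
        lambda c: config.fold_map[track].get(c, 1.0)
    ).to_numpy(dtype=float)
    mu = config.mean_tile_depth * folds
    alpha = config.nb_dispersion
    if alpha < 1e-9:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
        counts = rng.poisson(lam)
    out = truth.tile_classes[["chrom", "start", "end"]].copy()
    out["count"] = counts.astype(np.int64)
    return out


def simulate_bisulfite(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Per-CpG bisulfite calls: total ~ Poisson, methylated ~ Binomial."""
    rng = _rng(config.seed, "bisulfite")
    n = len(truth.cpgs)
    total = rng.poisson(config.cpg_coverage_mean, size=n)
    meth = rng.binomial(total, truth.cpgs["true_meth"].to_numpy())
    out = truth.cpgs[["chrom", "pos"]].copy()
    out["meth"] = meth.astype(np.int64)
    out["total"] = total.astype(np.int64)
    return out


def expand_read_starts(counts: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Expand per-tile counts into synthetic read-start intervals (BED-like).

    Each tile with count c emits c single-bp read starts uniformly
    within the tile, for exercising the counting path.
    """
    rng = _rng(seed, "expand")
    c = counts["count"].to_numpy()
    reps = np.repeat(np.arange(len(counts)), c)
    starts = counts["start"].to_numpy()[reps]
    widths = (counts["end"].to_numpy() - counts["start"].to_numpy())[reps]
    pos = starts + rng.integers(0, widths) if len(reps) else np.array([], dtype=np.int64)
    return pd.DataFrame(
        {"chrom": counts["chrom"].to_numpy()[reps], "start": pos, "end": pos + 1}
    )


def simulate_profile_archetypes(
    n_per_cluster: int = 40,
    n_bins: int = 40,
    depth: float = 30.0,
    dispersion: float = 0.05,
    fold: float = 8.0,
    seed: int = 0,
):
    """Anchored-signal rows drawn around five planted profile archetypes.

    Archetypes mimic the qualitative binding shapes seen around
    unmethylated regions: 5' border peak, 3' border peak, both borders,
    broad body enrichment, and unbound background. Returns (matrix,
    labels).
    """
    rng = _rng(seed, "archetypes")
    shapes = np.ones((5, n_bins))
    q = n_bins // 8
    shapes[0, q : 3 * q] = fold                 # 5' border peak
    shapes[1, -3 * q : -q] = fold               # 3' border peak
    shapes[2, q : 3 * q] = fold                 # both borders
    shapes[2, -3 * q : -q] = fold
    shapes[3, 2 * q : -2 * q] = fold            # broad central enrichment
    labels = np.repeat(np.arange(5), n_per_cluster)
    mu = depth * shapes[labels]
    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    return rng.poisson(lam).astype(float), labels


def write_fixture(truth: SyntheticTruth, tracks: dict, calls: pd.DataFrame, outdir, config: SyntheticConfig) -> dict:
    """Write the fixture as BED/TSV text plus a manifest; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    isl = truth.islands.copy()
    isl["name"] = isl["island_class"] + "|" + isl["gene"]
    io.write_bed(isl.assign(score=0)[["chrom", "start", "end", "name", "score", "strand"]],
                 outdir / "islands.bed")
    paths["islands"] = outdir / "islands.bed"

    g = truth.genes.copy()
    g["name"] = g["name"] + "|" + np.where(g["transcribed"], "transcribed", "silent")
    io.write_bed(g.assign(score=0)[["chrom", "start", "end", "name", "score", "strand"]],
                 outdir / "genes.bed")
    paths["genes"] = outdir / "genes.bed"

    io.write_bed(truth.umrs.rename(columns={"island_class": "name"}), outdir / "umrs.bed")
    paths["umrs"] = outdir / "umrs.bed"
    io.write_bed(truth.lmrs, outdir / "lmrs.bed")
    paths["lmrs"] = outdir / "lmrs.bed"

    for track, counts in tracks.items():
        p = outdir / f"counts_{track}.tsv"
        io.write_counts(counts, p)
        paths[f"counts:{track}"] = p

    cp = calls.copy()
    cp["pos1"] = cp["pos"] + 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cp["total"] > 0, 100.0 * cp["meth"] / cp["total"], 0.0)
    cp["percent"] = np.round(pct, 4)
    cp[["chrom", "pos", "pos1", "meth", "total", "percent"]].to_csv(
        outdir / "cpg_calls.tsv", sep="\t", index=False,
        header=["chrom", "start", "end", "meth", "total", "percent"],
    )
    paths["calls"] = outdir / "cpg_calls.tsv"

    truth.tile_classes.to_csv(outdir / "truth_tiles.tsv", sep="\t", index=False)
    paths["truth_tiles"] = outdir / "truth_tiles.tsv"
    io.write_chrom_sizes(truth.chrom_sizes, outdir / "chrom.sizes")
    paths["chrom_sizes"] = outdir / "chrom.sizes"

    with open(outdir / "manifest.tsv", "w") as fh:
        for key, value in asdict(config).items():
            if isinstance(value, dict):
                value = json.dumps(value, sort_keys=True)
            fh.write(f"{key}\t{value}\n")
    paths["manifest"] = outdir / "manifest.tsv"
    return paths


def read_manifest(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            key, value = line.rstrip("\n").split("\t", 1)
            out[key] = value
    return out
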