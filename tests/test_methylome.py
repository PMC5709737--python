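"""Call loading, region statistics and methylome segmentation."""

import numpy as np
import pandas as pd
import pytest

from shoremap import methylome
from shoremap.config import SegmentationParams
from shoremap.io import FormatError


def _write_calls(path, rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "meth", "total", "percent"])
    df.to_csv(path, sep="\t", index=False)
    return path


class TestLoadCalls:
    def test_wgbs_coverage_boundary(self, tmp_path):
        p = _write_calls(tmp_path / "c.tsv", [("chr1", 10, 11, 5, 10, 50.0),
                                              ("chr1", 20, 21, 5, 11, 45.5)])
        calls = methylome.load_calls(p, "WGBS")
        assert list(calls["pos"]) == [20]  # total 10 dropped: rule is strictly > 10

    def test_rrbs_coverage_boundary(self, tmp_path):
        p = _write_calls(tmp_path / "c.tsv", [("chr1", 10, 11, 5, 20, 25.0),
                                              ("chr1", 20, 21, 5, 21, 23.8)])
        calls = methylome.load_calls(p, "RRBS")
        assert list(calls["pos"]) == [20]

    def test_snp_mask_and_coverage_combined(self, tmp_path):
        rows = [("chr1", i * 10, i * 10 + 1, 5, t, 0.0)
                for i, t in enumerate([30, 5, 30, 8, 30, 30])]
        p = _write_calls(tmp_path / "c.tsv", rows)
        mask = pd.DataFrame({"chrom": ["chr1"], "start": [40], "end": [41]})
        calls = methylome.load_calls(p, "WGBS", snp_mask=mask)
        assert len(calls) == 3  # 2 under-covered + 1 SNP-masked dropped

    def test_meth_exceeding_total_rejected(self, tmp_path):
        p = _write_calls(tmp_path / "c.tsv", [("chr1", 10, 11, 12, 11, 0.0)])
        with pytest.raises(FormatError, match="line"):
            methylome.load_calls(p)


def _calls(pos, frac, chrom="chr1", total=100):
    pos = np.asarray(pos)
    frac = np.asarray(frac, dtype=float)
    return pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "meth": np.round(frac * total).astype(int), "total": total, "frac": frac,
    })


class TestRegionStats:
    def test_single_cpg_percent(self):
        calls = pd.DataFrame({"chrom": ["chr1"], "pos": [50], "meth": [3],
                              "total": [4], "frac": [0.75]})
        assert methylome.region_methylation(("chr1", 0, 100), calls) == 75.0

    def test_unweighted_mean(self):
        calls = _calls([10, 20], [1.0, 0.0])
        assert methylome.region_methylation(("chr1", 0, 100), calls) == 50.0
        calls = _calls([10, 20, 30], [0.2, 0.4, 0.9])
        assert methylome.region_methylation(("chr1", 0, 100), calls) == pytest.approx(50.0)

    def test_empty_region_is_missing_not_zero(self):
        calls = _calls([10], [0.5])
        assert np.isnan(methylome.region_methylation(("chr1", 500, 600), calls))

    def test_depth_invariance(self):
        pos = np.arange(10) * 7
        frac = np.linspace(0.1, 0.9, 10)
        a = _calls(pos, frac, total=100)
        b = _calls(pos, frac, total=200)  # every read duplicated
        r = ("chr1", 0, 100)
        assert methylome.region_methylation(r, a) == methylome.region_methylation(r, b)

    @pytest.mark.parametrize("n,length,expect", [(5, 1000, 0.5), (0, 1000, 0.0), (13, 650, 2.0)])
    def test_cpg_density(self, n, length, expect):
        calls = _calls(np.arange(n) * 3, np.full(n, 0.5)) if n else _calls([], [])
        assert methylome.cpg_density(("chr1", 0, length), calls) == pytest.approx(expect)


def oracle_segment(pos, frac, params):
    """Independent run-enumeration segmentation oracle (list-based)."""
    n = len(pos)
    sm = [sum(frac[max(0, i - 1): i + 2]) / len(frac[max(0, i - 1): i + 2])
          for i in range(n)]
    hypo = [s <= params.hypo_cutoff for s in sm]
    segs = []
    taken = [False] * n
    i = 0
    while i < n:
        if hypo[i]:
            j = i + 1
            while j < n and hypo[j] and pos[j] - pos[j - 1] <= params.max_gap_bp:
                j += 1
            if j - i >= params.min_run_cpgs:
                cls = "UMR" if j - i >= params.umr_min_cpgs else "LMR"
                segs.append((pos[i], pos[j - 1] + 1, cls, j - i))
                for k in range(i, j):
                    taken[k] = True
            i = j
        else:
            i += 1
    i = 0
    while i < n:
        if not taken[i]:
            j = i + 1
            while j < n and not taken[j] and pos[j] - pos[j - 1] <= params.max_gap_bp:
                j += 1
            segs.append((pos[i], pos[j - 1] + 1, "FMR", j - i))
            i = j
        else:
            i += 1
    return sorted(segs)


class TestSegmentation:
    def test_fully_unmethylated_is_one_umr(self):
        pos = np.arange(40) * 20
        calls = _calls(pos, np.zeros(40))
        segs = methylome.segment_methylome(calls)
        assert list(segs["seg_class"]) == ["UMR"]
        assert (segs.iloc[0].start, segs.iloc[0].end) == (0, 781)

    def test_fully_methylated_is_one_fmr(self):
        pos = np.arange(40) * 20
        segs = methylome.segment_methylome(_calls(pos, np.full(40, 0.9)))
        assert list(segs["seg_class"]) == ["FMR"]

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(10)
        params = SegmentationParams()
        for _ in range(300):
            n = 60
            gaps = rng.integers(5, 400, n)
            pos = np.cumsum(gaps)
            # dyadic fractions keep every partial sum exact in binary, so the
            # cutoff comparison is identical for both routes
            frac = rng.integers(0, 17, n) / 16.0
            calls = _calls(pos, frac)
            segs = methylome.segment_methylome(calls, params)
            got = sorted(zip(segs["start"], segs["end"], segs["seg_class"], segs["n_cpgs"]))
            assert got == oracle_segment(list(pos), list(frac), params)

    def test_partition_covers_every_cpg_once(self, small_run):
        segs = small_run.segments
        n_cpgs = len(small_run.calls)
        covered = np.zeros(n_cpgs, dtype=int)
        for _, s in segs.iterrows():
            covered[s.cpg_lo:s.cpg_hi] += 1
        assert (covered == 1).all()

    def test_class_mean_ordering_on_synthetic_truth(self, small_run):
        means = small_run.segments.groupby("seg_class")["mean_meth"].mean()
        assert means["UMR"] < means["LMR"] < means["FMR"]

    def test_tiny_chromosome_skipped(self):
        calls = _calls([5, 10], [0.0, 0.0])
        segs = methylome.segment_methylome(calls.iloc[:2])
        assert len(segs) == 0 or segs["n_cpgs"].sum() <= 2


class TestProfileFilters:
    def _segs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "seg_class"])

    def test_close_hypo_pair_both_dropped(self):
        segs = self._segs([("chr1", 0, 1000, "UMR"), ("chr1", 6000, 7000, "UMR")])
        assert len(methylome.filter_segments_for_profiles(segs)) == 0

    def test_isolated_hypo_kept(self):
        segs = self._segs([("chr1", 0, 1000, "UMR"), ("chr1", 11_001, 12_000, "LMR")])
        assert len(methylome.filter_segments_for_profiles(segs)) == 2

    def test_toy_set_hand_enumeration(self):
        segs = self._segs([
            ("chr1", 0, 1000, "UMR"),        # 4 kb from next: dropped
            ("chr1", 5000, 6000, "LMR"),     # dropped (pair)
            ("chr1", 40_000, 41_000, "UMR"), # isolated: kept
            ("chr1", 60_000, 80_000, "FMR"), # 20 kb: kept
            ("chr1", 90_000, 95_000, "FMR"), # 5 kb: dropped
            ("chr2", 0, 1000, "UMR"),        # other chromosome: isolated
        ])
        out = methylome.filter_segments_for_profiles(segs)
        assert list(out["start"]) == [40_000, 60_000, 0]


class TestFmrDensityBins:
    def _fmrs(self, n, length=1000):
        return pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 10_000,
                             "end": np.arange(n) * 10_000 + length})

    def test_equal_bins_in_density_order(self):
        fmrs = self._fmrs(9)
        # k-th FMR gets k methylated CpGs
        rows = []
        for k in range(9):
            for j in range(k + 1):
                rows.append((k * 10_000 + j * 7, 0.9))
        calls = _calls([r[0] for r in rows], [r[1] for r in rows])
        labels = methylome.fmr_density_bins(fmrs, calls, 3)
        assert list(labels) == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_remainder_goes_to_lowest_bins(self):
        fmrs = self._fmrs(10)
        calls = _calls([k * 10_000 + j * 7 for k in range(10) for j in range(k + 1)],
                       [0.9] * 55)
        labels = methylome.fmr_density_bins(fmrs, calls, 3)
        counts = pd.Series(labels).value_counts().sort_index()
        assert list(counts) == [4, 3, 3]

    def test_all_ties_resolved_by_genomic_order(self):
        fmrs = self._fmrs(6)
        calls = _calls([k * 10_000 for k in range(6)], [0.9] * 6)
        labels = methylome.fmr_density_bins(fmrs, calls, 3)
        assert list(labels) == [1, 1, 2, 2, 3, 3]

    def test_too_few_fmrs(self):
        with pytest.raises(ValueError):
            methylome.fmr_density_bins(self._fmrs(2), _calls([1], [0.9]), 3)


class TestUmrBorders:
    def _genes(self, strand="+"):
        return pd.DataFrame({"chrom": ["chr1"], "start": [7500], "end": [20_000],
                             "name": ["g"], "strand": [strand]})

    def _segs(self):
        return pd.DataFrame({
            "chrom": ["chr1"] * 3,
            "start": [0, 7000, 11_000],
            "end": [5000, 9000, 20_000],
            "seg_class": ["FMR", "UMR", "FMR"],
        })

    def test_borders_from_flanking_fmrs(self):
        segs = self._segs()
        b = methylome.umr_borders(segs[segs.seg_class == "UMR"],
                                  segs[segs.seg_class == "FMR"], self._genes())
        assert sorted(b["pos"]) == [5000, 11_000]
        assert dict(zip(b["pos"], b["side"])) == {5000: "5p", 11_000: "3p"}

    def test_minus_strand_swaps_labels(self):
        segs = self._segs()
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [8600],
                              "name": ["g"], "strand": ["-"]})
        b = methylome.umr_borders(segs[segs.seg_class == "UMR"],
                                  segs[segs.seg_class == "FMR"], genes)
        assert dict(zip(b["pos"], b["side"])) == {5000: "3p", 11_000: "5p"}

    def test_missing_flank_skipped(self):
        segs = self._segs().iloc[1:]  # no preceding FMR
        b = methylome.umr_borders(segs[segs.seg_class == "UMR"],
                                  segs[segs.seg_class == "FMR"], self._genes())
        assert list(b["pos"]) == [11_000]

    def test_fixture_borders_near_island_edges(self, default_run):
        truth = default_run.truth
        borders = default_run.borders
        biv = truth.islands[truth.islands.island_class == "bivalent"]
        for _, isl in biv.iterrows():
            mine = borders[(borders["chrom"] == isl.chrom)
                           & (borders["umr_start"] < isl.end)
                           & (borders["umr_end"] > isl.start)]
            assert len(mine) == 2
            for _, row in mine.iterrows():
                edge = isl.start if abs(row.pos - isl.start) < abs(row.pos - isl.end) else isl.end
                # border within ~2 background inter-CpG gaps of the planted edge
                assert abs(row.pos - edge) <= 600
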