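"""Anchored profiles, clustering, dynamics and class enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from shoremap import profiles
from shoremap.synthetic import simulate_profile_archetypes


def _grid(counts, chrom="chr1", width=1000):
    n = len(counts)
    return pd.DataFrame({"chrom": chrom, "start": np.arange(n) * width,
                         "end": (np.arange(n) + 1) * width, "count": counts})


class TestAnchorProfile:
    def test_constant_track_is_flat(self):
        tiles = _grid(np.full(50, 20))
        anchors = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10_000, 20_000, 25_500],
                                "strand": ["+", "-", "+"]})
        prof = profiles.anchor_profile(tiles, anchors, 5000, 500)
        expect = 20 * 0.5 * 1e7 / (50 * 20)  # half a tile per bin, normalized
        np.testing.assert_allclose(prof.column_means(), expect)

    def test_point_mass_and_strand_flip(self):
        counts = np.zeros(50)
        counts[20] = 100  # mass in tile [20000, 21000)
        tiles = _grid(counts)
        plus = pd.DataFrame({"chrom": ["chr1"], "pos": [20_000], "strand": ["+"]})
        minus = plus.assign(strand="-")
        p = profiles.anchor_profile(tiles, plus, 2000, 1000)
        m = profiles.anchor_profile(tiles, minus, 2000, 1000)
        assert np.argmax(p.matrix[0]) == 2   # first downstream bin
        np.testing.assert_allclose(m.matrix[0], p.matrix[0][::-1])

    def test_library_scaling_invariance(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(30, 50)
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [25_000], "strand": ["+"]})
        a = profiles.anchor_profile(_grid(counts), anchors, 3000, 500)
        b = profiles.anchor_profile(_grid(counts * 7), anchors, 3000, 500)
        np.testing.assert_allclose(a.matrix, b.matrix)

    def test_mirror_symmetry(self):
        """Mirroring the genome and flipping strands leaves means unchanged."""
        rng = np.random.default_rng(13)
        counts = rng.poisson(30, 50)
        anchors = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [12_345, 31_000],
                                "strand": ["+", "+"]})
        fwd = profiles.anchor_profile(_grid(counts), anchors, 3000, 500)
        L = 50 * 1000
        mirrored = profiles.anchor_profile(
            _grid(counts[::-1]),
            pd.DataFrame({"chrom": ["chr1"] * 2, "pos": L - anchors["pos"],
                          "strand": ["-", "-"]}),
            3000, 500)
        np.testing.assert_allclose(fwd.column_means(), mirrored.column_means(),
                                   atol=1e-9)

    def test_out_of_chromosome_rows_nan_padded(self):
        tiles = _grid(np.full(10, 5))
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [500], "strand": ["+"]})
        prof = profiles.anchor_profile(tiles, anchors, 2000, 500,
                                       chrom_sizes={"chr1": 10_000})
        assert np.isnan(prof.matrix[0][:3]).all()
        assert np.isfinite(prof.matrix[0][3:]).all()


class TestScaledGeneProfile:
    def test_constant_track_flat_across_body_boundary(self):
        tiles = _grid(np.full(100, 10))
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [30_000], "end": [47_500],
                              "name": ["g"], "strand": ["+"]})
        prof = profiles.scaled_gene_profile(tiles, genes, n_body_bins=10,
                                            flank_bp=2000, bin_bp=500)
        row = prof.matrix[0]
        np.testing.assert_allclose(row, row[0], rtol=1e-9)

    def test_body_restricted_track(self):
        counts = np.zeros(100)
        counts[30:48] = 50
        tiles = _grid(counts)
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [30_000], "end": [48_000],
                              "name": ["g"], "strand": ["+"]})
        prof = profiles.scaled_gene_profile(tiles, genes, 10, 2000, 500)
        assert prof.matrix[0][:4].sum() == 0
        assert prof.matrix[0][-4:].sum() == 0
        assert (prof.matrix[0][4:-4] > 0).all()

    def test_overlapping_genes_dropped(self):
        tiles = _grid(np.full(100, 10))
        genes = pd.DataFrame({"chrom": ["chr1"] * 3,
                              "start": [10_000, 15_000, 60_000],
                              "end": [20_000, 25_000, 70_000],
                              "name": ["a", "b", "c"], "strand": ["+", "+", "-"]})
        prof = profiles.scaled_gene_profile(tiles, genes, 10, 2000, 500)
        assert list(prof.anchors["name"]) == ["c"]

    def test_fixture_body_enrichment_structure(self, default_run):
        """Transcription-coupled tracks are body-enriched; DNMT3A1 is not."""
        genes = default_run.truth.genes
        transcribed = genes[genes["transcribed"]]
        ratios = {}
        for track in ("H3K36me3", "DNMT3B", "DNMT3A1"):
            prof = profiles.scaled_gene_profile(
                default_run.counts[track], transcribed, n_body_bins=10,
                flank_bp=2000, bin_bp=500)
            m = prof.column_means()
            body, flank = m[4:-4].mean(), np.concatenate([m[:4], m[-4:]]).mean()
            ratios[track] = body / flank
        assert ratios["H3K36me3"] > 2
        assert ratios["DNMT3B"] > 2
        assert ratios["DNMT3A1"] == pytest.approx(1.0, abs=0.3)


class TestClusterUmrs:
    def _prof(self, X):
        return profiles.ProfileMatrix(X, np.arange(X.shape[1] + 1),
                                      pd.DataFrame(index=range(len(X))),
                                      "t", 1e7, 1.0)

    def test_separable_archetypes_fully_recovered(self):
        rng = np.random.default_rng(14)
        X = np.vstack([rng.poisson(5, (20, 10)), rng.poisson(200, (20, 10))]).astype(float)
        res = profiles.cluster_umrs(self._prof(X), k=2, seed=0)
        truth = np.repeat([0, 1], 20)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_k_one_centroid_is_column_mean(self):
        rng = np.random.default_rng(15)
        X = rng.poisson(30, (12, 6)).astype(float)
        res = profiles.cluster_umrs(self._prof(X), k=1, seed=0)
        np.testing.assert_allclose(res.centroids[0], np.log2(X + 8).mean(axis=0),
                                   rtol=1e-12)

    def test_incomplete_rows_excluded(self):
        X = np.ones((6, 4))
        X[2, 1] = np.nan
        res = profiles.cluster_umrs(self._prof(X), k=1, seed=0)
        assert res.labels[2] == -1
        assert (res.labels[[0, 1, 3, 4, 5]] == 0).all()

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            profiles.cluster_umrs(self._prof(np.ones((3, 4))), k=5, seed=0)

    def test_five_archetype_recovery(self):
        X, truth = simulate_profile_archetypes(seed=3)
        res = profiles.cluster_umrs(self._prof(X), k=5, seed=0)
        assert adjusted_rand_score(truth, res.labels) >= 0.9


class TestDifferentialBinding:
    def test_identical_libraries_zero(self):
        x = np.array([10.0, 50.0, 0.0])
        np.testing.assert_allclose(profiles.differential_binding(x, x), 0.0)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(16)
        es, npc = rng.poisson(30, 100).astype(float), rng.poisson(40, 100).astype(float)
        fwd = profiles.differential_binding(es, npc)
        rev = profiles.differential_binding(npc, es)
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_doubling_limit(self):
        es = np.full(10, 1e6)
        fc = profiles.differential_binding(es, 2 * es, es_library_size=1.0,
                                           np_library_size=1.0)
        np.testing.assert_allclose(fc, 1.0, atol=1e-4)

    def test_restriction_mask(self):
        x = np.array([10.0, 10.0])
        fc = profiles.differential_binding(x, x, restrict=np.array([True, False]))
        assert fc[0] == 0.0 and np.isnan(fc[1])


class TestRankedWindowMedians:
    def test_constant_values(self):
        out = profiles.ranked_window_medians(np.full(1200, 3.5), np.arange(1200), 500)
        assert list(out["median_value"]) == [3.5, 3.5]  # 700-tile tail merged? no: 500+700
        assert out["n"].sum() == 1200

    def test_monotone_case_three_blocks(self):
        v = np.random.default_rng(17).permutation(1500).astype(float)
        out = profiles.ranked_window_medians(v, v, 500)
        med = list(out["median_value"])
        assert len(med) == 3
        assert med[0] < med[1] < med[2]

    def test_matches_direct_computation(self):
        rng = np.random.default_rng(18)
        v = rng.normal(size=1000)
        key = rng.normal(size=1000)
        out = profiles.ranked_window_medians(v, key, 300)
        order = np.argsort(key, kind="mergesort")
        # blocks of 300: 300, 300, 300, tail of 100 (< 150) merged into previous
        expected_bounds = [(0, 300), (300, 600), (600, 1000)]
        assert len(out) == len(expected_bounds)
        for row, (i0, i1) in zip(out.itertuples(), expected_bounds):
            assert row.median_value == pytest.approx(np.median(v[order[i0:i1]]))
            assert row.mean_rank_key == pytest.approx(np.mean(key[order[i0:i1]]))

    def test_short_tail_kept_if_half_block(self):
        out = profiles.ranked_window_medians(np.arange(750.0), np.arange(750.0), 500)
        assert list(out["n"]) == [500, 250]

    def test_too_few_windows(self):
        with pytest.raises(ValueError):
            profiles.ranked_window_medians(np.arange(100.0), np.arange(100.0), 500)


class TestPromoterClassEnrichment:
    def test_extreme_class_equals_up_set(self):
        universe = {f"g{i}" for i in range(30)}
        up = {f"g{i}" for i in range(6)}
        res = profiles.promoter_class_enrichment(
            up, {"hit": up, "rest": universe - up}, universe)
        hit = res[res["class"] == "hit"].iloc[0]
        assert hit.fraction == 1.0
        assert hit.p_value == min(res["p_value"])
        assert hit.significant

    def test_exact_enumeration_example(self):
        universe = {f"g{i}" for i in range(20)}
        up = {f"g{i}" for i in range(5)}
        cls = {f"g{i}" for i in range(4)} | {"g10", "g11"}  # 6 genes, 4 up
        res = profiles.promoter_class_enrichment(up, {"c": cls}, universe)
        expect = sum(math.comb(5, k) * math.comb(15, 6 - k) for k in (4, 5)) / math.comb(20, 6)
        assert res.iloc[0].p_value == pytest.approx(expect, abs=1e-15)
        assert res.iloc[0].fraction == pytest.approx(4 / 6)

    def test_background_rate_not_significant(self):
        universe = {f"g{i}" for i in range(200)}
        up = {f"g{i}" for i in range(0, 200, 4)}      # 25% global up rate
        cls = {f"g{i}" for i in range(0, 80)}          # class with the same rate
        res = profiles.promoter_class_enrichment(up, {"c": cls}, universe)
        assert 0.05 < res.iloc[0].p_value

    def test_up_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            profiles.promoter_class_enrichment({"x"}, {"c": {"a"}}, {"a", "b"})

    def test_empty_class_skipped(self):
        res = profiles.promoter_class_enrichment(
            {"a"}, {"empty": set(), "full": {"a", "b"}}, {"a", "b"})
        assert list(res["class"]) == ["full"]
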