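import numpy as np
import pandas as pd
import pytest

from enhancerxai.calling import EnhancerRegion
from enhancerxai.io import GeneModel
from enhancerxai.profiles import (
    BIDIRECTIONAL,
    NEGATIVE,
    NON_TRANSCRIBED,
    POSITIVE,
    ProfileMatrix,
    annotation_category_map,
    body_percentile_score,
    compare_groups,
    directionality_score,
    feature_overlap_enrichment,
    obs_exp_signal_enrichment,
    profile_matrix,
    tad_proximity,
    winsorize_rescale,
)
from enhancerxai.tracks import tile_genome


@pytest.fixture
def grid():
    return tile_genome({"A": 100_000}, width=10)


def region(start, end, chrom="A"):
    return EnhancerRegion(chrom, start, end, 0.9)


class TestProfileMatrix:
    def test_constant_track(self, grid):
        track = np.full(grid.n_bins, 3.5)
        matrix = profile_matrix(track, [region(50_000, 50_500)], grid, flank=1000)
        assert np.all(matrix.values == 3.5)

    def test_rows_sorted_by_size_descending(self, grid):
        track = np.zeros(grid.n_bins)
        regions = [region(10_000, 10_500), region(40_000, 42_000)]
        matrix = profile_matrix(track, regions, grid, flank=1000)
        assert matrix.region_ids[0] == "A:40000-42000"

    def test_width_formula(self, grid):
        track = np.zeros(grid.n_bins)
        matrix = profile_matrix(track, [region(50_000, 50_100)], grid, flank=5000)
        assert matrix.values.shape[1] == 2 * 5000 // 10 + 1

    def test_off_chromosome_positions_missing(self, grid):
        track = np.ones(grid.n_bins)
        matrix = profile_matrix(track, [region(100, 200)], grid, flank=1000)
        assert np.isnan(matrix.values[0, 0])
        assert matrix.values[0, -1] == 1.0

    def test_empty_regions_rejected(self, grid):
        with pytest.raises(ValueError, match="regions"):
            profile_matrix(np.zeros(grid.n_bins), [], grid)


class TestWinsorize:
    def mat(self, values):
        arr = np.asarray(values, float)[None, :]
        return ProfileMatrix(["r1"], np.arange(arr.shape[1]), arr)

    def test_hand_computed_unsigned(self):
        out = winsorize_rescale(self.mat([-1.0, 0.0, 5.0, 10.0]), "unsigned", q=1.0)
        np.testing.assert_allclose(out.values[0], [0.0, 0.0, 0.5, 1.0])

    def test_signed_maps_extremes(self):
        out = winsorize_rescale(self.mat([-4.0, -1.0, 2.0, 8.0]), "signed", q=1.0)
        assert out.values[0][0] == -1.0
        assert out.values[0][-1] == 1.0
        assert -1.0 < out.values[0][1] < 0.0

    def test_bounds_for_any_input(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            arr = rng.normal(0, 5, size=(8, 30))
            uns = winsorize_rescale(ProfileMatrix(["x"] * 8, np.arange(30), arr.copy()))
            assert np.nanmin(uns.values) >= 0.0 and np.nanmax(uns.values) <= 1.0
            sig = winsorize_rescale(
                ProfileMatrix(["x"] * 8, np.arange(30), arr.copy()), "signed"
            )
            assert np.nanmin(sig.values) >= -1.0 and np.nanmax(sig.values) <= 1.0

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(1)
        for mode in ("unsigned", "signed"):
            arr = rng.normal(0, 5, size=(10, 50))
            once = winsorize_rescale(
                ProfileMatrix(["x"] * 10, np.arange(50), arr), mode
            )
            twice = winsorize_rescale(once, mode)
            np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_all_zero_warns_unchanged(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = winsorize_rescale(self.mat([0.0, 0.0, 0.0]))
        np.testing.assert_array_equal(out.values[0], [0.0, 0.0, 0.0])

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            winsorize_rescale(self.mat([1.0]), mode="weird")


class TestDirectionality:
    def tracks_with(self, grid, plus_windows, minus_windows, level=5.0):
        plus = np.zeros(grid.n_bins)
        minus = np.zeros(grid.n_bins)
        for lo, hi, scale in plus_windows:
            plus[lo // 10 : hi // 10] = level * scale
        for lo, hi, scale in minus_windows:
            minus[lo // 10 : hi // 10] = -level * scale
        return plus, minus

    def test_equal_strands_score_zero(self, grid):
        r = region(50_000, 51_000)
        plus, minus = self.tracks_with(
            grid, [(51_500, 52_000, 1.0)], [(49_000, 49_500, 1.0)]
        )
        rec = directionality_score(plus, minus, r, grid, pseudocount=0.0)
        assert rec.score == 0.0
        assert rec.label == BIDIRECTIONAL

    def test_ten_to_one_score_one(self, grid):
        r = region(50_000, 51_000)
        plus, minus = self.tracks_with(
            grid, [(51_500, 52_000, 1.0)], [(49_000, 49_500, 0.1)]
        )
        rec = directionality_score(plus, minus, r, grid, pseudocount=0.0)
        assert rec.score == pytest.approx(1.0, abs=1e-12)
        assert rec.label == POSITIVE

    def test_boundary_at_half_is_bidirectional(self, grid):
        r = region(50_000, 51_000)
        ratio = 10 ** 0.4
        plus, minus = self.tracks_with(
            grid, [(51_500, 52_000, ratio)], [(49_000, 49_500, 1.0)]
        )
        rec = directionality_score(plus, minus, r, grid, pseudocount=0.0)
        assert rec.score == pytest.approx(0.4, abs=1e-9)
        assert rec.label == BIDIRECTIONAL

    def test_negative_class(self, grid):
        r = region(50_000, 51_000)
        plus, minus = self.tracks_with(
            grid, [(51_500, 52_000, 0.05)], [(49_000, 49_500, 1.0)]
        )
        rec = directionality_score(plus, minus, r, grid, pseudocount=0.0)
        assert rec.label == NEGATIVE

    def test_non_transcribed_floor(self, grid):
        r = region(50_000, 51_000)
        plus = np.zeros(grid.n_bins)
        minus = np.zeros(grid.n_bins)
        rec = directionality_score(plus, minus, r, grid)
        assert rec.label == NON_TRANSCRIBED

    def test_off_chromosome_flank_returns_none(self, grid):
        assert directionality_score(
            np.zeros(grid.n_bins), np.zeros(grid.n_bins), region(100, 500), grid
        ) is None

    def test_strand_swap_antisymmetry_random(self, grid):
        rng = np.random.default_rng(2)
        plus = rng.uniform(0, 3, grid.n_bins)
        minus = -rng.uniform(0, 3, grid.n_bins)
        for _ in range(100):
            start = int(rng.integers(2000, 90_000))
            r = region(start, start + int(rng.integers(100, 2000)))
            fwd = directionality_score(plus, minus, r, grid)
            swapped = directionality_score(-minus, -plus, r, grid)
            assert swapped.score == pytest.approx(-fwd.score, abs=1e-12)


class TestSignalEnrichment:
    def test_whole_genome_identity(self, grid):
        rng = np.random.default_rng(3)
        track = rng.uniform(0, 1, grid.n_bins)
        rec = obs_exp_signal_enrichment(
            track, [region(0, 100_000)], grid, "genome"
        )
        assert rec.log2_ratio == pytest.approx(0.0, abs=1e-12)

    def test_double_mean_gives_one(self, grid):
        track = np.ones(grid.n_bins)
        track[: grid.n_bins // 2] = 2.0  # first half doubled
        track[grid.n_bins // 2 :] = 0.0
        rec = obs_exp_signal_enrichment(track, [region(0, 50_000)], grid)
        assert rec.log2_ratio == pytest.approx(1.0)

    def test_brute_force_mean_oracle(self):
        rng = np.random.default_rng(4)
        grid = tile_genome({"A": 100_000}, width=10)  # 1e4 bins
        track = rng.uniform(0, 2, grid.n_bins)
        regions = [region(s, s + 700) for s in (5_000, 42_000, 77_700)]
        rec = obs_exp_signal_enrichment(track, regions, grid)
        mask = np.zeros(grid.n_bins, dtype=bool)
        for r in regions:
            for b in range(grid.n_bins):
                lo, hi = b * 10, (b + 1) * 10
                if r.start < hi and lo < r.end:
                    mask[b] = True
        expected = np.log2(track[mask].mean() / track.mean())
        assert rec.log2_ratio == pytest.approx(expected, abs=1e-12)

    def test_empty_group_rejected(self, grid):
        with pytest.raises(ValueError, match="group"):
            obs_exp_signal_enrichment(np.ones(grid.n_bins), [], grid)


def toy_genes():
    # gene on [10000, 16000): exons [10000,12000) & [14000,16000),
    # first intron [12000,14000), 5'UTR [10000,10200), 3'UTR [15800,16000)
    return [
        GeneModel(
            "g1",
            "A",
            10_000,
            16_000,
            "+",
            exons=[(10_000, 12_000), (14_000, 16_000)],
            utr5=(10_000, 10_200),
            utr3=(15_800, 16_000),
        )
    ]


class TestFeatureOverlap:
    def test_regions_inside_first_intron(self, grid):
        cmap = annotation_category_map(toy_genes(), grid)
        records = feature_overlap_enrichment([region(12_500, 13_000)], cmap)
        by_cat = {r.category: r for r in records}
        assert by_cat["first_intron"].observed == pytest.approx(1.0)
        assert by_cat["exon"].observed == 0.0

    def test_precedence_promoter_over_intergenic(self, grid):
        cmap = annotation_category_map(toy_genes(), grid)
        arr = cmap["A"]
        # promoter paints [9750, 10000)
        from enhancerxai.profiles import CATEGORY_PRECEDENCE

        code = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
        assert arr[9_800] == code["promoter"]
        assert arr[10_100] == code["utr5"]
        assert arr[15_900] == code["utr3"]
        assert arr[11_000] == code["exon"]
        assert arr[13_000] == code["first_intron"]
        assert arr[50_000] == code["intergenic"]

    def test_base_count_oracle(self, grid):
        cmap = annotation_category_map(toy_genes(), grid)
        regions = [region(9_900, 10_400), region(13_900, 14_200)]
        records = feature_overlap_enrichment(regions, cmap)
        arr = cmap["A"]
        from enhancerxai.profiles import CATEGORY_PRECEDENCE

        covered = np.concatenate([arr[9_900:10_400], arr[13_900:14_200]])
        total_region = len(covered)
        for rec in records:
            code = CATEGORY_PRECEDENCE.index(rec.category)
            assert rec.observed == pytest.approx(np.mean(covered == code))
            assert rec.expected == pytest.approx(np.mean(arr == code))

    def test_minus_strand_first_intron(self, grid):
        genes = [
            GeneModel(
                "g2",
                "A",
                20_000,
                26_000,
                "-",
                exons=[(20_000, 22_000), (24_000, 26_000)],
            )
        ]
        assert genes[0].first_intron() == (22_000, 24_000)


class TestTadProximity:
    def borders(self, *positions):
        return pd.DataFrame(
            [("A", p, p + 1) for p in positions], columns=["chrom", "start", "end"]
        )

    def test_within_two_kb(self):
        flags = tad_proximity([region(10_000, 11_000)], self.borders(12_500))
        assert flags["A:10000-11000"] is True

    def test_beyond_two_kb(self):
        flags = tad_proximity([region(10_000, 11_000)], self.borders(13_500))
        assert flags["A:10000-11000"] is False

    def test_linear_scan_oracle(self):
        rng = np.random.default_rng(5)
        regions = [region(int(s), int(s) + 500) for s in rng.integers(0, 95_000, 100)]
        positions = rng.integers(0, 100_000, 30)
        flags = tad_proximity(regions, self.borders(*positions))
        for r in regions:
            expected = False
            for p in positions:
                if r.start < p + 1 and p < r.end:
                    gap = 0
                elif p >= r.end:
                    gap = p - r.end
                else:
                    gap = r.start - (p + 1)
                if gap <= 2000:
                    expected = True
            assert flags[r.region_id] == expected


class TestBodyPercentile:
    def test_constant_region(self, grid):
        track = np.full(grid.n_bins, 4.2)
        assert body_percentile_score(track, region(10_000, 11_000), grid) == 4.2

    def test_sort_based_oracle(self, grid):
        track = np.zeros(grid.n_bins)
        track[1000:1100] = np.arange(1, 101)  # bins for [10000, 11000)
        score = body_percentile_score(track, region(10_000, 11_000), grid)
        assert score == pytest.approx(np.percentile(np.arange(1, 101), 95))

    def test_homogeneous_scaling(self, grid):
        rng = np.random.default_rng(6)
        track = rng.uniform(0, 1, grid.n_bins)
        r = region(10_000, 12_000)
        assert body_percentile_score(2 * track, r, grid) == pytest.approx(
            2 * body_percentile_score(track, r, grid)
        )

    def test_sub_bin_region_rejected(self):
        grid = tile_genome({"A": 1000}, width=10)
        with pytest.raises(ValueError, match="spans no bins"):
            body_percentile_score(np.zeros(grid.n_bins), region(2000, 2005), grid)


class TestGroupComparison:
    def test_identical_groups_reject_at_nominal_rate(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_trials = 400
        for _ in range(n_trials):
            a = rng.normal(0, 1, 40)
            b = rng.normal(0, 1, 40)
            _, p = compare_groups(a, b)
            rejections += p < 0.05
        rate = rejections / n_trials
        assert 0.01 <= rate <= 0.10  # ~5% nominal

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1.5, 1, 200)
        _, p = compare_groups(a, b)
        assert p < 1e-6
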