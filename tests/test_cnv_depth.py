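"""Depth-ratio CNV detection: normalization, calling, thinning, benchmarking."""

import numpy as np
import pytest

import panelsmith as ps
from panelsmith.cnv_depth import TargetDepthMatrix, sensitivity_curve, target_depth_matrix
from panelsmith.genomic_io import DepthProfile, GenomicInterval


def _targets(n, size=100, gap=1000, chrom="chr1"):
    return [GenomicInterval(chrom, i * (size + gap), i * (size + gap) + size,
                            f"t{i}") for i in range(n)]


def _matrix(depths):
    depths = np.asarray(depths, dtype=float)
    return TargetDepthMatrix(
        targets=_targets(depths.shape[1]),
        samples=[f"S{i}" for i in range(depths.shape[0])],
        mean_depth=depths,
    )


class TestNormalization:
    def test_identical_profiles_give_zero_ratios(self):
        ratios, flagged = ps.normalize_target_depths(
            _matrix(np.full((4, 8), 100.0)))
        assert np.allclose(ratios.to_numpy(), 0.0)
        assert flagged == []

    def test_doubled_target_stands_out(self):
        depths = np.full((4, 8), 100.0)
        depths[0, 3] = 200.0
        ratios, _ = ps.normalize_target_depths(_matrix(depths))
        assert ratios.iloc[0, 3] == pytest.approx(1.0, abs=0.02)
        others = np.delete(ratios.to_numpy(), 3, axis=1)
        assert np.allclose(others, 0.0, atol=1e-9)

    def test_global_scaling_of_one_sample_cancels_exactly(self):
        rng = np.random.default_rng(0)
        depths = rng.uniform(50, 400, size=(4, 30))
        base, _ = ps.normalize_target_depths(_matrix(depths))
        scaled = depths.copy()
        scaled[2] *= 7.3
        after, _ = ps.normalize_target_depths(_matrix(scaled))
        assert np.allclose(base.to_numpy()[2], after.to_numpy()[2],
                           atol=1e-6)

    def test_all_zero_target_pinned_at_zero_and_flagged(self):
        depths = np.full((3, 5), 80.0)
        depths[:, 2] = 0.0
        ratios, flagged = ps.normalize_target_depths(_matrix(depths))
        assert flagged == [2]
        assert np.all(ratios.to_numpy()[:, 2] == 0.0)

    def test_single_sample_is_an_error(self):
        with pytest.raises(ValueError):
            ps.normalize_target_depths(_matrix(np.full((1, 4), 10.0)))


class TestCalling:
    def test_consecutive_deleted_targets_merge_into_one_call(self):
        targets = _targets(9)
        log2 = [0, 0, -1.0, -1.0, -1.0, -1.0, -1.0, 0, 0]
        (call,) = ps.call_depth_cnv(targets, log2, min_targets=3)
        assert call.kind == "del"
        assert call.n_targets == 5
        assert call.interval.start == targets[2].start
        assert call.interval.end == targets[6].end
        assert call.mean_log2 == pytest.approx(-1.0)

    def test_flat_profile_yields_no_calls(self):
        assert ps.call_depth_cnv(_targets(10), [0.0] * 10) == []

    def test_single_target_event_suppressed_below_min_targets(self):
        log2 = [0, 0, -1.2, 0, 0]
        assert ps.call_depth_cnv(_targets(5), log2, min_targets=3) == []

    def test_duplication_threshold(self):
        log2 = [0.6, 0.6, 0.6, 0.0]
        (call,) = ps.call_depth_cnv(_targets(4), log2, min_targets=3)
        assert call.kind == "dup"

    def test_runs_do_not_cross_chromosomes(self):
        targets = _targets(2) + _targets(2, chrom="chr2")
        assert ps.call_depth_cnv(targets, [-1.0] * 4, min_targets=3) == []


class TestDownsampling:
    def _profile(self, depth=400, n=10_000):
        return DepthProfile("s", {("1", p): depth for p in range(n)},
                            source_reads=40_000_000)

    def test_fraction_one_is_identity(self):
        prof = self._profile()
        out = ps.downsample_depth(prof, ps.DownsampleSpec(fraction=1.0))
        assert out.depths == prof.depths

    def test_fraction_zero_empties_profile(self):
        out = ps.downsample_depth(self._profile(),
                                  ps.DownsampleSpec(fraction=0.0))
        assert all(d == 0 for d in out.depths.values())

    def test_mean_matches_binomial_expectation(self):
        prof = self._profile(depth=400, n=10_000)
        spec = ps.DownsampleSpec(target_reads=20_000_000,
                                 source_reads=40_000_000, seed=42)
        out = ps.downsample_depth(prof, spec)
        mean = np.mean(list(out.depths.values()))
        se = np.sqrt(400 * 0.25 / 10_000)
        assert abs(mean - 200) < 20 * 3 * se

    def test_reproducible_for_fixed_seed(self):
        prof = self._profile(n=500)
        spec = ps.DownsampleSpec(fraction=0.3, seed=7)
        assert ps.downsample_depth(prof, spec).depths == \
               ps.downsample_depth(prof, spec).depths

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValueError):
            ps.DownsampleSpec(target_reads=2, source_reads=1)


class TestComparison:
    def test_self_comparison_is_perfect(self):
        iv = GenomicInterval("chr22", 49_453_028, 51_181_061)
        cmp = ps.compare_cnv_calls(iv, iv)
        assert cmp.reciprocal_overlap == 1.0
        assert cmp.start_delta_bp == cmp.end_delta_bp == 0
        assert cmp.matched

    def test_kilobase_scale_breakpoint_deltas(self):
        truth = GenomicInterval("chr22", 49_453_028, 51_181_061)
        called = GenomicInterval("chr22", 49_411_085, 51_244_066)
        cmp = ps.compare_cnv_calls(truth, called)
        assert cmp.start_delta_bp == 41_943
        assert cmp.end_delta_bp == -63_005
        assert cmp.matched

    def test_disjoint_intervals_do_not_match(self):
        cmp = ps.compare_cnv_calls(GenomicInterval("chr1", 0, 100),
                                   GenomicInterval("chr1", 500, 600))
        assert cmp.reciprocal_overlap == 0.0 and not cmp.matched

    def test_missing_call(self):
        cmp = ps.compare_cnv_calls(GenomicInterval("chr1", 0, 100), None)
        assert cmp.called is None and not cmp.matched


class TestSensitivity:
    def test_large_event_at_full_depth_always_found(self):
        table = sensitivity_curve(cnv_sizes_bp=[2_000_000],
                                  depth_fractions=[1.0], replicates=5,
                                  seed=3)
        assert table.iloc[0, 0] == 1.0

    def test_zero_depth_finds_nothing(self):
        table = sensitivity_curve(cnv_sizes_bp=[2_000_000],
                                  depth_fractions=[0.0], replicates=3,
                                  seed=3)
        assert table.iloc[0, 0] == 0.0

    def test_sub_detection_floor_events_always_missed(self):
        # 100 kb spans at most 2 of the 60-kb-spaced targets: below
        # min_targets at any depth
        table = sensitivity_curve(cnv_sizes_bp=[100_000],
                                  depth_fractions=[0.5, 1.0], replicates=5,
                                  seed=11)
        assert (table.to_numpy() == 0.0).all()


class TestTargetDepthMatrix:
    def test_mean_depth_from_profiles(self):
        targets = _targets(2, size=10, gap=10)
        prof = DepthProfile(
            "a", {("1", p): 30 for p in range(targets[0].start,
                                              targets[0].end)})
        mat = target_depth_matrix([prof, DepthProfile("b")], targets)
        assert mat.mean_depth[0, 0] == 30.0
        assert mat.mean_depth[0, 1] == 0.0
        assert mat.mean_depth[1, 0] == 0.0
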