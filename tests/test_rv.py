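"""The RV metric: deviations, threshold ladder, tube volumes, reliability."""

import math

import numpy as np
import pytest

from rvskill import (
    AlignmentError,
    DeviationMatrix,
    DomainError,
    Path3D,
    RepetitionSet,
    compute_rv_curve,
    conventional_working_volume,
    pointwise_deviations,
    reliability_at_threshold,
    threshold_ladder,
    tube_volume,
    volume_at_reliability,
)
from conftest import shifted_repset


def _repset_from_points(std_pts, rep_pts_list):
    std = Path3D(np.asarray(std_pts, float), label="std")
    reps = tuple(Path3D(np.asarray(p, float), label=f"r{i}") for i, p in enumerate(rep_pts_list))
    return std, RepetitionSet(std, reps, len(std))


class TestDeviations:
    def test_identical_repetition_is_zero(self, line_standard):
        std, rs = _repset_from_points(line_standard.points, [line_standard.points])
        assert pointwise_deviations(std, rs).values.max() == 0.0

    def test_three_four_five(self):
        std, rs = _repset_from_points([[0, 0, 0], [1, 0, 0]], [[[3, 4, 0], [1, 0, 0]]])
        assert pointwise_deviations(std, rs).values[0, 0] == pytest.approx(5.0)

    def test_constant_offset(self, helix_standard):
        shifted = Path3D(helix_standard.points + 1.0)  # (1,1,1) offset
        rs = RepetitionSet(helix_standard, (shifted,), len(helix_standard))
        dev = pointwise_deviations(helix_standard, rs)
        np.testing.assert_allclose(dev.values, math.sqrt(3.0))

    def test_length_mismatch_instructs_resampling(self, helix_standard, line_standard):
        with pytest.raises(AlignmentError, match="resample"):
            RepetitionSet(helix_standard, (line_standard,), len(helix_standard))


class TestThresholdLadder:
    matrix = DeviationMatrix(np.array([[1.0, 3.0], [2.0, 2.0]]))

    def test_full_multiset(self):
        np.testing.assert_array_equal(
            threshold_ladder(self.matrix, "full").thresholds, [3.0, 2.0, 1.0]
        )

    def test_per_path_maxima(self):
        np.testing.assert_array_equal(
            threshold_ladder(self.matrix, "maxima").thresholds, [3.0, 2.0]
        )

    def test_all_zero_collapses_to_single_rung(self):
        zeros = DeviationMatrix(np.zeros((3, 4)))
        np.testing.assert_array_equal(threshold_ladder(zeros, "full").thresholds, [0.0])


class TestTubeVolume:
    @pytest.mark.parametrize(
        "d,h,expected", [(1, 1, math.pi), (0, 5, 0.0), (2, 3, 12 * math.pi)]
    )
    def test_closed_form(self, d, h, expected):
        assert tube_volume(d, h) == pytest.approx(expected)

    @pytest.mark.parametrize("d,h", [(-1, 1), (1, 0), (1, -2)])
    def test_domain_errors(self, d, h):
        with pytest.raises(DomainError):
            tube_volume(d, h)


class TestReliability:
    dev = DeviationMatrix(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]))

    def test_partial_containment(self):
        assert reliability_at_threshold(self.dev, 3.0) == (0.6, 3)

    def test_global_max_contains_all(self):
        assert reliability_at_threshold(self.dev, 5.0) == (1.0, 5)

    def test_below_every_maximum(self):
        assert reliability_at_threshold(self.dev, 0.5) == (0.0, 0)


class TestRVCurve:
    def test_two_repetition_hand_example(self, helix_standard):
        # rigid x-shifts make per-path maxima exactly 1 and 2
        rs = shifted_repset(helix_standard, [1.0, 2.0])
        curve = compute_rv_curve(helix_standard, rs, h_mode="fixed", fixed_h=2.0)
        assert [(p.d, p.reliability) for p in curve.points] == [(2.0, 1.0), (1.0, 0.5)]
        assert curve.points[0].volume == pytest.approx(8 * math.pi)
        assert curve.points[1].volume == pytest.approx(2 * math.pi)

    def test_identical_repetition_single_zero_rung(self, helix_standard):
        rs = RepetitionSet(helix_standard, (Path3D(helix_standard.points.copy()),), len(helix_standard))
        curve = compute_rv_curve(helix_standard, rs)
        assert len(curve.points) == 1
        p = curve.points[0]
        assert (p.d, p.volume, p.reliability) == (0.0, 0.0, 1.0)

    def test_single_repetition_reliability_binary(self, helix_standard):
        rs = shifted_repset(helix_standard, [0.7])
        curve = compute_rv_curve(helix_standard, rs, ladder_origin="full")
        assert set(p.reliability for p in curve.points) <= {0.0, 1.0}

    def test_first_rung_has_full_reliability(self, helix_standard, small_repset):
        curve = compute_rv_curve(helix_standard, small_repset)
        assert curve.points[0].reliability == 1.0


class TestVolumeAtReliability:
    def test_scan_for_smallest_qualifying_volume(self, helix_standard):
        rs = shifted_repset(helix_standard, [1.0, 2.0, 3.0])  # R rungs 1, 2/3, 1/3
        curve = compute_rv_curve(helix_standard, rs, h_mode="fixed", fixed_h=1.0)
        assert volume_at_reliability(curve, 0.95) == pytest.approx(9 * math.pi)
        assert volume_at_reliability(curve, 0.5) == pytest.approx(4 * math.pi)

    def test_target_one_returns_max_deviation_rung(self, helix_standard, small_repset):
        curve = compute_rv_curve(helix_standard, small_repset)
        assert volume_at_reliability(curve, 1.0) == curve.max_volume

    @pytest.mark.parametrize("target", [0.0, -0.1, 1.5])
    def test_target_domain(self, helix_standard, small_repset, target):
        curve = compute_rv_curve(helix_standard, small_repset)
        with pytest.raises(DomainError):
            volume_at_reliability(curve, target)


class TestConventionalWorkingVolume:
    @staticmethod
    def _axis_star(r, center=(0.0, 0.0, 0.0)):
        """6 points at distance r from the center along each axis."""
        pts = np.vstack([np.eye(3) * r, -np.eye(3) * r]) + np.asarray(center)
        return Path3D(pts)

    def test_symmetric_configuration(self):
        std = self._axis_star(1.0)
        rs = RepetitionSet(std, (self._axis_star(2.0),), 6)
        assert conventional_working_volume(rs) == pytest.approx(32 * math.pi / 3)

    def test_coincident_points_zero(self, helix_standard):
        flat = Path3D(np.zeros((len(helix_standard), 3)) + 1.0)
        rs = RepetitionSet(Path3D(np.zeros((len(helix_standard), 3)) + 1.0), (flat,), len(flat))
        assert conventional_working_volume(rs) == 0.0

    def test_mean_of_sphere_volumes(self):
        std = self._axis_star(1.0)
        rs = RepetitionSet(std, (self._axis_star(1.0), self._axis_star(2.0, center=(5, 5, 5))), 6)
        expected = (4 / 3 * math.pi + 32 / 3 * math.pi) / 2  # = 6*pi
        assert conventional_working_volume(rs) == pytest.approx(expected)


def brute_force_reliability(values: np.ndarray, d_j: float) -> tuple[float, int]:
    """Literal double loop over (m, n) applying the state function d_mn - d_j."""
    n_success = 0
    for row in values:
        if all(d_mn - d_j <= 0 for d_mn in row):
            n_success += 1
    return n_success / len(values), n_success


class TestInvariants:
    def test_reliability_non_decreasing_in_threshold(self, helix_standard, small_repset):
        curve = compute_rv_curve(helix_standard, small_repset, ladder_origin="full")
        rel = [p.reliability for p in curve.points]  # descending d
        assert all(a >= b for a, b in zip(rel, rel[1:]))

    def test_maxima_ladder_is_lossless(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m, n = rng.integers(1, 11), rng.integers(1, 21)
            dev = DeviationMatrix(rng.exponential(1.0, size=(m, n)))
            full = threshold_ladder(dev, "full").thresholds
            maxima = threshold_ladder(dev, "maxima").thresholds
            for d in np.concatenate([full, maxima]):
                assert reliability_at_threshold(dev, d) == brute_force_reliability(dev.values, d)
            # R(d) is a step function that only changes at per-path maxima:
            # at any full-multiset rung it equals R at the largest maxima
            # rung not exceeding it (or 0 below the smallest maximum)
            for d in full:
                below = maxima[maxima <= d]
                expected = reliability_at_threshold(dev, below[0])[0] if below.size else 0.0
                assert reliability_at_threshold(dev, d)[0] == expected

    def test_reliability_multiples_of_one_over_m(self, helix_standard, small_repset):
        curve = compute_rv_curve(helix_standard, small_repset, ladder_origin="full")
        for p in curve.points:
            assert (p.reliability * small_repset.M) == pytest.approx(round(p.reliability * small_repset.M))

    def test_max_volume_monotone_under_appending(self, helix_standard, small_repset):
        vols = []
        for m in range(1, small_repset.M + 1):
            curve = compute_rv_curve(helix_standard, small_repset.prefix(m))
            vols.append(curve.max_volume)
        assert all(b >= a for a, b in zip(vols, vols[1:]))
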