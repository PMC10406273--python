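"""Voxel-wise summary maps and group inference: closed-form examples,
brute-force oracles and invariance properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from parc5d.spatiodynamics import (Map3D, collect_peak_values,
                                   difference_map, select_peaks,
                                   subject_mean, temporal_deviation,
                                   threshold_mask, time_mean,
                                   voxelwise_ttest)

RNG = np.random.default_rng(7)


def _random_map4d(shape=(4, 5, 3, 6)):
    return RNG.random(shape)


class TestTimeMean:
    def test_matches_bruteforce_loops(self):
        omega = _random_map4d()
        out = time_mean(omega).data
        expect = np.zeros(omega.shape[:3])
        for idx in np.ndindex(omega.shape[:3]):
            acc = 0.0
            for t in range(omega.shape[-1]):
                acc += omega[idx + (t,)]
            expect[idx] = acc / omega.shape[-1]
        np.testing.assert_allclose(out, expect, rtol=1e-10)

    def test_constant_series_identity(self):
        frame = RNG.random((3, 3, 3))
        omega = np.repeat(frame[..., None], 5, axis=-1)
        np.testing.assert_allclose(time_mean(omega).data, frame)

    def test_single_timepoint(self):
        omega = _random_map4d((2, 2, 2, 1))
        np.testing.assert_array_equal(time_mean(omega).data,
                                      omega[..., 0])

    def test_hand_average(self):
        omega = np.zeros((1, 1, 1, 2))
        omega[0, 0, 0] = [0.2, 0.4]
        assert time_mean(omega).data[0, 0, 0] == pytest.approx(0.3)


class TestTemporalDeviation:
    def test_matches_bruteforce_loops(self):
        omega = _random_map4d()
        out = temporal_deviation(omega).data
        expect = np.zeros(omega.shape[:3])
        for idx in np.ndindex(omega.shape[:3]):
            acc = 0.0
            for t in range(omega.shape[-1] - 1):
                acc += abs(omega[idx + (t + 1,)] - omega[idx + (t,)])
            expect[idx] = acc
        np.testing.assert_allclose(out, expect, rtol=1e-10)

    def test_zero_iff_constant(self):
        frame = RNG.random((3, 3, 3))
        omega = np.repeat(frame[..., None], 4, axis=-1)
        assert np.all(temporal_deviation(omega).data == 0)
        omega[1, 1, 1, 2] += 0.5
        dev = temporal_deviation(omega).data
        assert dev[1, 1, 1] > 0
        dev[1, 1, 1] = 0
        assert np.all(dev == 0)

    def test_hand_value_and_monotone_telescoping(self):
        omega = np.zeros((1, 1, 1, 3))
        omega[0, 0, 0] = [1.0, 3.0, 2.0]
        assert temporal_deviation(omega).data[0, 0, 0] == pytest.approx(3.0)
        omega[0, 0, 0] = [0.1, 0.4, 0.9]  # monotone: last - first
        assert temporal_deviation(omega).data[0, 0, 0] == pytest.approx(0.8)

    def test_requires_two_timepoints(self):
        with pytest.raises(ValueError, match="2 timepoints"):
            temporal_deviation(_random_map4d((2, 2, 2, 1)))

    def test_nonnegative(self):
        assert temporal_deviation(_random_map4d()).data.min() >= 0


class TestSubjectMean:
    def test_closed_form_and_symmetry(self):
        a = Map3D(RNG.random((3, 3, 3)), "time_mean")
        b = Map3D(RNG.random((3, 3, 3)), "time_mean")
        m = subject_mean([a, b])
        np.testing.assert_allclose(m.data, (a.data + b.data) / 2)
        assert m.kind == "group_mean"
        np.testing.assert_array_equal(subject_mean([b, a]).data, m.data)

    def test_single_subject_identity(self):
        a = Map3D(RNG.random((2, 2, 2)), "temporal_deviation")
        m = subject_mean([a])
        np.testing.assert_array_equal(m.data, a.data)
        assert m.kind == "group_deviation"

    def test_mixed_kinds_rejected(self):
        a = Map3D(np.zeros((2, 2, 2)), "time_mean")
        b = Map3D(np.zeros((2, 2, 2)), "temporal_deviation")
        with pytest.raises(ValueError, match="mixed"):
            subject_mean([a, b])

    def test_commutes_with_time_mean(self):
        """Mean over time then subjects equals mean over subjects then
        time."""
        stack = [_random_map4d((3, 3, 3, 5)) for _ in range(4)]
        a = subject_mean([time_mean(o) for o in stack]).data
        b = time_mean(np.mean(stack, axis=0)).data
        np.testing.assert_allclose(a, b, rtol=1e-10)


class TestVoxelwiseTTest:
    def _maps(self, arr):
        return [Map3D(a, "time_mean") for a in arr]

    def test_hand_worked_example(self):
        """Groups (1,2,3) vs (2,3,4) at a single voxel: t = -sqrt(3/2)."""
        gc = self._maps(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1, 1))
        gs = self._maps(np.array([2.0, 3.0, 4.0]).reshape(3, 1, 1, 1))
        res = voxelwise_ttest(gc, gs)
        assert res.tmap.data[0, 0, 0] == pytest.approx(-np.sqrt(1.5))
        assert res.tmap.data[0, 0, 0] == pytest.approx(-1.224744871)

    def test_matches_scipy_welch(self):
        """Independent oracle: scipy's Welch t-test, voxel by voxel."""
        xc = RNG.random((5, 3, 3, 3))
        xs = RNG.random((7, 3, 3, 3))
        res = voxelwise_ttest(self._maps(xc), self._maps(xs))
        t_ref, p_ref = stats.ttest_ind(xc, xs, axis=0, equal_var=False)
        np.testing.assert_allclose(res.tmap.data, t_ref, rtol=1e-10)
        np.testing.assert_allclose(res.pmap, p_ref, rtol=1e-8)

    def test_identical_groups_zero(self):
        x = RNG.random((4, 2, 2, 2))
        res = voxelwise_ttest(self._maps(x), self._maps(x.copy()))
        np.testing.assert_array_equal(res.tmap.data, 0)

    def test_antisymmetric_under_swap(self):
        xc, xs = RNG.random((4, 2, 2, 2)), RNG.random((4, 2, 2, 2))
        a = voxelwise_ttest(self._maps(xc), self._maps(xs)).tmap.data
        b = voxelwise_ttest(self._maps(xs), self._maps(xc)).tmap.data
        np.testing.assert_allclose(a, -b, rtol=1e-12)

    def test_sign_matches_mean_difference(self):
        xc, xs = RNG.random((6, 3, 3, 3)), RNG.random((6, 3, 3, 3))
        res = voxelwise_ttest(self._maps(xc), self._maps(xs))
        np.testing.assert_array_equal(np.sign(res.tmap.data),
                                      np.sign(res.mean_c - res.mean_s))

    def test_zero_variance_voxels_masked(self):
        xc = np.zeros((3, 2, 2, 2))
        xs = np.zeros((3, 2, 2, 2))
        res = voxelwise_ttest(self._maps(xc), self._maps(xs))
        assert not res.valid.any()
        np.testing.assert_array_equal(res.tmap.data, 0)

    def test_group_size_guard(self):
        x = RNG.random((1, 2, 2, 2))
        with pytest.raises(ValueError, match=">=2"):
            voxelwise_ttest(self._maps(x), self._maps(RNG.random((3, 2, 2, 2))))


class TestDifferenceAndPeaks:
    def test_difference_locality_and_antisymmetry(self):
        a = Map3D(np.zeros((3, 3, 3)), "group_mean")
        b = Map3D(np.zeros((3, 3, 3)), "group_mean")
        b.data[1, 2, 0] = 0.5
        d = difference_map(a, b)
        assert d.data[1, 2, 0] == -0.5
        assert np.count_nonzero(d.data) == 1
        np.testing.assert_array_equal(difference_map(b, a).data, -d.data)

    def test_peaks_argmax_argmin(self):
        diff = Map3D(np.zeros((4, 4, 4)), "difference")
        diff.data[1, 1, 1] = 2.0
        diff.data[2, 3, 0] = -1.5
        sel = select_peaks(diff, np.ones((4, 4, 4), bool))
        assert sel.positive == (1, 1, 1)
        assert sel.negative == (2, 3, 0)

    def test_all_positive_reports_missing_negative(self):
        diff = Map3D(np.full((2, 2, 2), 0.3), "difference")
        sel = select_peaks(diff, np.ones((2, 2, 2), bool))
        assert sel.negative is None
        assert sel.positive is not None

    def test_mask_restricts_peaks(self):
        diff = Map3D(np.zeros((3, 3, 3)), "difference")
        diff.data[0, 0, 0] = 5.0
        diff.data[1, 1, 1] = 1.0
        mask = np.ones((3, 3, 3), bool)
        mask[0, 0, 0] = False
        assert select_peaks(diff, mask).positive == (1, 1, 1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_peaks(Map3D(np.ones((2, 2, 2)), "difference"),
                         np.zeros((2, 2, 2), bool))

    def test_collect_peak_values(self):
        diff = Map3D(np.zeros((2, 2, 2)), "difference")
        diff.data[0, 0, 0] = 1.0
        sel = select_peaks(diff, np.ones((2, 2, 2), bool))
        maps = [Map3D(np.full((2, 2, 2), v), "time_mean")
                for v in (0.1, 0.2, 0.7)]
        sel = collect_peak_values(sel, maps, ["control", "control",
                                              "patient"])
        labels, values = sel.values["positive"]
        np.testing.assert_allclose(values, [0.1, 0.2, 0.7])
        assert labels == ["control", "control", "patient"]


class TestThresholdMask:
    def test_zero_cutoff_full_mask(self):
        m = Map3D(RNG.random((4, 4, 4)), "tstat")
        assert threshold_mask(m, cutoff=0.0).all()

    def test_quantile_order_statistics(self):
        data = np.arange(1000, dtype=float).reshape(10, 10, 10) + 1
        mask = threshold_mask(Map3D(data, "tstat"), quantile=0.99)
        assert mask.sum() == 10

    def test_stricter_rule_gives_subset(self):
        m = Map3D(RNG.standard_normal((5, 5, 5)), "tstat")
        loose = threshold_mask(m, cutoff=0.5)
        strict = threshold_mask(m, cutoff=1.5)
        assert not (strict & ~loose).any()
        q_loose = threshold_mask(m, quantile=0.5)
        q_strict = threshold_mask(m, quantile=0.9)
        assert not (q_strict & ~q_loose).any()

    def test_invalid_arguments(self):
        m = Map3D(np.ones((2, 2, 2)), "tstat")
        with pytest.raises(ValueError):
            threshold_mask(m, quantile=1.5)
        with pytest.raises(ValueError):
            threshold_mask(m)
        with pytest.raises(ValueError):
            threshold_mask(m, cutoff=1.0, quantile=0.5)


@given(arrays(np.float64, (2, 2, 2, 5),
              elements=st.floats(0, 1, allow_nan=False)))
def test_deviation_zero_exactly_where_constant(omega):
    """Property: the temporal-deviation map is zero at a voxel iff its
    time series is constant."""
    dev = temporal_deviation(omega).data
    const = np.all(omega == omega[..., :1], axis=-1)
    np.testing.assert_array_equal(dev == 0, const)
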