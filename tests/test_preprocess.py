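"""Volume discard, framewise displacement, motion QC, nuisance regression,
and the band-pass filter, checked against direct evaluation of their
definitions and a discrete-Fourier power oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fcnet
from fcnet.preprocess import (
    QC_MAX_TRANSLATION_MM,
    RoiTimeSeries,
    NuisanceModel,
    bandpass,
    build_nuisance_model,
    discard_initial_volumes,
    framewise_displacement,
    friston24,
    qc_exclude,
    regress_nuisance,
)


def _ts(values, tr=1.0):
    values = np.asarray(values, dtype=float)
    return RoiTimeSeries(values, [f"R{i}" for i in range(values.shape[1])], tr)


class TestDiscard:
    def test_default_discard_leaves_390_of_400(self, rng):
        ts = _ts(rng.standard_normal((400, 4)))
        out = discard_initial_volumes(ts, 10)
        assert out.n_volumes == 390
        np.testing.assert_array_equal(out.values, ts.values[10:])

    def test_zero_discard_is_identity(self, rng):
        ts = _ts(rng.standard_normal((20, 3)))
        np.testing.assert_array_equal(discard_initial_volumes(ts, 0).values, ts.values)

    def test_discard_to_single_volume(self, rng):
        ts = _ts(rng.standard_normal((11, 3)))
        out = discard_initial_volumes(ts, 10)
        assert out.n_volumes == 1
        np.testing.assert_array_equal(out.values[0], ts.values[-1])

    def test_discarding_all_volumes_raises(self, rng):
        ts = _ts(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError):
            discard_initial_volumes(ts, 10)


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        fd = framewise_displacement(np.zeros((50, 6)))
        np.testing.assert_array_equal(fd, 0.0)

    def test_single_translation_step(self):
        m = np.zeros((10, 6))
        m[5:, 0] = 0.5  # 0.5 mm step on x at volume 5
        fd = framewise_displacement(m)
        assert fd[5] == pytest.approx(0.5)
        assert np.all(fd[np.arange(10) != 5] == 0)

    def test_rotation_converted_on_50mm_sphere(self):
        m = np.zeros((10, 6))
        m[3:, 4] = 0.01  # 0.01 rad step
        fd = framewise_displacement(m)
        assert fd[3] == pytest.approx(0.5)

    def test_first_volume_fd_is_zero(self, rng):
        fd = framewise_displacement(rng.standard_normal((30, 6)))
        assert fd[0] == 0.0

    def test_wrong_column_count_raises(self):
        with pytest.raises(ValueError):
            framewise_displacement(np.zeros((10, 5)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset=st.floats(-5, 5, allow_nan=False))
    def test_invariant_to_constant_offset(self, offset):
        rng = np.random.default_rng(7)
        m = rng.standard_normal((40, 6)) * 0.1
        np.testing.assert_allclose(
            framewise_displacement(m + offset),
            framewise_displacement(m),
            atol=1e-10,
        )


class TestQc:
    def test_zero_motion_passes(self):
        assert qc_exclude(np.zeros((20, 6))).passed

    def test_translation_over_bound_fails_with_reason(self):
        m = np.zeros((20, 6))
        m[10, 1] = 1.6
        res = qc_exclude(m)
        assert not res.passed
        assert "translation" in res.reason and "1.6" in res.reason
        assert res.max_translation_mm == pytest.approx(1.6)

    def test_rotation_over_bound_fails_in_degrees(self):
        m = np.zeros((20, 6))
        m[4, 5] = np.radians(1.7)
        res = qc_exclude(m)
        assert not res.passed
        assert "rotation" in res.reason

    def test_both_under_bound_passes(self):
        m = np.zeros((20, 6))
        m[3, 0] = 1.4
        m[3, 4] = np.radians(1.4)
        assert qc_exclude(m).passed

    def test_bound_is_strict(self):
        m = np.zeros((20, 6))
        m[3, 2] = QC_MAX_TRANSLATION_MM
        assert qc_exclude(m).passed


class TestNuisanceRegression:
    def test_intercept_only_on_zero_mean_input(self, rng):
        x = rng.standard_normal((50, 3))
        x -= x.mean(axis=0)
        model = NuisanceModel(np.ones((50, 1)), ["intercept"])
        # trend is appended automatically, so remove linear content first
        t = np.linspace(-1, 1, 50)
        x -= np.outer(t, (t @ x) / (t @ t))
        out = regress_nuisance(_ts(x), model)
        np.testing.assert_allclose(out.values, x, atol=1e-10)

    def test_input_equal_to_regressor_gives_zero_residuals(self, rng):
        reg = rng.standard_normal(60)
        model = NuisanceModel(reg[:, None], ["motion"])
        out = regress_nuisance(_ts(np.column_stack([reg, 2 * reg])), model)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_trend_removed_sinusoid_survives(self):
        n = 200
        t = np.arange(n)
        sinus = np.sin(2 * np.pi * 7 * t / n)
        x = 0.05 * t + 3.0 + sinus
        model = build_nuisance_model(n)
        out = regress_nuisance(_ts(x[:, None]), model)
        # the sinusoid is not exactly orthogonal to the trend; compare to
        # its own least-squares detrending
        X = model.regressors
        expect = sinus - X @ np.linalg.lstsq(X, sinus, rcond=None)[0]
        np.testing.assert_allclose(out.values[:, 0], expect, atol=1e-8)

    def test_residualization_is_idempotent(self, rng):
        x = rng.standard_normal((80, 4))
        model = build_nuisance_model(80, motion=rng.standard_normal((80, 6)) * 0.1)
        once = regress_nuisance(_ts(x), model)
        twice = regress_nuisance(once, model)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_exactly_collinear_columns_are_pruned(self, rng):
        reg = rng.standard_normal(40)
        X = np.column_stack([reg, reg, 2 * reg])
        model = NuisanceModel(X, ["a", "a_dup", "a_scaled"])
        out = regress_nuisance(_ts(rng.standard_normal((40, 2))), model)
        assert out.n_volumes == 40  # no crash; duplicates dropped

    def test_friston24_shape_and_content(self, rng):
        m = rng.standard_normal((30, 6))
        f = friston24(m)
        assert f.shape == (30, 24)
        np.testing.assert_array_equal(f[:, :6], m)
        np.testing.assert_array_equal(f[1:, 6:12], m[:-1])
        np.testing.assert_array_equal(f[:, 12:18], m**2)


class TestBandpass:
    def _power(self, x):
        return float(np.sum(np.abs(x) ** 2))

    def test_stopband_sinusoid_suppressed(self):
        t = np.arange(400)
        x = np.sin(2 * np.pi * 0.2 * t)  # 0.2 Hz at TR = 1 s
        out = bandpass(_ts(x[:, None]))
        assert self._power(out.values) < 0.01 * self._power(x)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(400)
        x = np.sin(2 * np.pi * 0.04 * t)
        out = bandpass(_ts(x[:, None]))
        assert self._power(out.values) > 0.95 * self._power(x)

    def test_constant_series_maps_to_zero(self):
        out = bandpass(_ts(np.full((100, 2), 3.7)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_output_mean_near_zero(self, rng):
        out = bandpass(_ts(rng.standard_normal((256, 3)) + 5.0))
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-10)

    def test_preserves_shape_and_labels(self, rng):
        ts = _ts(rng.standard_normal((128, 5)))
        out = bandpass(ts)
        assert out.values.shape == ts.values.shape
        assert out.region_labels == ts.region_labels

    def test_high_cut_at_or_above_nyquist_rejected(self, rng):
        ts = _ts(rng.standard_normal((100, 2)), tr=1.0)
        with pytest.raises(ValueError):
            bandpass(ts, 0.01, 0.5)

    def test_spectral_support_matches_band(self, rng):
        # DFT oracle: all retained power lies inside [low, high]
        x = rng.standard_normal((512, 1))
        out = bandpass(_ts(x), 0.02, 0.1)
        spec = np.abs(np.fft.rfft(out.values[:, 0]))
        freqs = np.fft.rfftfreq(512, 1.0)
        outside = (freqs < 0.02) | (freqs > 0.1)
        assert np.all(spec[outside] < 1e-8)


class TestFullSubjectPipeline:
    def test_runs_and_preserves_shape(self, rng):
        values = rng.standard_normal((400, 8))
        ts = RoiTimeSeries(values, [f"R{i}" for i in range(8)], 1.0)
        motion = rng.standard_normal((400, 6)) * 0.05
        out = fcnet.preprocess_subject(ts, motion=motion)
        assert out.values.shape == (390, 8)
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-8)
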