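"""Framewise displacement, censoring, confound regression, band-pass filter."""

import numpy as np
import pytest

from funconn import (
    FdSeries,
    MotionParams,
    RoiTimeSeries,
    bandpass,
    censor_volumes,
    compute_fd,
    friston24,
    regress_confounds,
)
from funconn.preprocess import InsufficientDataError, clean


def make_ts(values, tr=2.0):
    values = np.asarray(values, dtype=float)
    return RoiTimeSeries(
        values=values, tr_seconds=tr,
        region_names=tuple(f"R{i}" for i in range(values.shape[1])),
    )


class TestFd:
    def test_zero_motion(self):
        fd = compute_fd(MotionParams(np.zeros((10, 6)), 2.0))
        assert np.all(fd.values == 0)

    def test_translation_step(self):
        m = np.zeros((5, 6))
        m[2:, 0] = 0.5  # 0.5 mm step at frame index 2
        fd = compute_fd(MotionParams(m, 2.0))
        expected = np.zeros(5)
        expected[2] = 0.5
        np.testing.assert_allclose(fd.values, expected)

    def test_rotation_step_scaled_by_sphere_radius(self):
        m = np.zeros((4, 6))
        m[1:, 4] = 0.01  # 0.01 rad step -> 0.5 mm on a 50 mm sphere
        fd = compute_fd(MotionParams(m, 2.0))
        np.testing.assert_allclose(fd.values, [0, 0.5, 0, 0])

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            MotionParams(np.zeros((5, 4)), 2.0)


class TestCensor:
    def test_all_below_threshold_keeps_everything(self):
        ts = make_ts(np.arange(12).reshape(6, 2))
        fd = FdSeries(np.zeros(6))
        out, kept = censor_volumes(ts, fd, min_frames=2)
        np.testing.assert_array_equal(out.values, ts.values)
        np.testing.assert_array_equal(kept, np.arange(6))

    def test_single_frame_removed(self):
        ts = make_ts([[1, 1], [2, 2], [3, 3]])
        fd = FdSeries(np.array([0, 0.6, 0.2]))
        out, kept = censor_volumes(ts, fd, min_frames=2)
        np.testing.assert_array_equal(kept, [0, 2])
        np.testing.assert_array_equal(out.values, [[1, 1], [3, 3]])

    def test_insufficient_data_signalled(self):
        ts = make_ts(np.ones((3, 2)) * [[1], [2], [3]])
        fd = FdSeries(np.array([0, 0.9, 0.9]))
        with pytest.raises(InsufficientDataError):
            censor_volumes(ts, fd, min_frames=2)


class TestFriston24:
    def test_zero_motion_all_zero(self):
        assert np.all(friston24(MotionParams(np.zeros((8, 6)), 2.0)) == 0)

    def test_constant_motion_structure(self):
        c = 0.3
        x = friston24(MotionParams(np.full((5, 6), c), 2.0))
        assert x.shape == (5, 24)
        assert np.all(x[:, :6] == c)
        assert np.all(x[0, 6:12] == 0) and np.all(x[1:, 6:12] == c)  # lag
        assert np.all(x[:, 12:18] == c**2)
        assert np.all(x[0, 18:24] == 0) and np.all(x[1:, 18:24] == c**2)

    def test_always_24_columns(self):
        rng = np.random.default_rng(0)
        x = friston24(MotionParams(rng.standard_normal((30, 6)), 2.0))
        assert x.shape[1] == 24


class TestRegressConfounds:
    def test_region_equal_to_confound_becomes_zero(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal(40)
        ts = make_ts(np.column_stack([sig, rng.standard_normal(40)]))
        out = regress_confounds(ts, sig[:, None])
        np.testing.assert_allclose(out.values[:, 0], 0, atol=1e-10)

    def test_orthogonal_confounds_only_demean(self):
        t = 64
        ts = make_ts(np.column_stack([np.sin(np.arange(t)), np.cos(np.arange(t)) + 5]))
        conf = np.zeros((t, 1))
        conf[:, 0] = (-1.0) ** np.arange(t) * 1e-18  # numerically negligible
        out = regress_confounds(ts, conf)
        np.testing.assert_allclose(out.values, ts.values - ts.values.mean(axis=0), atol=1e-8)

    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(2)
        ts = make_ts(rng.standard_normal((50, 3)))
        conf = rng.standard_normal((50, 4))
        out = regress_confounds(ts, conf)
        np.testing.assert_allclose(conf.T @ out.values, 0, atol=1e-8)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        ts = make_ts(rng.standard_normal((60, 3)))
        conf = rng.standard_normal((60, 5))
        once = regress_confounds(ts, conf)
        twice = regress_confounds(once, conf)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_collinear_columns_dropped(self, caplog):
        rng = np.random.default_rng(4)
        ts = make_ts(rng.standard_normal((30, 2)))
        c = rng.standard_normal((30, 1))
        out = regress_confounds(ts, np.hstack([c, c]))  # duplicate column
        assert out.values.shape == ts.values.shape


class TestBandpass:
    def test_dc_removed(self):
        ts = make_ts(np.full((100, 2), 7.0))
        out = bandpass(ts, 0.01, 0.08)
        np.testing.assert_allclose(out.values, 0, atol=1e-10)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(200) * 2.0  # TR = 2 s
        sig = np.sin(2 * np.pi * 0.04 * t)
        out = bandpass(make_ts(sig[:, None]), 0.01, 0.08)
        assert out.values[:, 0].max() == pytest.approx(sig.max(), rel=0.01)

    def test_stopband_sinusoid_removed(self):
        t = np.arange(200) * 2.0
        sig = np.sin(2 * np.pi * 0.2 * t)
        out = bandpass(make_ts(sig[:, None]), 0.01, 0.08)
        assert np.abs(out.values).max() <= 0.01 * np.abs(sig).max()

    def test_band_outside_nyquist_rejected(self):
        ts = make_ts(np.random.default_rng(0).standard_normal((50, 1)), tr=2.0)
        with pytest.raises(ValueError):
            bandpass(ts, 0.01, 0.3)  # Nyquist is 0.25 Hz


class TestCleanPipeline:
    def test_metadata_preserved(self):
        rng = np.random.default_rng(5)
        ts = make_ts(rng.standard_normal((120, 3)))
        m = np.hstack([rng.normal(0, 0.01, (120, 3)), rng.normal(0, 1e-4, (120, 3))])
        out, kept = clean(ts, motion=MotionParams(m, 2.0), min_frames=50)
        assert out.region_names == ts.region_names
        assert out.tr_seconds == ts.tr_seconds

    def test_spiky_frames_censored(self):
        rng = np.random.default_rng(6)
        ts = make_ts(rng.standard_normal((150, 3)))
        m = np.hstack([rng.normal(0, 0.005, (150, 3)), rng.normal(0, 5e-5, (150, 3))])
        m[70, 0] += 2.0  # large spike
        out, kept = clean(ts, motion=MotionParams(m, 2.0), min_frames=50)
        assert 70 not in kept or 71 not in kept
        assert out.n_timepoints == kept.size
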