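import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nhkit.preprocess import (
    BoldRun,
    MotionTrace,
    PreprocessConfig,
    bandpass,
    detrend_linear,
    discard_initial,
    framewise_displacement,
    friston24,
    motion_exclude,
    preprocess_run,
    regress_nuisance,
)
from .conftest import make_run


def _run_and_motion(t=200, v=24):
    rng = np.random.default_rng(0)
    run = make_run(rng.standard_normal((v, t)), grid=(4, 3, 2))
    params = rng.standard_normal((t, 6))
    params[:, :3] *= 0.05   # mm
    params[:, 3:] *= 0.002  # radians, well under the 2 degree rule
    motion = MotionTrace(params)
    return run, motion


class TestDiscard:
    def test_drops_frames_synchronized(self):
        run, motion = _run_and_motion(t=200)
        run2, motion2 = discard_initial(run, motion, 10)
        assert run2.n_volumes == 190
        assert motion2.n_frames == 190
        np.testing.assert_array_equal(run2.data, run.data[..., 10:])
        np.testing.assert_array_equal(motion2.params, motion.params[10:])

    def test_zero_is_identity(self):
        run, motion = _run_and_motion(t=30)
        run2, motion2 = discard_initial(run, motion, 0)
        np.testing.assert_array_equal(run2.data, run.data)

    def test_discarding_everything_refused(self):
        run, motion = _run_and_motion(t=30)
        with pytest.raises(ValueError):
            discard_initial(run, motion, 30)


class TestMotionExclude:
    def test_still_subject_kept(self):
        dec = motion_exclude(MotionTrace(np.zeros((50, 6))), PreprocessConfig())
        assert dec.keep

    def test_translation_over_2mm_excluded_with_axis_in_reason(self):
        p = np.zeros((50, 6))
        p[30, 0] = 2.5
        dec = motion_exclude(MotionTrace(p), PreprocessConfig())
        assert not dec.keep
        assert "x" in dec.reason and "30" in dec.reason

    @pytest.mark.parametrize("deg,expect_keep", [(1.9, True), (2.0, True), (2.1, False)])
    def test_rotation_threshold_is_strict(self, deg, expect_keep):
        p = np.zeros((50, 6))
        p[10, 5] = np.radians(deg)
        dec = motion_exclude(MotionTrace(p), PreprocessConfig())
        assert dec.keep is expect_keep

    def test_displacement_measured_from_first_frame(self):
        # constant 5 mm offset from zero on all frames: no displacement at all
        p = np.full((40, 6), 0.0)
        p[:, 1] = 5.0
        assert motion_exclude(MotionTrace(p), PreprocessConfig()).keep


class TestFramewiseDisplacement:
    def test_constant_trace_gives_zero(self):
        s = framewise_displacement(MotionTrace(np.ones((30, 6))))
        assert np.all(s.fd == 0) and s.mean_fd == 0

    def test_translation_step_identity(self):
        p = np.zeros((30, 6))
        p[10:, 0] = 1.0  # single 1 mm step
        s = framewise_displacement(MotionTrace(p))
        assert s.fd[10] == pytest.approx(1.0)
        assert np.count_nonzero(s.fd) == 1

    def test_rotation_converted_on_50mm_sphere(self):
        p = np.zeros((30, 6))
        p[5:, 3] = 0.01  # 0.01 rad step
        s = framewise_displacement(MotionTrace(p))
        assert s.fd[5] == pytest.approx(0.5)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=6))
    def test_invariant_to_constant_column_offsets(self, offsets):
        rng = np.random.default_rng(7)
        p = 0.1 * rng.standard_normal((40, 6))
        fd1 = framewise_displacement(MotionTrace(p)).fd
        fd2 = framewise_displacement(MotionTrace(p + np.asarray(offsets))).fd
        np.testing.assert_allclose(fd1, fd2, atol=1e-12)


class TestDetrend:
    def test_removes_exact_line(self):
        t = np.arange(40, dtype=float)
        run = make_run(np.tile(2 * t + 1, (24, 1)))
        out = detrend_linear(run)
        np.testing.assert_allclose(out.data, 0, atol=1e-10)

    def test_residual_orthogonal_to_trend_basis(self, rng):
        run = make_run(rng.standard_normal((24, 50)))
        out = detrend_linear(run).data.reshape(24, 50)
        t = np.arange(50, dtype=float)
        assert np.abs(out.sum(axis=1)).max() < 1e-8
        assert np.abs(out @ t).max() < 1e-8

    def test_idempotent(self, rng):
        run = make_run(rng.standard_normal((24, 50)))
        once = detrend_linear(run)
        twice = detrend_linear(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)


class TestBandpass:
    def _sinusoid(self, freq_hz, t=200, tr=2.5):
        time = np.arange(t) * tr
        return make_run(np.tile(np.sin(2 * np.pi * freq_hz * time), (24, 1)), tr_s=tr)

    def test_inband_sinusoid_retained(self):
        run = self._sinusoid(0.04)
        out = bandpass(run, 0.01, 0.08)
        ratio = out.data.std() / run.data.std()
        assert ratio >= 0.95

    def test_out_of_band_sinusoid_suppressed(self):
        run = self._sinusoid(0.15)
        out = bandpass(run, 0.01, 0.08)
        assert out.data.std() / run.data.std() <= 0.05

    def test_dc_removed(self):
        run = make_run(np.full((24, 100), 3.7))
        out = bandpass(run, 0.01, 0.08)
        np.testing.assert_allclose(out.data, 0, atol=1e-10)

    def test_band_outside_nyquist_rejected(self):
        run = self._sinusoid(0.04)
        with pytest.raises(ValueError):
            bandpass(run, 0.01, 0.3)  # Nyquist is 0.2 Hz at TR 2.5 s

    def test_zero_phase_no_shift(self):
        # an in-band sinusoid keeps its phase: correlation with input ~ 1
        run = self._sinusoid(0.04)
        out = bandpass(run, 0.01, 0.08)
        a, b = run.data.reshape(24, -1)[0], out.data.reshape(24, -1)[0]
        assert np.corrcoef(a, b)[0, 1] > 0.999


class TestNuisance:
    def test_friston24_matches_brute_force(self, rng):
        p = rng.standard_normal((30, 6))
        x = friston24(MotionTrace(p))
        assert x.shape == (30, 24)
        lag = np.vstack([np.zeros((1, 6)), p[:-1]])
        np.testing.assert_array_equal(x[:, :6], p)
        np.testing.assert_array_equal(x[:, 6:12], lag)
        np.testing.assert_array_equal(x[:, 12:18], p**2)
        np.testing.assert_array_equal(x[:, 18:24], lag**2)

    def test_series_in_regressor_span_removed(self, rng):
        v, t = 24, 80
        data = rng.standard_normal((v, t))
        wm = np.zeros((4, 3, 2), bool)
        wm[0, 0, 0] = True
        data[0] = np.sin(np.arange(t) / 3.0)
        data[1] = 2.0 * data[0] + 5.0  # exactly in the span of wm mean + intercept
        run = make_run(data)
        out = regress_nuisance(run, None, wm_mask=wm, filter_regressors=False)
        np.testing.assert_allclose(out.data.reshape(v, t)[1], 0, atol=1e-8)

    def test_orthogonal_series_unchanged(self, rng):
        v, t = 24, 80
        data = rng.standard_normal((v, t))
        wm = np.zeros((4, 3, 2), bool)
        wm[0, 0, 0] = True
        run = make_run(data)
        out = regress_nuisance(run, None, wm_mask=wm, filter_regressors=False)
        # residual of voxel 5 is the OLS projection complement: recompute by hand
        x = np.column_stack([np.ones(t), data[0]])
        beta = np.linalg.lstsq(x, data[5], rcond=None)[0]
        np.testing.assert_allclose(out.data.reshape(v, t)[5], data[5] - x @ beta, atol=1e-10)

    def test_collinear_columns_dropped_with_warning(self, rng):
        run = make_run(rng.standard_normal((24, 60)))
        motion = MotionTrace(np.zeros((60, 6)))  # 24 all-zero regressors
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_nuisance(run, motion, filter_regressors=False)
        assert out.data.shape == run.data.shape


class TestFullPreprocess:
    def test_geometry_preserved_and_finite(self):
        run, motion = _run_and_motion(t=200)
        res = preprocess_run(run, motion, PreprocessConfig())
        assert res.decision.keep
        assert res.run.data.shape[:3] == run.data.shape[:3]
        assert res.run.n_volumes == 190
        np.testing.assert_array_equal(res.run.affine, run.affine)
        assert np.isfinite(res.run.data).all()
        assert res.summary.mean_fd >= 0

    def test_excluded_subject_returns_no_run(self):
        run, motion = _run_and_motion(t=50)
        motion.params[30, 2] = 4.0
        res = preprocess_run(run, motion, PreprocessConfig(n_discard=5))
        assert not res.decision.keep and res.run is None
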