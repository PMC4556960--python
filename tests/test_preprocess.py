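"""Conditioning steps checked against independent regression / Fourier
oracles, plus the motion quality-control rules."""

import numpy as np
import pytest

from fcdpipe.images import BoldImage, FcdPipeError, MotionTrace
from fcdpipe.preprocess import (
    bandpass_filter,
    count_motion_spikes,
    detrend_linear,
    discard_initial_volumes,
    framewise_displacement,
    motion_excluded,
    regress_nuisance,
)


def make_bold(data, tr_s=2.0, mask=None):
    data = np.asarray(data, float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldImage(data=data, voxel_size_mm=3.0, tr_s=tr_s, brain_mask=mask)


def flat_motion(t):
    return MotionTrace(np.zeros((t, 3)), np.zeros((t, 3)))


class TestDiscard:
    @pytest.mark.parametrize("total, n, remaining", [(250, 10, 240), (64, 0, 64), (12, 10, 2)])
    def test_volume_arithmetic(self, rng, total, n, remaining):
        bold = make_bold(rng.standard_normal((2, 2, 2, total)))
        out = discard_initial_volumes(bold, n)
        assert out.n_volumes == remaining
        np.testing.assert_array_equal(out.data, bold.data[..., n:])
        assert out.provenance[-1].startswith("discard_initial_volumes")

    def test_discarding_everything_rejected(self, rng):
        bold = make_bold(rng.standard_normal((2, 2, 2, 10)))
        with pytest.raises(FcdPipeError, match="cannot discard"):
            discard_initial_volumes(bold, 10)


class TestDetrend:
    def test_pure_line_removed_exactly(self):
        t = np.arange(40, dtype=float)
        series = 3.0 + 0.5 * t
        bold = make_bold(np.broadcast_to(series, (2, 2, 2, 40)).copy())
        out = detrend_linear(bold)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_full_period_sinusoid_unchanged(self):
        # a centered cosine over whole periods is orthogonal to both the
        # intercept and the (centered) ramp
        n = 64
        t = np.arange(n, dtype=float) - (n - 1) / 2
        series = np.cos(2 * np.pi * 4 * t / n)
        bold = make_bold(series.reshape(1, 1, 1, -1))
        out = detrend_linear(bold)
        np.testing.assert_allclose(out.data[0, 0, 0], series, atol=1e-8)

    def test_matches_polyfit_oracle(self, rng):
        data = rng.standard_normal((3, 2, 2, 30))
        out = detrend_linear(make_bold(data))
        t = np.arange(30, dtype=float)
        for idx in np.ndindex(3, 2, 2):
            coef = np.polyfit(t, data[idx], 1)
            np.testing.assert_allclose(out.data[idx], data[idx] - np.polyval(coef, t),
                                       atol=1e-10)

    def test_idempotent(self, rng):
        bold = make_bold(rng.standard_normal((2, 2, 2, 25)))
        once = detrend_linear(bold)
        twice = detrend_linear(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_too_short_rejected(self, rng):
        with pytest.raises(FcdPipeError, match="3 time points"):
            detrend_linear(make_bold(rng.standard_normal((1, 1, 1, 2))))


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(200, dtype=float) * 2.0
        series = np.cos(2 * np.pi * 0.05 * t)
        out = bandpass_filter(make_bold(series.reshape(1, 1, 1, -1)))
        ratio = out.data[0, 0, 0].std() / series.std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_out_of_band_sinusoid_suppressed(self):
        t = np.arange(200, dtype=float) * 2.0  # Nyquist 0.25 Hz
        series = np.cos(2 * np.pi * 0.2 * t)
        out = bandpass_filter(make_bold(series.reshape(1, 1, 1, -1)))
        assert out.data[0, 0, 0].std() < 0.01 * series.std()

    def test_matches_fourier_masking_oracle(self, rng):
        data = rng.standard_normal((2, 2, 1, 80))
        out = bandpass_filter(make_bold(data), 0.01, 0.08)
        freqs = np.fft.fftfreq(80, d=2.0)
        keep = (np.abs(freqs) >= 0.01) & (np.abs(freqs) <= 0.08)
        oracle = np.real(np.fft.ifft(np.fft.fft(data, axis=-1) * keep, axis=-1))
        np.testing.assert_allclose(out.data, oracle, atol=1e-10)

    def test_output_power_confined_to_band(self, rng):
        data = rng.standard_normal((1, 1, 1, 400))
        out = bandpass_filter(make_bold(data))
        spec = np.abs(np.fft.rfft(out.data[0, 0, 0])) ** 2
        freqs = np.fft.rfftfreq(400, d=2.0)
        outside = (freqs < 0.01) | (freqs > 0.08)
        assert spec[outside].sum() < 1e-18 * spec.sum()

    def test_idempotent(self, rng):
        bold = make_bold(rng.standard_normal((2, 2, 2, 60)))
        once = bandpass_filter(bold)
        twice = bandpass_filter(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_band_above_nyquist_rejected(self, rng):
        bold = make_bold(rng.standard_normal((1, 1, 1, 50)), tr_s=2.0)
        with pytest.raises(FcdPipeError, match="Nyquist"):
            bandpass_filter(bold, 0.01, 0.3)


class TestNuisanceRegression:
    def setup_masks(self, shape):
        csf = np.zeros(shape, bool)
        wm = np.zeros(shape, bool)
        csf[0, 0, 0] = True
        wm[-1, -1, -1] = True
        return csf, wm

    def test_voxel_equal_to_global_mean_zeroed(self, rng):
        t = 40
        data = rng.standard_normal((3, 3, 3, t))
        # a voxel set to the mean of all others equals the overall mean
        others = (data.reshape(-1, t).sum(axis=0) - data[1, 1, 0]) / 26
        data[1, 1, 0] = others
        bold = make_bold(data)
        csf, wm = self.setup_masks((3, 3, 3))
        motion = MotionTrace(rng.normal(0, 0.1, (t, 3)), rng.normal(0, 0.1, (t, 3)))
        out = regress_nuisance(bold, motion, csf, wm, use_global=True)
        np.testing.assert_allclose(out.data[1, 1, 0], 0.0, atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        t = 50
        data = rng.standard_normal((3, 2, 2, t))
        motion = MotionTrace(rng.standard_normal((t, 3)), rng.standard_normal((t, 3)))
        bold = make_bold(data)
        csf, wm = self.setup_masks((3, 2, 2))
        out = regress_nuisance(bold, motion, csf, wm, use_global=True)
        design = np.column_stack(
            [np.ones(t), motion.as_array(),
             data[0, 0, 0], data[-1, -1, -1], data.mean(axis=(0, 1, 2))]
        )
        beta = np.linalg.solve(design.T @ design, design.T @ data.reshape(-1, t).T)
        oracle = data.reshape(-1, t) - (design @ beta).T
        np.testing.assert_allclose(out.data.reshape(-1, t), oracle, atol=1e-8)

    def test_residuals_orthogonal_to_regressors(self, rng):
        t = 40
        data = rng.standard_normal((3, 3, 3, t))
        motion = MotionTrace(rng.standard_normal((t, 3)), rng.standard_normal((t, 3)))
        csf, wm = self.setup_masks((3, 3, 3))
        out = regress_nuisance(make_bold(data), motion, csf, wm)
        resid = out.data.reshape(-1, t)
        for col in motion.as_array().T:
            np.testing.assert_allclose(resid @ col, 0.0, atol=1e-8)
        np.testing.assert_allclose(resid.sum(axis=1), 0.0, atol=1e-8)

    def test_collinear_design_names_columns(self, rng):
        t = 30
        data = rng.standard_normal((3, 3, 3, t))
        csf = np.zeros((3, 3, 3), bool)
        csf[0, 0, 0] = True
        with pytest.raises(FcdPipeError, match="csf_mean.*wm_mean"):
            # identical CSF and WM masks give identical mean regressors
            regress_nuisance(make_bold(data), flat_motion(t), csf, csf,
                             use_global=False)

    def test_masked_voxels_untouched(self, rng):
        t = 40
        data = rng.standard_normal((3, 3, 3, t))
        mask = np.ones((3, 3, 3), bool)
        mask[1, 1, 1] = False
        bold = make_bold(data, mask=mask)
        csf, wm = self.setup_masks((3, 3, 3))
        motion = MotionTrace(rng.standard_normal((t, 3)), rng.standard_normal((t, 3)))
        for step in (detrend_linear,
                     bandpass_filter,
                     lambda b: regress_nuisance(b, motion, csf, wm)):
            out = step(bold)
            np.testing.assert_array_equal(out.data[1, 1, 1], data[1, 1, 1])


class TestMotionQc:
    def test_exclusion_rule_is_strict_above_one(self):
        t = 20
        trans = np.zeros((t, 3))
        trans[5, 0] = 1.2
        assert motion_excluded(MotionTrace(trans, np.zeros((t, 3)))) is True
        assert motion_excluded(flat_motion(t)) is False
        trans[5, 0] = 1.0  # "more than" is strict
        assert motion_excluded(MotionTrace(trans, np.zeros((t, 3)))) is False

    def test_rotation_triggers_exclusion(self):
        t = 10
        rot = np.zeros((t, 3))
        rot[3, 2] = -1.5
        assert motion_excluded(MotionTrace(np.zeros((t, 3)), rot)) is True

    def test_constant_trace_has_no_spikes(self):
        assert count_motion_spikes(flat_motion(30), 0.2) == 0

    def test_single_step_is_one_spike(self):
        t = 30
        trans = np.zeros((t, 3))
        trans[10:, 1] = 0.4  # one step of 2x threshold
        assert count_motion_spikes(MotionTrace(trans, np.zeros((t, 3))), 0.2) == 1

    def test_spike_count_matches_loop_oracle(self, rng):
        t = 60
        trace = MotionTrace(rng.normal(0, 0.2, (t, 3)), rng.normal(0, 0.2, (t, 3)))
        thr = 0.5
        count = 0
        params = trace.as_array()
        for i in range(1, t):
            d = np.abs(params[i] - params[i - 1])
            fd = d[:3].sum() + np.deg2rad(d[3:]).sum() * 50.0
            count += fd > thr
        assert count_motion_spikes(trace, thr) == count
        assert len(framewise_displacement(trace)) == t
        assert framewise_displacement(trace)[0] == 0.0
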