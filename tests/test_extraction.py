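"""The five pulse-recovery methods, JADE, EMD/CEEMDAN and spatial averaging."""

import numpy as np
import pytest
from scipy.signal import periodogram

from ippgsim.config import SimulationConfig
from ippgsim.emd import ceemdan, emd
from ippgsim.errors import (
    DegenerateSignalError,
    InvalidParameterError,
    NoPulseFoundError,
)
from ippgsim.evaluation import estimate_hr_windows
from ippgsim.extraction import (
    RGBTrace,
    bandpass_filter,
    ceemdan_method,
    chrom_method,
    green_method,
    ica_method,
    pos_method,
    spatial_average,
)
from ippgsim.jade import jade
from ippgsim.pipeline import extract_method, simulate_cube
from ippgsim.ppg import generate_beat_sequence, normalize_unit, synthesize_ppg
from ippgsim.video import VideoCube

FS = 25.0


def _sine_trace(freqs=(1.2, 1.2, 1.2), amps=(0.01, 0.02, 0.015),
                duration=30.0, offset=0.5):
    t = np.arange(int(duration * FS)) / FS
    chans = [offset + a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps)]
    return RGBTrace(r=chans[0], g=chans[1], b=chans[2], fs=FS)


def _dominant_freq(x, fs=FS):
    f, p = periodogram(x - x.mean(), fs=fs, window="hann")
    return f[np.argmax(p)]


class TestSpatialAverage:
    def test_uniform_frames_give_constant_trace(self):
        frames = np.full((10, 4, 4, 3), 0.25, dtype=np.float32)
        trace = spatial_average(VideoCube(frames=frames, fps=FS))
        np.testing.assert_allclose(trace.r, 0.25)
        np.testing.assert_allclose(trace.g, 0.25)

    def test_single_pixel_mask(self):
        rng = np.random.default_rng(0)
        frames = rng.random((20, 4, 4, 3)).astype(np.float32)
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 2] = True
        trace = spatial_average(VideoCube(frames=frames, fps=FS), mask)
        np.testing.assert_allclose(trace.g, frames[:, 1, 2, 1])
        assert trace.roi_pixel_count == 1

    def test_empty_mask_rejected(self):
        frames = np.zeros((5, 4, 4, 3), dtype=np.float32)
        with pytest.raises(InvalidParameterError):
            spatial_average(VideoCube(frames=frames, fps=FS), np.zeros((4, 4), bool))


class TestBandpassAndGreen:
    def test_passband_identity(self):
        trace = _sine_trace()
        out = green_method(trace).waveform
        assert _dominant_freq(out) == pytest.approx(1.2, abs=1.0 / 30.0)

    def test_dc_only_input_maps_to_zero(self):
        trace = _sine_trace(amps=(0.0, 0.0, 0.0))
        out = green_method(trace).waveform
        assert np.max(np.abs(out)) < 1e-9

    def test_out_of_band_attenuation_20db(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 0.25 * t) + np.sin(2 * np.pi * 1.2 * t)
        y = bandpass_filter(x, FS, (0.7, 4.0))

        def amp_at(sig, f0):
            spec = np.abs(np.fft.rfft(sig))
            freqs = np.fft.rfftfreq(sig.size, 1 / FS)
            return spec[np.argmin(np.abs(freqs - f0))]

        atten_slow = amp_at(y, 0.25) / amp_at(x, 0.25)
        keep_fast = amp_at(y, 1.2) / amp_at(x, 1.2)
        assert 20 * np.log10(atten_slow) <= -20.0
        assert keep_fast > 0.7

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            bandpass_filter(np.zeros(100), FS, (0.7, 20.0))


class TestJadeICA:
    def _mixture(self, duration=120.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration * FS)) / FS
        S = np.vstack([
            np.sin(2 * np.pi * 0.3 * t),
            np.sin(2 * np.pi * 1.2 * t + 1.0),
            np.sin(2 * np.pi * 3.0 * t + 2.0),
        ])
        A = rng.normal(size=(3, 3))
        return S, A @ S

    def test_source_recovery_up_to_permutation_and_scale(self):
        S, X = self._mixture()
        rec, _ = jade(X)
        for s in S:
            best = max(abs(np.corrcoef(s, r)[0, 1]) for r in rec)
            assert best > 0.95

    def test_agrees_with_fastica_cross_check(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        S, X = self._mixture(seed=3)
        rec, _ = jade(X)
        fica = sklearn.FastICA(n_components=3, random_state=0, whiten="unit-variance")
        rec2 = fica.fit_transform(X.T).T
        # each JADE component matches some FastICA component up to sign
        for r in rec:
            best = max(abs(np.corrcoef(r, q)[0, 1]) for q in rec2)
            assert best > 0.95

    def test_component_spectrum_peaks_in_band_with_sidelobes_down(self):
        _, X = self._mixture(seed=1)
        rec, _ = jade(X)
        margins = []
        for comp in rec:
            f, p = periodogram(comp, fs=FS, window="hann")
            cardiac = p[(f > 1.1) & (f < 1.3)].max()
            others = p[(f < 1.0) | (f > 1.5)].max()
            margins.append(10 * np.log10(cardiac / others))
        # some recovered component is the 1.2 Hz source, sidelobes >= 20 dB down
        assert max(margins) >= 20.0

    def test_identical_channels_fall_back_with_warning(self):
        beats = generate_beat_sequence(72.0, duration=30.0)
        pulse = normalize_unit(synthesize_ppg(beats, fs=FS)).samples
        trace = RGBTrace(r=pulse.copy(), g=pulse.copy(), b=pulse.copy(), fs=FS)
        with pytest.warns(RuntimeWarning):
            result = ica_method(trace)
        assert result.diagnostics["fallback"]
        band = bandpass_filter(pulse - pulse.mean(), FS)
        r = abs(np.corrcoef(result.waveform, band)[0, 1])
        assert r > 0.95

    def test_constant_input_rejected(self):
        n = int(30 * FS)
        trace = RGBTrace(r=np.ones(n), g=np.ones(n), b=np.ones(n), fs=FS)
        with pytest.raises(DegenerateSignalError):
            ica_method(trace)

    def test_too_short_input_rejected(self):
        trace = _sine_trace(duration=5.0)
        with pytest.raises(InvalidParameterError):
            ica_method(trace)


class TestCEEMDAN:
    def test_emd_is_complete(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(400)
        parts = emd(x)
        np.testing.assert_allclose(np.sum(parts, axis=0), x, atol=1e-9)

    def test_ceemdan_is_complete_and_deterministic(self):
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * 1.2 * t) + 0.5 * t / t.max()
        a = ceemdan(x, trials=30, seed=7)
        b = ceemdan(x, trials=30, seed=7)
        np.testing.assert_allclose(np.sum(a, axis=0), x, atol=1e-9)
        assert len(a) == len(b)
        for u, v in zip(a, b):
            np.testing.assert_array_equal(u, v)

    def test_selects_cardiac_imf_over_drift(self):
        t = np.arange(int(40 * FS)) / FS
        g = 0.5 + 0.02 * np.sin(2 * np.pi * 1.2 * t) + 0.05 * np.sin(2 * np.pi * 0.2 * t)
        trace = RGBTrace(r=g.copy(), g=g, b=g.copy(), fs=FS)
        result = ceemdan_method(trace, trials=50, seed=1)
        assert _dominant_freq(result.waveform) == pytest.approx(1.2, abs=0.15)

    def test_white_noise_with_strict_threshold_raises(self):
        rng = np.random.default_rng(9)
        g = rng.standard_normal(int(30 * FS))
        trace = RGBTrace(r=g.copy(), g=g, b=g.copy(), fs=FS)
        with pytest.raises(NoPulseFoundError):
            ceemdan_method(trace, trials=30, seed=2, min_inband_fraction=0.99)

    def test_same_seed_same_imf_index(self):
        t = np.arange(int(20 * FS)) / FS
        g = 0.5 + 0.02 * np.sin(2 * np.pi * 1.5 * t)
        trace = RGBTrace(r=g.copy(), g=g, b=g.copy(), fs=FS)
        a = ceemdan_method(trace, trials=30, seed=3)
        b = ceemdan_method(trace, trials=30, seed=3)
        assert a.diagnostics["imf_index"] == b.diagnostics["imf_index"]
        np.testing.assert_array_equal(a.waveform, b.waveform)


class TestChromPos:
    def test_achromatic_flicker_cancels(self):
        t = np.arange(int(30 * FS)) / FS
        flick = 0.5 + 0.05 * np.sin(2 * np.pi * 1.3 * t)
        trace = RGBTrace(r=flick.copy(), g=flick.copy(), b=flick.copy(), fs=FS)
        for method in (chrom_method, pos_method):
            out = method(trace).waveform
            assert np.max(np.abs(out)) <= 1e-6 * 0.05

    def test_chrom_single_window_linearity(self):
        base = _sine_trace(freqs=(1.2, 1.2, 1.2), amps=(0.005, 0.02, 0.01),
                           duration=8.0)
        double = _sine_trace(freqs=(1.2, 1.2, 1.2), amps=(0.01, 0.04, 0.02),
                             duration=8.0)
        w1 = chrom_method(base, window_s=100.0).waveform
        w2 = chrom_method(double, window_s=100.0).waveform
        np.testing.assert_allclose(w2, 2.0 * w1, rtol=0.05, atol=1e-6)

    def test_pos_full_length_window_matches_single_window(self):
        trace = _sine_trace(amps=(0.004, 0.01, 0.006), duration=20.0)
        a = pos_method(trace, window_s=20.0).waveform
        b = pos_method(trace, window_s=1000.0).waveform
        np.testing.assert_allclose(a, b, atol=1e-12)

    @pytest.mark.parametrize("method", ["chrom", "pos"])
    def test_closed_loop_hr_recovery(self, method, stable_cube_30s):
        result = extract_method(stable_cube_30s, method)
        est = estimate_hr_windows(result.waveform, FS)
        truth = stable_cube_30s.ground_truth["hr_trace"].mean()
        assert np.all(np.abs(est - truth) <= 6.0)  # one 10-s spectral bin

    @pytest.mark.parametrize("method", ["chrom", "pos"])
    def test_illumination_rescale_invariance(self, method):
        waves = []
        for i0 in (0.4, 0.8):
            cfg = SimulationConfig(duration=30.0, width=16, height=16, hr=75.0,
                                   noise_sigma=0.0, illumination_I0=i0, seed=6)
            cube = simulate_cube(cfg)  # float mode
            waves.append(extract_method(cube, method).waveform)
        r = np.corrcoef(waves[0], waves[1])[0, 1]
        assert r > 0.999


class TestClosedLoopAllMethods:
    @pytest.mark.parametrize("method", ["green", "ica", "ceemdan", "chrom", "pos"])
    def test_spectral_peak_within_bin_of_configured_hr(self, method, stable_cube_30s):
        result = extract_method(stable_cube_30s, method)
        f0 = _dominant_freq(np.asarray(result.waveform))
        assert abs(f0 - 72.0 / 60.0) <= 1.0 / 30.0 + 1e-9
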