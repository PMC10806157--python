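"""Skin model, illumination, frame composition and quantization."""

import numpy as np
import pytest
from scipy.signal import periodogram

from ippgsim.config import SimulationConfig
from ippgsim.errors import InvalidParameterError, ResampleRequiredError
from ippgsim.extraction import spatial_average
from ippgsim.pipeline import simulate_cube
from ippgsim.ppg import NoiseSpec, PPGSignal
from ippgsim.video import (
    DEFAULT_BETA,
    SKIN_TONE_PRESETS,
    IlluminationProfile,
    compose_frames,
    dequantize,
    pulsatile_color,
    quantize,
    skin_tone_preset,
)


def _flat_ppg(value=0.0, n=50, fs=25.0):
    return PPGSignal(np.full(n, value), fs=fs, duration=n / fs, normalized=True)


def _pulse_ppg(hr=72.0, duration=20.0, fs=25.0):
    from ippgsim.ppg import generate_beat_sequence, normalize_unit, synthesize_ppg

    beats = generate_beat_sequence(hr, 0.3, 0.05, duration)
    return normalize_unit(synthesize_ppg(beats, fs=fs))


class TestPulsatileColor:
    def test_extremes_and_linearity(self):
        np.testing.assert_array_equal(pulsatile_color(0.0), [0.0, 0.0, 0.0])
        np.testing.assert_allclose(pulsatile_color(1.0), DEFAULT_BETA)
        np.testing.assert_allclose(pulsatile_color(0.5), [0.165, 0.385, 0.265])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            pulsatile_color(1.5)
        with pytest.raises(InvalidParameterError):
            pulsatile_color(-0.1)


class TestSkinTonePresets:
    def test_luma_strictly_decreases_with_class(self):
        weights = np.array([0.2126, 0.7152, 0.0722])
        names = ["I", "II", "III", "IV", "V", "VI"]
        lumas = [np.dot(weights, SKIN_TONE_PRESETS[n]) for n in names]
        assert all(a > b for a, b in zip(lumas, lumas[1:]))

    def test_green_ordering_and_beta_unchanged(self):
        assert SKIN_TONE_PRESETS["VI"][1] < SKIN_TONE_PRESETS["II"][1]
        assert skin_tone_preset("V").beta == DEFAULT_BETA

    def test_unknown_preset_rejected(self):
        with pytest.raises(InvalidParameterError):
            skin_tone_preset("VII")


class TestIllumination:
    def test_kinds_evaluate(self):
        t = np.linspace(0, 10, 251)
        assert np.all(IlluminationProfile("constant", 0.8).evaluate(t) == 0.8)
        step = IlluminationProfile("step", 1.0, {"t_step": 5.0, "level": 0.5}).evaluate(t)
        assert step[0] == 1.0 and step[-1] == 0.5
        ramp = IlluminationProfile(
            "ramp", 1.0, {"t_start": 2.0, "t_stop": 8.0, "level": 0.4}
        ).evaluate(t)
        assert ramp[0] == 1.0 and ramp[-1] == pytest.approx(0.4)

    def test_nonpositive_light_rejected(self):
        with pytest.raises(InvalidParameterError):
            IlluminationProfile("step", 1.0, {"t_step": 1.0, "level": -0.1}).evaluate(
                np.linspace(0, 5, 100)
            )
        with pytest.raises(InvalidParameterError):
            IlluminationProfile("constant", 0.0)


class TestComposeFrames:
    def test_static_scene_gives_identical_frames(self):
        cube = compose_frames(
            skin_tone_preset("II"), _flat_ppg(0.0), None,
            IlluminationProfile(), NoiseSpec(0.0, 0), 8, 8, 25.0,
        )
        assert np.all(cube.frames == cube.frames[0])

    def test_green_trace_tracks_pulse(self):
        cfg = SimulationConfig(duration=20.0, width=16, height=16,
                               noise_sigma=0.0, motion_enabled=False, seed=5)
        cube = simulate_cube(cfg)
        trace = spatial_average(cube)
        r = np.corrcoef(trace.g, cube.ground_truth["pulse"])[0, 1]
        assert r > 0.99

    def test_illumination_is_multiplicative(self):
        ppg = _pulse_ppg()
        kw = dict(motion=None, noise=NoiseSpec(0.0, 0), height=8, width=8,
                  fps=25.0, clip=False)
        c1 = compose_frames(skin_tone_preset("III"), ppg,
                            illum=IlluminationProfile("constant", 0.5), **kw)
        c2 = compose_frames(skin_tone_preset("III"), ppg,
                            illum=IlluminationProfile("constant", 1.0), **kw)
        np.testing.assert_allclose(c2.frames, 2.0 * c1.frames, rtol=1e-6)

    def test_fs_mismatch_raises(self):
        with pytest.raises(ResampleRequiredError):
            compose_frames(skin_tone_preset("II"), _flat_ppg(fs=30.0), None,
                           IlluminationProfile(), NoiseSpec(0.0, 0), 8, 8, 25.0)

    def test_unnormalized_ppg_rejected(self):
        sig = PPGSignal(np.linspace(0, 2, 50), fs=25.0, duration=2.0)
        with pytest.raises(InvalidParameterError):
            compose_frames(skin_tone_preset("II"), sig, None,
                           IlluminationProfile(), NoiseSpec(0.0, 0), 8, 8, 25.0)

    def test_noise_snr_monotone_in_sigma(self):
        """Raising camera noise strictly lowers the pulse-band spectral SNR
        of the spatial-mean green trace."""
        snrs = []
        for sigma in (0.002, 0.01, 0.05):
            cfg = SimulationConfig(duration=30.0, width=16, height=16, hr=72.0,
                                   noise_sigma=sigma, motion_enabled=False, seed=8)
            trace = spatial_average(simulate_cube(cfg))
            f, p = periodogram(trace.g - trace.g.mean(), fs=25.0, window="hann")
            peak = p[np.argmin(np.abs(f - 1.2))]
            floor = np.median(p[(f > 2.0) & (f < 10.0)])
            snrs.append(peak / floor)
        assert snrs[0] > snrs[1] > snrs[2]

    def test_ground_truth_round_trip_hr(self):
        cfg = SimulationConfig(duration=30.0, width=8, height=8, hr=70.0, seed=1)
        cube = simulate_cube(cfg)
        beat_times = cube.ground_truth["beat_times"]
        hr_est = 60.0 / np.mean(np.diff(beat_times))
        assert hr_est == pytest.approx(70.0, abs=0.1)


class TestQuantize:
    def _cube(self, value):
        return compose_frames(
            skin_tone_preset("II"), _flat_ppg(value), None,
            IlluminationProfile(), NoiseSpec(0.0, 0), 4, 4, 25.0,
        )

    def test_round_half_up(self):
        cube = self._cube(0.0)
        cube.frames[:] = 0.5
        assert np.all(quantize(cube).frames == 128)

    def test_round_trip_error_bound(self):
        ppg = _pulse_ppg(duration=10.0)
        cube = compose_frames(skin_tone_preset("III"), ppg, None,
                              IlluminationProfile(), NoiseSpec(0.002, 3), 8, 8, 25.0)
        back = dequantize(quantize(cube))
        assert np.max(np.abs(back.frames - cube.frames)) <= 1.0 / 510.0 + 1e-7

    def test_zero_frame_and_range_check(self):
        cube = self._cube(0.0)
        cube.frames[:] = 0.0
        assert np.all(quantize(cube).frames == 0)
        cube.frames[0, 0, 0, 0] = 1.5
        with pytest.raises(InvalidParameterError):
            quantize(cube)

    def test_darker_tone_has_smaller_quantized_pulse_amplitude(self):
        """With the pulse riding on the base reflectance, melanin attenuates
        the recoverable green-channel amplitude after 8-bit quantization."""
        amps = {}
        for tone in ("II", "VI"):
            cfg = SimulationConfig(duration=30.0, width=16, height=16, hr=72.0,
                                   noise_sigma=0.0, motion_enabled=False,
                                   pulse_mode="multiplicative", seed=2,
                                   skin_tone=tone)
            cube = simulate_cube(cfg, quantize_8bit=True)
            g = spatial_average(cube).g
            f, p = periodogram(g - g.mean(), fs=25.0, window="hann")
            band = (f > 1.0) & (f < 1.4)
            amps[tone] = np.sqrt(p[band].max())
        assert amps["VI"] <= amps["II"]
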