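"""Synthetic photoplethysmogram (PPG) waveform generation.

A single PPG beat is described by four key-points — wave onset, systolic
peak, dicrotic notch and diastolic peak — placed at fixed fractions of each
inter-beat interval (IBI) and joined by a shape-preserving cubic
interpolant.  Beat timing carries heart-rate variability as a sinusoidal
modulation of the instantaneous IBI, and additive white Gaussian noise
emulates the camera sensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DegenerateSignalError, InvalidParameterError

__all__ = [
    "BeatSequence",
    "KeypointTemplate",
    "PPGSignal",
    "NoiseSpec",
    "generate_beat_sequence",
    "synthesize_ppg",
    "normalize_unit",
    "add_noise",
]

HR_MIN = 30.0
HR_MAX = 240.0


@dataclass(frozen=True)
class BeatSequence:
    """Heartbeat onset times with their generating rate parameters.

    Attributes
    ----------
    onset_times : np.ndarray
        Strictly increasing beat-onset times in seconds, first onset at 0.
    mean_hr : float
        Mean heart rate in beats/min.
    ibi_mod_freq : float
        Frequency (Hz) of the sinusoidal inter-beat-interval modulation.
    ibi_mod_depth : float
        Modulation depth as a fraction of the mean IBI (0 disables HRV).
    duration : float
        Length of the covered interval [0, duration) in seconds.
    """

    onset_times: np.ndarray
    mean_hr: float
    ibi_mod_freq: float
    ibi_mod_depth: float
    duration: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onset_times, dtype=float)
        object.__setattr__(self, "onset_times", onsets)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise InvalidParameterError("beat onsets must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.onset_times.size)

    @property
    def ibis(self) -> np.ndarray:
        """Inter-beat intervals (s) between consecutive onsets."""
        return np.diff(self.onset_times)

    def instantaneous_hr(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous heart rate (bpm) implied by the IBI modulation law."""
        t = np.asarray(t, dtype=float)
        base_ibi = 60.0 / self.mean_hr
        ibi = base_ibi * (
            1.0 + self.ibi_mod_depth * np.sin(2.0 * np.pi * self.ibi_mod_freq * t)
        )
        return 60.0 / ibi


@dataclass(frozen=True)
class KeypointTemplate:
    """Relative timing and amplitude of the four PPG key-points.

    Times are fractions of the IBI, amplitudes are relative (systolic is the
    maximum, onset the minimum).  The default template places the systolic
    peak a quarter of the way through the beat with the dicrotic notch and
    diastolic peak on the falling limb.
    """

    times: tuple[float, float, float, float] = (0.0, 0.25, 0.45, 0.60)
    amplitudes: tuple[float, float, float, float] = (0.0, 1.0, 0.55, 0.65)

    def __post_init__(self) -> None:
        t_on, t_sys, t_notch, t_dia = self.times
        a_on, a_sys, a_notch, a_dia = self.amplitudes
        if not (0.0 <= t_on < t_sys < t_notch < t_dia < 1.0):
            raise InvalidParameterError(
                "key-point times must satisfy 0 <= onset < systolic < notch < diastolic < 1"
            )
        if a_sys < max(self.amplitudes) or a_sys <= a_notch:
            raise InvalidParameterError("systolic amplitude must be the maximum")
        if a_on > min(self.amplitudes):
            raise InvalidParameterError("onset amplitude must be the minimum")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian camera-noise specification."""

    sigma: float = 0.0
    seed: int = 0
    kind: str = "gaussian-white"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError("noise sigma must be >= 0")
        if self.kind != "gaussian-white":
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")


@dataclass(frozen=True)
class PPGSignal:
    """A sampled pulsatile waveform with its generating beat sequence."""

    samples: np.ndarray
    fs: float
    duration: float
    beat_sequence: BeatSequence | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        expected = int(round(self.duration * self.fs))
        if samples.size != expected:
            raise InvalidParameterError(
                f"sample count {samples.size} != round(duration*fs) = {expected}"
            )

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def generate_beat_sequence(
    mean_hr: float,
    ibi_mod_freq: float = 0.3,
    ibi_mod_depth: float = 0.05,
    duration: float = 10.0,
    seed: int | None = None,
) -> BeatSequence:
    """Generate beat onsets with sinusoidally modulated inter-beat intervals.

    The instantaneous IBI evaluated at each onset time t is
    ``(60/mean_hr) * (1 + ibi_mod_depth * sin(2*pi*ibi_mod_freq*t))``; onsets
    start at t=0 and cover [0, duration).  ``seed`` is accepted for interface
    symmetry with the other generators (the modulation law is deterministic)
    and reserved for future beat-timing jitter.
    """
    if not (HR_MIN <= mean_hr <= HR_MAX):
        raise InvalidParameterError(
            f"mean_hr must lie in [{HR_MIN}, {HR_MAX}] bpm, got {mean_hr}"
        )
    if not (0.0 <= ibi_mod_depth < 0.5):
        raise InvalidParameterError("ibi_mod_depth must lie in [0, 0.5)")
    if ibi_mod_freq < 0:
        raise InvalidParameterError("ibi_mod_freq must be >= 0")
    if duration <= 60.0 / mean_hr:
        raise InvalidParameterError("duration must exceed one beat period")

    base_ibi = 60.0 / mean_hr
    onsets = []
    t = 0.0
    while t < duration:
        onsets.append(t)
        ibi = base_ibi * (
            1.0 + ibi_mod_depth * math.sin(2.0 * math.pi * ibi_mod_freq * t)
        )
        t += ibi
    return BeatSequence(
        onset_times=np.array(onsets),
        mean_hr=mean_hr,
        ibi_mod_freq=ibi_mod_freq,
        ibi_mod_depth=ibi_mod_depth,
        duration=duration,
    )


def _keypoint_knots(beats: BeatSequence, template: KeypointTemplate):
    """Place key-points for each beat, padded with one phantom beat per side.

    The phantom beats keep the interpolant well-behaved at the signal
    boundaries; interior beat shapes are unaffected by them.
    """
    onsets = beats.onset_times
    ibis = beats.ibis
    if ibis.size:
        first_ibi, last_ibi = ibis[0], ibis[-1]
    else:
        first_ibi = last_ibi = 60.0 / beats.mean_hr
    # phantom beat before the first onset and after the last
    padded_onsets = np.concatenate(
        [[onsets[0] - first_ibi], onsets, [onsets[-1] + last_ibi]]
    )
    padded_ibis = np.concatenate([np.diff(padded_onsets), [last_ibi]])
    rel_t = np.asarray(template.times)
    rel_a = np.asarray(template.amplitudes)
    knot_t = (padded_onsets[:, None] + rel_t[None, :] * padded_ibis[:, None]).ravel()
    knot_v = np.tile(rel_a, padded_onsets.size)
    return knot_t, knot_v


def synthesize_ppg(
    beats: BeatSequence,
    template: KeypointTemplate | None = None,
    fs: float = 25.0,
    duration: float | None = None,
) -> PPGSignal:
    """Interpolate per-beat key-points into a sampled PPG waveform.

    A shape-preserving (monotone) piecewise-cubic interpolant joins the
    key-points so no spurious extrema are introduced between them; the
    systolic knot is therefore the unique maximum of each beat.
    """
    if fs <= 0:
        raise InvalidParameterError("fs must be positive")
    if beats is None or beats.n_beats == 0:
        raise DegenerateSignalError("beat sequence is empty")
    template = template or KeypointTemplate()
    if duration is None:
        duration = beats.duration
    n = int(round(duration * fs))
    if n <= 0:
        raise InvalidParameterError("duration too short for the sampling rate")
    knot_t, knot_v = _keypoint_knots(beats, template)
    interp = PchipInterpolator(knot_t, knot_v, extrapolate=True)
    t = np.arange(n) / fs
    samples = interp(t)
    return PPGSignal(samples=samples, fs=fs, duration=duration, beat_sequence=beats)


def normalize_unit(signal: PPGSignal) -> PPGSignal:
    """Affinely rescale a waveform into [0, 1] (min -> 0, max -> 1)."""
    x = signal.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise DegenerateSignalError("cannot normalize a constant signal")
    scaled = (x - lo) / (hi - lo)
    return replace(signal, samples=scaled, normalized=True)


def add_noise(signal: PPGSignal, noise: NoiseSpec) -> PPGSignal:
    """Add i.i.d. zero-mean Gaussian camera noise; reproducible under seed."""
    if noise.sigma == 0:
        return signal
    rng = np.random.default_rng(noise.seed)
    noisy = signal.samples + rng.normal(0.0, noise.sigma, signal.samples.size)
    return replace(signal, samples=noisy, normalized=False)
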