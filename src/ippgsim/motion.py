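"""Involuntary body-motion traces and their pixel-intensity projection.

Two motion sources are modelled: ballistocardiographic (BCG) neck rotation
locked to the heart rate, and breathing-driven displacement of head,
shoulders (vertical) and chest (horizontal).  For a patch-level simulator
these geometric motions are projected to a single zero-mean per-frame
intensity modulation m(t) via configurable linear gains — m(t) plays the
role of the specular-reflection artifact term and is therefore achromatic
(added equally to all color channels downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .errors import AliasingError, InvalidParameterError, ShapeError

__all__ = [
    "MotionTrace",
    "MotionGains",
    "BREATH_BAND",
    "bcg_trace",
    "breathing_trace",
    "project_to_intensity",
    "make_motion_trace",
]

#: physiological breathing-frequency band (Hz), 8-24 breaths/min
BREATH_BAND = (0.13, 0.4)

#: default neck-rotation amplitude statistics (degrees)
THETA_MEAN_DEG = 0.12
THETA_SD_DEG = 0.03

#: default breathing displacement amplitudes (normalized scene units)
DEFAULT_BREATH_AMPLITUDES = (0.02, 0.015, 0.01)  # head_dy, shoulder_dy, chest_dx


@dataclass(frozen=True)
class MotionGains:
    """Linear gains mapping each motion trace to pixel-intensity units.

    The BCG gain default makes the intensity artifact's standard deviation
    roughly 20% of the green-channel pulsatile amplitude under the default
    pulse scale, so motion is a visible but not overwhelming artifact.
    """

    bcg: float = 0.0045  # intensity units per degree
    head_dy: float = 0.01
    shoulder_dy: float = 0.01
    chest_dx: float = 0.01


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame motion state and its combined intensity projection."""

    t: np.ndarray
    bcg_angle: np.ndarray
    breath_head_dy: np.ndarray
    breath_shoulder_dy: np.ndarray
    breath_chest_dx: np.ndarray
    intensity_modulation: np.ndarray

    def __post_init__(self) -> None:
        n = self.t.size
        for name in (
            "bcg_angle",
            "breath_head_dy",
            "breath_shoulder_dy",
            "breath_chest_dx",
            "intensity_modulation",
        ):
            if getattr(self, name).size != n:
                raise ShapeError(f"{name} length != frame count {n}")


def bcg_trace(
    hr: float,
    duration: float,
    fps: float,
    theta_mean: float = THETA_MEAN_DEG,
    theta_sd: float = THETA_SD_DEG,
    seed: int | None = None,
) -> np.ndarray:
    """Heart-rate-locked neck-rotation angle trace (degrees).

    Each cardiac cycle is one sinusoid period whose amplitude is re-drawn
    from Normal(theta_mean, theta_sd) truncated at zero, so the fundamental
    frequency is exactly hr/60 Hz while the amplitude fluctuates beat to
    beat.
    """
    if theta_mean <= 0:
        raise InvalidParameterError("theta_mean must be positive")
    if theta_sd < 0:
        raise InvalidParameterError("theta_sd must be >= 0")
    f0 = hr / 60.0
    if fps <= 2.0 * f0:
        raise AliasingError(
            f"fps {fps} cannot represent a {f0:.2f} Hz oscillation (need fps > {2*f0:.2f})"
        )
    period = 1.0 / f0
    if duration < period:
        raise InvalidParameterError("duration shorter than one cardiac period")
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    cycle = np.floor(t * f0).astype(int)
    n_cycles = int(cycle.max()) + 1
    rng = np.random.default_rng(seed)
    if theta_sd == 0:
        amps = np.full(n_cycles, theta_mean)
    else:
        a = (0.0 - theta_mean) / theta_sd
        amps = truncnorm.rvs(
            a, np.inf, loc=theta_mean, scale=theta_sd, size=n_cycles, random_state=rng
        )
    return amps[cycle] * np.sin(2.0 * np.pi * f0 * t)


def breathing_trace(
    breath_freq: float,
    duration: float,
    fps: float,
    amplitudes: tuple[float, float, float] = DEFAULT_BREATH_AMPLITUDES,
    allow_out_of_band: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Breathing displacements: head dy, shoulder dy (up/down), chest dx.

    All three are phase-aligned sinusoids at ``breath_freq`` (inhale moves
    head/shoulders up and chest forward together).  The frequency must lie
    in the physiological 0.13-0.4 Hz band unless explicitly overridden.
    """
    lo, hi = BREATH_BAND
    if not allow_out_of_band and not (lo <= breath_freq <= hi):
        raise InvalidParameterError(
            f"breath_freq {breath_freq} Hz outside the physiological band "
            f"[{lo}, {hi}] Hz (pass allow_out_of_band=True to override)"
        )
    if duration <= 0 or fps <= 0:
        raise InvalidParameterError("duration and fps must be positive")
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    carrier = np.sin(2.0 * np.pi * breath_freq * t)
    a_head, a_shoulder, a_chest = amplitudes
    return a_head * carrier, a_shoulder * carrier, a_chest * carrier


def project_to_intensity(
    bcg: np.ndarray,
    breathing: tuple[np.ndarray, np.ndarray, np.ndarray],
    gains: MotionGains = MotionGains(),
) -> np.ndarray:
    """Linear, zero-mean projection of motion traces to intensity units.

    m(t) = sum_k gain_k * (trace_k - mean(trace_k)); the DC level of the
    scene is carried by the illumination term, so m is pure fluctuation.
    """
    head, shoulder, chest = breathing
    traces = (bcg, head, shoulder, chest)
    gvals = (gains.bcg, gains.head_dy, gains.shoulder_dy, gains.chest_dx)
    n = np.asarray(bcg).size
    for tr in traces:
        if np.asarray(tr).size != n:
            raise ShapeError("motion traces must share a common length")
    m = np.zeros(n)
    for g, tr in zip(gvals, traces):
        tr = np.asarray(tr, dtype=float)
        m += g * (tr - tr.mean())
    return m


def make_motion_trace(
    hr: float,
    breath_freq: float,
    duration: float,
    fps: float,
    gains: MotionGains = MotionGains(),
    amplitudes: tuple[float, float, float] = DEFAULT_BREATH_AMPLITUDES,
    theta_mean: float = THETA_MEAN_DEG,
    theta_sd: float = THETA_SD_DEG,
    seed: int | None = None,
) -> MotionTrace:
    """Convenience constructor combining BCG + breathing into a MotionTrace."""
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    bcg = bcg_trace(hr, duration, fps, theta_mean, theta_sd, seed=seed)
    breath = breathing_trace(breath_freq, duration, fps, amplitudes)
    m = project_to_intensity(bcg, breath, gains)
    return MotionTrace(
        t=t,
        bcg_angle=bcg,
        breath_head_dy=breath[0],
        breath_shoulder_dy=breath[1],
        breath_chest_dx=breath[2],
        intensity_modulation=m,
    )
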