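"""Skin-patch video composition.

Each rendered pixel follows a multiplicative illumination model on top of a
three-layer skin description: a static base-color layer (melanin / skin
tone), a pulsatile subsurface layer carrying the cardiac color signal
c(t) = beta ⊙ P(t), and a static multiplicative surface-texture layer.  A
scalar achromatic motion term m(t) models specular-reflection artifacts and
per-pixel Gaussian noise models the camera sensor:

    frame(t) = clip( I(t) * ( base_rgb * texture(x, y) + s*c(t) + m(t) ) + N )

with pulse scale s (≈1% green-channel modulation by default).  A
multiplicative pulse mode, where the subsurface modulation rides on the
base reflectance (darker skin → smaller absolute pulse amplitude), is
available as a configuration switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import (
    InvalidParameterError,
    ResampleRequiredError,
    ShapeError,
)
from .motion import MotionTrace
from .ppg import NoiseSpec, PPGSignal

__all__ = [
    "SkinModel",
    "IlluminationProfile",
    "VideoCube",
    "DEFAULT_BETA",
    "SKIN_TONE_PRESETS",
    "skin_tone_preset",
    "pulsatile_color",
    "texture_field",
    "compose_frames",
    "quantize",
    "dequantize",
]

#: per-channel weights of the cardiac signal in R, G, B
DEFAULT_BETA = (0.33, 0.77, 0.53)

#: base-layer diffuse reflectance per skin-tone class, light (I) to dark (VI);
#: luma strictly decreases with class
SKIN_TONE_PRESETS: dict[str, tuple[float, float, float]] = {
    "I": (0.914, 0.784, 0.690),
    "II": (0.866, 0.718, 0.608),
    "III": (0.796, 0.635, 0.518),
    "IV": (0.643, 0.475, 0.369),
    "V": (0.486, 0.341, 0.251),
    "VI": (0.333, 0.224, 0.157),
}


@dataclass(frozen=True)
class SkinModel:
    """Base color, cardiac channel weights and surface texture parameters."""

    base_rgb: tuple[float, float, float]
    beta: tuple[float, float, float] = DEFAULT_BETA
    texture_seed: int = 0
    texture_contrast: float = 0.05

    def __post_init__(self) -> None:
        if not all(0.0 <= v <= 1.0 for v in self.base_rgb):
            raise InvalidParameterError("base_rgb components must lie in [0, 1]")
        if not all(0.0 <= v <= 1.0 for v in self.beta):
            raise InvalidParameterError("beta components must lie in [0, 1]")
        if self.texture_contrast < 0:
            raise InvalidParameterError("texture_contrast must be >= 0")


@dataclass(frozen=True)
class IlluminationProfile:
    """Time course of the (strictly positive) relative illumination I(t)."""

    kind: str = "constant"
    I0: float = 1.0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.I0 <= 0:
            raise InvalidParameterError("I0 must be positive")
        if self.kind not in ("constant", "step", "ramp", "sinusoid"):
            raise InvalidParameterError(f"unknown illumination kind {self.kind!r}")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.full(t.shape, self.I0)
        elif self.kind == "step":
            t_step = self.params.get("t_step", 0.0)
            level = self.params.get("level", self.I0)
            out = np.where(t < t_step, self.I0, level)
        elif self.kind == "ramp":
            t0 = self.params.get("t_start", 0.0)
            t1 = self.params.get("t_stop", t0 + 1.0)
            level = self.params.get("level", self.I0)
            frac = np.clip((t - t0) / max(t1 - t0, 1e-12), 0.0, 1.0)
            out = self.I0 + (level - self.I0) * frac
        else:  # sinusoid
            freq = self.params.get("freq", 0.1)
            amp = self.params.get("amp", 0.1)
            out = self.I0 * (1.0 + amp * np.sin(2.0 * np.pi * freq * t))
        if np.any(out <= 0):
            raise InvalidParameterError("illumination must stay strictly positive")
        return out


@dataclass
class VideoCube:
    """A T x H x W x 3 frame stack with attached ground truth."""

    frames: np.ndarray
    fps: float
    bit_depth: str = "float32"  # or "uint8"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ShapeError("frames must have shape (T, H, W, 3)")
        if self.bit_depth not in ("float32", "uint8"):
            raise InvalidParameterError("bit_depth must be 'float32' or 'uint8'")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


def skin_tone_preset(name: str, **overrides) -> SkinModel:
    """Return the SkinModel for one of the six skin-tone classes I..VI."""
    try:
        base = SKIN_TONE_PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown skin-tone preset {name!r}; choose from {list(SKIN_TONE_PRESETS)}"
        ) from None
    return SkinModel(base_rgb=base, **overrides)


def pulsatile_color(
    P_value: float | np.ndarray, beta: tuple[float, float, float] = DEFAULT_BETA
) -> np.ndarray:
    """Cardiac color contribution c = beta ⊙ P for normalized pulse P∈[0,1]."""
    P = np.asarray(P_value, dtype=float)
    if np.any(P < 0) or np.any(P > 1):
        raise InvalidParameterError("normalized pulse values must lie in [0, 1]")
    return P[..., None] * np.asarray(beta, dtype=float)


def texture_field(
    height: int, width: int, seed: int = 0, contrast: float = 0.05, smooth_px: float = 3.0
) -> np.ndarray:
    """Static multiplicative surface-texture layer, mean 1.

    Seeded white noise smoothed to ``smooth_px`` pixels and rescaled to the
    requested contrast (relative standard deviation), floored well above
    zero so reflectance stays physical.
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(height, width))
    smooth = gaussian_filter(raw, sigma=smooth_px, mode="reflect")
    sd = smooth.std()
    z = smooth / sd if sd > 0 else np.zeros_like(smooth)
    return np.clip(1.0 + contrast * z, 0.1, None)


def compose_frames(
    skin: SkinModel,
    ppg: PPGSignal,
    motion: MotionTrace | None,
    illum: IlluminationProfile | np.ndarray,
    noise: NoiseSpec,
    height: int = 64,
    width: int = 64,
    fps: float = 25.0,
    pulse_scale: float = 0.01,
    pulse_mode: str = "additive",
    clip: bool = True,
    ground_truth: dict | None = None,
) -> VideoCube:
    """Render a skin-patch video cube from its physiological components.

    The normalized pulse, motion modulation and illumination are combined
    per frame; the spatial texture is static; sensor noise is i.i.d. per
    pixel and frame and added after the illumination scaling.
    """
    if height < 1 or width < 1:
        raise InvalidParameterError("height and width must be >= 1")
    if not ppg.normalized:
        raise InvalidParameterError("ppg must be normalized to [0, 1] first")
    if abs(ppg.fs - fps) > 1e-9:
        raise ResampleRequiredError(
            f"ppg sampled at {ppg.fs} Hz but video runs at {fps} fps; resample upstream"
        )
    if pulse_mode not in ("additive", "multiplicative"):
        raise InvalidParameterError("pulse_mode must be 'additive' or 'multiplicative'")

    n = ppg.samples.size
    t = np.arange(n) / fps
    c = pulse_scale * pulsatile_color(np.clip(ppg.samples, 0.0, 1.0), skin.beta)  # (T,3)

    if motion is None:
        m = np.zeros(n)
    else:
        m = np.asarray(motion.intensity_modulation, dtype=float)
        if m.size != n:
            raise ShapeError("motion trace length != frame count")

    if isinstance(illum, IlluminationProfile):
        I = illum.evaluate(t)
    else:
        I = np.asarray(illum, dtype=float)
        if I.size != n:
            raise ShapeError("illumination array length != frame count")
        if np.any(I <= 0):
            raise InvalidParameterError("illumination must stay strictly positive")

    tex = texture_field(height, width, skin.texture_seed, skin.texture_contrast)
    base = np.asarray(skin.base_rgb, dtype=float)[None, None, :] * tex[:, :, None]

    frames = np.empty((n, height, width, 3), dtype=np.float32)
    rng = np.random.default_rng(noise.seed)
    # frame-by-frame keeps peak memory low and the noise stream frame-ordered
    for k in range(n):
        if pulse_mode == "additive":
            sig = base + c[k][None, None, :] + m[k]
        else:
            sig = base * (1.0 + c[k][None, None, :] + m[k])
        frame = I[k] * sig
        if noise.sigma > 0:
            frame = frame + rng.normal(0.0, noise.sigma, frame.shape)
        frames[k] = frame
    if clip:
        np.clip(frames, 0.0, 1.0, out=frames)

    gt = dict(ground_truth or {})
    gt.setdefault("m", m)
    gt.setdefault("I", I)
    if ppg.beat_sequence is not None:
        gt.setdefault("beat_times", ppg.beat_sequence.onset_times)
        gt.setdefault("mean_hr", ppg.beat_sequence.mean_hr)
        gt.setdefault("hr_trace", ppg.beat_sequence.instantaneous_hr(t))
    gt.setdefault("pulse", ppg.samples)
    return VideoCube(frames=frames, fps=fps, bit_depth="float32", ground_truth=gt)


def quantize(video: VideoCube) -> VideoCube:
    """Quantize a float cube to 8-bit with round-half-up convention."""
    if video.bit_depth != "float32":
        raise InvalidParameterError("quantize expects a float video cube")
    f = video.frames
    if f.min() < 0.0 or f.max() > 1.0 + 1e-6:
        raise InvalidParameterError("float frames must be clipped to [0, 1] before quantization")
    q = np.floor(255.0 * f + 0.5).astype(np.uint8)
    return VideoCube(frames=q, fps=video.fps, bit_depth="uint8",
                     ground_truth=video.ground_truth)


def dequantize(video: VideoCube) -> VideoCube:
    """Map uint8 frames back to floats in [0, 1] (max abs error 1/510)."""
    if video.bit_depth != "uint8":
        raise InvalidParameterError("dequantize expects a uint8 video cube")
    f = (video.frames.astype(np.float32)) / 255.0
    return VideoCube(frames=f, fps=video.fps, bit_depth="float32",
                     ground_truth=video.ground_truth)
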