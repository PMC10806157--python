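"""Classical iPPG pulse-recovery methods: GREEN, ICA (JADE), CEEMDAN,
CHROM and POS.

All methods consume spatially averaged RGB channel traces.  GREEN band-
passes the green channel; ICA separates the z-scored channels with JADE
and takes the second component by convention; CEEMDAN decomposes the green
trace and selects the intrinsic mode whose spectrum peaks in the cardiac
band; CHROM projects normalized channels onto chrominance axes and POS
onto the plane orthogonal to the skin-tone axis, both with short
overlapping windows recombined by Hann overlap-add so slow illumination
changes cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, detrend, get_window, periodogram, sosfiltfilt

from .emd import ceemdan
from .errors import (
    DegenerateSignalError,
    InvalidParameterError,
    NoPulseFoundError,
    ShapeError,
)
from .jade import jade
from .video import VideoCube, dequantize

__all__ = [
    "RGBTrace",
    "IPPGResult",
    "DEFAULT_BAND",
    "spatial_average",
    "bandpass_filter",
    "green_method",
    "ica_method",
    "ceemdan_method",
    "chrom_method",
    "pos_method",
    "METHODS",
]

#: default cardiac pass-band in Hz (42-240 beats/min)
DEFAULT_BAND = (0.7, 4.0)

#: default CHROM/POS analysis window length in seconds
DEFAULT_WINDOW_S = 1.6


@dataclass(frozen=True)
class RGBTrace:
    """Spatial-mean RGB channel traces from a region of interest."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    fs: float
    roi_pixel_count: int = 1

    def __post_init__(self) -> None:
        if not (self.r.size == self.g.size == self.b.size):
            raise ShapeError("channel traces must have equal length")
        if self.roi_pixel_count < 1:
            raise InvalidParameterError("roi_pixel_count must be >= 1")

    @property
    def n(self) -> int:
        return int(self.g.size)

    def as_matrix(self) -> np.ndarray:
        return np.vstack([self.r, self.g, self.b])


@dataclass(frozen=True)
class IPPGResult:
    """Recovered pulse waveform plus method diagnostics."""

    waveform: np.ndarray
    fs: float
    method_id: str
    diagnostics: dict = field(default_factory=dict)


def spatial_average(video: VideoCube, roi_mask: np.ndarray | None = None) -> RGBTrace:
    """Per-frame, per-channel mean over the region of interest.

    ``roi_mask`` is a boolean H x W array; ``None`` selects the full frame.
    """
    cube = dequantize(video) if video.bit_depth == "uint8" else video
    frames = cube.frames
    _, h, w, _ = frames.shape
    if roi_mask is None:
        roi_mask = np.ones((h, w), dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != (h, w):
        raise ShapeError("roi_mask shape must match the frame geometry")
    npix = int(roi_mask.sum())
    if npix == 0:
        raise InvalidParameterError("roi_mask selects no pixels")
    means = frames[:, roi_mask, :].mean(axis=1)  # (T, 3)
    return RGBTrace(
        r=means[:, 0].astype(float),
        g=means[:, 1].astype(float),
        b=means[:, 2].astype(float),
        fs=cube.fps,
        roi_pixel_count=npix,
    )


def bandpass_filter(
    x: np.ndarray, fs: float, band: tuple[float, float] = DEFAULT_BAND, order: int = 3
) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise InvalidParameterError(
            f"band {band} must lie strictly inside (0, Nyquist={fs/2}) Hz"
        )
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def _dominant_frequency(x: np.ndarray, fs: float) -> float:
    f, p = periodogram(x - np.mean(x), fs=fs, window="hann")
    return float(f[np.argmax(p)])


def _inband_fraction(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    f, p = periodogram(x - np.mean(x), fs=fs, window="hann")
    total = float(np.sum(p))
    if total <= 0:
        return 0.0
    mask = (f >= band[0]) & (f <= band[1])
    return float(np.sum(p[mask])) / total


def green_method(
    trace: RGBTrace, band: tuple[float, float] = DEFAULT_BAND
) -> IPPGResult:
    """Detrended, band-passed spatial-mean green channel."""
    g = detrend(np.asarray(trace.g, dtype=float))
    out = bandpass_filter(g, trace.fs, band)
    return IPPGResult(waveform=out, fs=trace.fs, method_id="green",
                      diagnostics={"band": band})


def ica_method(
    trace: RGBTrace,
    band: tuple[float, float] = DEFAULT_BAND,
    component: int = 1,
) -> IPPGResult:
    """JADE blind source separation of the z-scored RGB channels.

    By convention the second recovered component (index 1) is taken as the
    cardiac signal; diagnostics also record which component actually has
    the most in-band energy.  Rank-deficient inputs fall back to selecting
    the component with the highest in-band energy.
    """
    if trace.n < 10 * trace.fs:
        raise InvalidParameterError("ICA needs at least 10 s of samples")
    X = trace.as_matrix()
    stds = X.std(axis=1)
    if np.all(stds < 1e-12):
        raise DegenerateSignalError("constant input; nothing to separate")
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(stds > 1e-12, stds, 1.0)[:, None]
    sources, B = jade(Z)
    fallback = sources.shape[0] < 3
    if fallback:
        warnings.warn(
            "rank-deficient RGB trace: falling back to spectral component selection",
            RuntimeWarning,
            stacklevel=2,
        )
    inband = [_inband_fraction(s, trace.fs, band) for s in sources]
    best = int(np.argmax(inband))
    chosen = best if fallback else min(component, sources.shape[0] - 1)
    out = bandpass_filter(sources[chosen], trace.fs, band)
    # fix sign against the band-passed green trace
    ref = bandpass_filter(detrend(np.asarray(trace.g, dtype=float)), trace.fs, band)
    corr = float(np.dot(out, ref))
    if corr < 0:
        out = -out
    return IPPGResult(
        waveform=out,
        fs=trace.fs,
        method_id="ica",
        diagnostics={
            "selected_index": chosen,
            "best_inband_index": best,
            "inband_fractions": inband,
            "fallback": fallback,
            "n_components": sources.shape[0],
        },
    )


def ceemdan_method(
    trace: RGBTrace,
    band: tuple[float, float] = DEFAULT_BAND,
    trials: int = 100,
    noise_scale: float = 0.2,
    seed: int = 0,
    min_inband_fraction: float = 0.0,
) -> IPPGResult:
    """CEEMDAN decomposition of the green trace; selects the cardiac IMF.

    Candidate IMFs must have their dominant frequency inside the cardiac
    band; among candidates the one with the highest in-band energy wins.
    ``min_inband_fraction`` optionally enforces a minimum in-band energy
    fraction for the winner (strict selection).
    """
    if trace.n < 10 * trace.fs:
        raise InvalidParameterError("CEEMDAN needs at least 10 s of samples")
    g = detrend(np.asarray(trace.g, dtype=float))
    modes = ceemdan(g, trials=trials, noise_scale=noise_scale, seed=seed)
    imfs = modes[:-1]  # drop the residue
    candidates = []
    for i, imf in enumerate(imfs):
        dom = _dominant_frequency(imf, trace.fs)
        if band[0] <= dom <= band[1]:
            candidates.append((i, _inband_fraction(imf, trace.fs, band)))
    if not candidates:
        raise NoPulseFoundError("no IMF has its dominant frequency in the cardiac band")
    idx, frac = max(candidates, key=lambda c: c[1])
    if frac < min_inband_fraction:
        raise NoPulseFoundError(
            f"best IMF in-band energy fraction {frac:.3f} below "
            f"threshold {min_inband_fraction}"
        )
    return IPPGResult(
        waveform=imfs[idx],
        fs=trace.fs,
        method_id="ceemdan",
        diagnostics={"imf_index": idx, "n_imfs": len(imfs), "inband_fraction": frac},
    )


def _overlap_windows(n: int, win: int):
    """Start indices for 50%-overlapping windows covering [0, n)."""
    hop = max(1, win // 2)
    starts = list(range(0, max(n - win, 0) + 1, hop))
    if not starts:
        starts = [0]
    # make sure the tail is covered
    if starts[-1] + win < n:
        starts.append(n - win)
    return starts, hop


def _overlap_add(n: int, win: int, segments) -> tuple[np.ndarray, int]:
    """Hann overlap-add of per-window segments produced by ``segments``.

    ``segments`` yields (start, values) pairs with len(values) == win.
    """
    out = np.zeros(n)
    weight = np.zeros(n)
    taper = get_window("hann", win)
    count = 0
    for start, vals in segments:
        out[start : start + win] += vals * taper
        weight[start : start + win] += taper
        count += 1
    nz = weight > 1e-8
    out[nz] /= weight[nz]
    return out, count


def chrom_method(
    trace: RGBTrace,
    band: tuple[float, float] = DEFAULT_BAND,
    window_s: float = DEFAULT_WINDOW_S,
) -> IPPGResult:
    """Chrominance-based pulse extraction.

    Per overlapping window the channels are normalized by their window
    means, projected onto X = 3Rn - 2Gn and Y = 1.5Rn + Gn - 1.5Bn, band-
    passed, and combined as S = X_f - alpha * Y_f with
    alpha = sigma(X_f)/sigma(Y_f); windows recombine by Hann overlap-add.
    """
    n = trace.n
    win = int(round(window_s * trace.fs))
    single = win >= n or win < 8
    if single:
        win = n

    def project(start: int) -> tuple[np.ndarray, np.ndarray]:
        sl = slice(start, start + win)
        r, g, b = trace.r[sl], trace.g[sl], trace.b[sl]
        rm, gm, bm = r.mean(), g.mean(), b.mean()
        if min(rm, gm, bm) <= 0:
            raise DegenerateSignalError("non-positive channel mean in window")
        rn, gn, bn = r / rm - 1.0, g / gm - 1.0, b / bm - 1.0
        return 3.0 * rn - 2.0 * gn, 1.5 * rn + gn - 1.5 * bn

    if single:
        x, y = project(0)
        starts = [0]
        count = 1
    else:
        starts, _ = _overlap_windows(n, win)
        x, count = _overlap_add(n, win, ((s, project(s)[0]) for s in starts))
        y, _ = _overlap_add(n, win, ((s, project(s)[1]) for s in starts))
    # filter the stitched chrominance signals at full length so low cardiac
    # fundamentals keep their spectral resolution
    xf = bandpass_filter(x, trace.fs, band)
    yf = bandpass_filter(y, trace.fs, band)

    def tune(start: int) -> np.ndarray:
        sl = slice(start, start + win)
        sy = yf[sl].std()
        alpha = xf[sl].std() / sy if sy > 1e-12 else 0.0
        return xf[sl] - alpha * yf[sl]

    if single:
        out = tune(0)
    else:
        out, _ = _overlap_add(n, win, ((s, tune(s)) for s in starts))
    return IPPGResult(waveform=out, fs=trace.fs, method_id="chrom",
                      diagnostics={"window_count": count, "window_s": window_s})


def pos_method(
    trace: RGBTrace,
    band: tuple[float, float] = DEFAULT_BAND,
    window_s: float = DEFAULT_WINDOW_S,
) -> IPPGResult:
    """Plane-orthogonal-to-skin pulse extraction.

    Per overlapping window the channels are temporally normalized by their
    window means and projected onto the plane axes (0, 1, -1) and
    (-2, 1, 1); the tuned combination S = S1 + (sigma1/sigma2) * S2 is
    mean-removed and recombined by Hann overlap-add, then band-passed.
    """
    n = trace.n
    win = int(round(window_s * trace.fs))
    single = win >= n or win < 4
    if single:
        win = n

    def seg(start: int) -> np.ndarray:
        sl = slice(start, start + win)
        r, g, b = trace.r[sl], trace.g[sl], trace.b[sl]
        rm, gm, bm = r.mean(), g.mean(), b.mean()
        if min(rm, gm, bm) <= 0:
            raise DegenerateSignalError("non-positive channel mean in window")
        rn, gn, bn = r / rm, g / gm, b / bm
        s1 = gn - bn
        s2 = -2.0 * rn + gn + bn
        sd2 = s2.std()
        h = s1 + (s1.std() / sd2) * s2 if sd2 > 1e-12 else s1
        return h - h.mean()

    if single:
        out = seg(0)
        count = 1
    else:
        starts, _ = _overlap_windows(n, win)
        out, count = _overlap_add(n, win, ((s, seg(s)) for s in starts))
    out = bandpass_filter(out, trace.fs, band)
    return IPPGResult(waveform=out, fs=trace.fs, method_id="pos",
                      diagnostics={"window_count": count, "window_s": window_s})


#: method registry used by the pipeline and CLI
METHODS = {
    "green": green_method,
    "ica": ica_method,
    "ceemdan": ceemdan_method,
    "chrom": chrom_method,
    "pos": pos_method,
}
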