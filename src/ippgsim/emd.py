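"""Empirical mode decomposition (EMD) and its complete-ensemble variant
with adaptive noise (CEEMDAN).

EMD sifts a signal into intrinsic mode functions (IMFs) by repeatedly
subtracting the mean of the cubic-spline envelopes through local maxima and
minima.  CEEMDAN stabilises the decomposition by averaging, at every stage,
the first IMF of the current residue perturbed with the matching EMD mode
of an ensemble of white-noise realisations, which removes mode mixing while
keeping the decomposition complete (the IMFs plus the final residue sum to
the input).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema

from .errors import DegenerateSignalError

__all__ = ["emd", "ceemdan"]

_SD_THRESH = 0.2  # Cauchy-like sifting stop criterion
_MAX_SIFTS = 12


def _local_extrema(x: np.ndarray):
    """Indices of strict local maxima and minima (plateaus collapse)."""
    mx = argrelextrema(x, np.greater_equal, order=1)[0]
    mn = argrelextrema(x, np.less_equal, order=1)[0]
    # drop plateau duplicates and endpoints
    mx = mx[(mx > 0) & (mx < x.size - 1)]
    mn = mn[(mn > 0) & (mn < x.size - 1)]
    if mx.size > 1:
        mx = mx[np.concatenate([[True], np.diff(mx) > 1])]
    if mn.size > 1:
        mn = mn[np.concatenate([[True], np.diff(mn) > 1])]
    return mx, mn


def _mirrored_spline(idx: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    """Cubic spline through extrema, mirror-extended past both boundaries."""
    # mirror up to two extrema about each end to tame boundary swings
    k = min(2, idx.size)
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    ti = np.concatenate([left_i, idx, right_i])
    tv = np.concatenate([left_v, val, right_v])
    ti, unique = np.unique(ti, return_index=True)
    tv = tv[unique]
    if ti.size < 2:
        return np.full(n, tv[0] if tv.size else 0.0)
    spline = CubicSpline(ti, tv)
    return spline(np.arange(n))


def _envelope_mean(x: np.ndarray):
    """Mean of upper/lower envelopes; None when too few extrema remain."""
    mx, mn = _local_extrema(x)
    if mx.size + mn.size < 3 or mx.size < 2 or mn.size < 2:
        return None
    upper = _mirrored_spline(mx, x[mx], x.size)
    lower = _mirrored_spline(mn, x[mn], x.size)
    return 0.5 * (upper + lower)


def _sift_imf(x: np.ndarray) -> np.ndarray | None:
    """Extract one IMF by sifting, or None if x is already a residue."""
    h = x
    for _ in range(_MAX_SIFTS):
        env = _envelope_mean(h)
        if env is None:
            return None if h is x else h
        h_new = h - env
        denom = float(np.sum(h * h))
        if denom > 0:
            sd = float(np.sum((h - h_new) ** 2)) / denom
        else:
            sd = 0.0
        h = h_new
        if sd < _SD_THRESH:
            break
    return h


def emd(x: np.ndarray, max_imfs: int = 12) -> list[np.ndarray]:
    """Decompose ``x`` into IMFs plus a final residue (last element).

    The returned arrays sum to the input to floating-point accuracy.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise DegenerateSignalError("EMD needs a 1-D signal of at least 8 samples")
    imfs: list[np.ndarray] = []
    residue = x.copy()
    for _ in range(max_imfs):
        imf = _sift_imf(residue)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
    imfs.append(residue)
    return imfs


def ceemdan(
    x: np.ndarray,
    trials: int = 100,
    noise_scale: float = 0.2,
    seed: int | None = None,
    max_imfs: int = 10,
) -> list[np.ndarray]:
    """Complete ensemble EMD with adaptive noise (IMFs + final residue).

    ``noise_scale`` is the noise standard deviation relative to the
    standard deviation of the input.  The same ``seed`` always yields the
    same decomposition.
    """
    x = np.asarray(x, dtype=float)
    sd = float(x.std())
    if sd <= 0:
        raise DegenerateSignalError("cannot decompose a constant signal")
    x0 = x / sd
    rng = np.random.default_rng(seed)
    noises = [rng.standard_normal(x.size) for _ in range(trials)]
    # precompute the EMD modes of each noise realisation once
    noise_modes = [emd(w, max_imfs=max_imfs) for w in noises]

    imfs: list[np.ndarray] = []
    # stage 1: IMF of the noise-perturbed input
    acc = np.zeros(x.size)
    for w in noises:
        imf = _sift_imf(x0 + noise_scale * w)
        acc += imf if imf is not None else (x0 + noise_scale * w)
    imfs.append(acc / trials)
    residue = x0 - imfs[-1]

    for k in range(1, max_imfs):
        env = _envelope_mean(residue)
        if env is None:  # residue is monotone-ish: stop
            break
        eps_k = noise_scale * float(residue.std())
        acc = np.zeros(x.size)
        used = 0
        for modes in noise_modes:
            if k < len(modes) - 1:  # k-th IMF of this noise realisation
                perturbed = residue + eps_k * modes[k]
            else:
                perturbed = residue
            imf = _sift_imf(perturbed)
            if imf is not None:
                acc += imf
                used += 1
        if used == 0:
            break
        imfs.append(acc / used)
        residue = residue - imfs[-1]
    imfs.append(residue)
    return [imf * sd for imf in imfs]
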