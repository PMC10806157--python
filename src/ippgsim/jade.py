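"""Joint Approximate Diagonalization of Eigenmatrices (JADE) for blind
source separation.

JADE whitens the observations, estimates the parallel set of fourth-order
cumulant matrices and joint-diagonalizes them with Jacobi rotations; the
resulting unmixing matrix separates statistically independent sources up to
permutation and scale.  Intended for the small channel counts of RGB pulse
extraction (the cumulant set grows as m^4).
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateSignalError

__all__ = ["jade"]


def _whiten(X: np.ndarray, rank_tol: float = 1e-10):
    m, T = X.shape
    X = X - X.mean(axis=1, keepdims=True)
    cov = (X @ X.T) / T
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[0] <= 0:
        raise DegenerateSignalError("input has no variance; cannot whiten")
    keep = eigval > rank_tol * eigval[0]
    r = int(keep.sum())
    W = (eigvec[:, :r] / np.sqrt(eigval[:r])).T  # (r, m)
    return W @ X, W, r


def _cumulant_matrices(Z: np.ndarray) -> np.ndarray:
    """Stack of m(m+1)/2 fourth-order cumulant matrices, shape (m, m*nbcm)."""
    m, T = Z.shape
    nbcm = m * (m + 1) // 2
    CM = np.zeros((m, m * nbcm))
    R = np.eye(m)
    pos = 0
    sqrt2 = np.sqrt(2.0)
    for im in range(m):
        Zim = Z[im]
        Q = ((Zim * Zim) * Z) @ Z.T / T - R - 2.0 * np.outer(R[:, im], R[:, im])
        CM[:, pos : pos + m] = Q
        pos += m
        for jm in range(im):
            Zijm = Zim * Z[jm]
            Q = sqrt2 * (
                (Zijm * Z) @ Z.T / T
                - np.outer(R[:, im], R[:, jm])
                - np.outer(R[:, jm], R[:, im])
            )
            CM[:, pos : pos + m] = Q
            pos += m
    return CM


def _joint_diagonalize(CM: np.ndarray, m: int, max_sweeps: int = 100) -> np.ndarray:
    """Jacobi joint diagonalization; returns the orthogonal rotation V."""
    n_mat = CM.shape[1] // m
    V = np.eye(m)
    thresh = 1e-8 / np.sqrt(CM.shape[1] / m)  # scale-free rotation threshold
    for _ in range(max_sweeps):
        rotated = False
        for p in range(m - 1):
            for q in range(p + 1, m):
                Ip = np.arange(p, m * n_mat, m)
                Iq = np.arange(q, m * n_mat, m)
                g = np.vstack([CM[p, Ip] - CM[q, Iq], CM[p, Iq] + CM[q, Ip]])
                gg = g @ g.T
                ton = gg[0, 0] - gg[1, 1]
                toff = gg[0, 1] + gg[1, 0]
                theta = 0.5 * np.arctan2(toff, ton + np.sqrt(ton * ton + toff * toff))
                if abs(theta) > thresh:
                    rotated = True
                    c, s = np.cos(theta), np.sin(theta)
                    pair = np.array([[c, -s], [s, c]])
                    # rotate the two rows of every cumulant matrix ...
                    CM[[p, q], :] = pair.T @ CM[[p, q], :]
                    # ... and the two columns
                    cols_p, cols_q = CM[:, Ip].copy(), CM[:, Iq].copy()
                    CM[:, Ip] = c * cols_p + s * cols_q
                    CM[:, Iq] = -s * cols_p + c * cols_q
                    V[:, [p, q]] = V[:, [p, q]] @ pair
        if not rotated:
            break
    return V


def jade(X: np.ndarray, rank_tol: float = 1e-10):
    """Blind source separation of ``X`` (channels x samples) via JADE.

    Returns
    -------
    S : np.ndarray, shape (r, T)
        Recovered sources (r = numerical rank of the input), ordered by
        decreasing explained variance in the observation space, each with
        its largest-magnitude mixing coefficient made positive.
    B : np.ndarray, shape (r, m)
        Unmixing matrix such that ``S = B @ (X - mean)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DegenerateSignalError("expected a 2-D channels-by-samples array")
    Z, W, r = _whiten(X, rank_tol)
    CM = _cumulant_matrices(Z)
    V = _joint_diagonalize(CM.copy(), r)
    B = V.T @ W  # (r, m)

    # order components by the energy they carry in the observations
    A = np.linalg.pinv(B)
    power = np.sum(A**2, axis=0)
    order = np.argsort(power)[::-1]
    B = B[order]
    # fix signs: largest-magnitude mixing coefficient positive
    A = np.linalg.pinv(B)
    for i in range(B.shape[0]):
        col = A[:, i]
        if col[np.argmax(np.abs(col))] < 0:
            B[i] *= -1.0
    Xc = X - X.mean(axis=1, keepdims=True)
    return B @ Xc, B
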