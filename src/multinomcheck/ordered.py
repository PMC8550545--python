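"""The ordered-probability cone and the Zipf-Mandelbrot family.

A multinomial with *ordered* probabilities requires
``theta_1 >= theta_2 >= ... >= theta_{k+1}``.  The cone of such points is in
bijection with the whole simplex through the upper-triangular matrix ``A_k``
whose j-th column is (1/j, ..., 1/j, 0, ..., 0) (j copies of 1/j):
``theta = A_k omega`` is nonincreasing for every simplex point ``omega`` and,
conversely, ``omega_i = i (theta_i - theta_{i+1})`` (with
``omega_{k+1} = (k+1) theta_{k+1}``) recovers a simplex point from any
nonincreasing ``theta``.  Pushing a Dirichlet prior on ``omega`` through the
map therefore yields a prior supported exactly on the cone.

The Zipf-Mandelbrot pmf ``theta_i = (alpha + i)^(-beta) / C_k(alpha, beta)``
is a two-parameter subfamily of the cone (uniform at beta = 0, degenerate on
the first cell as beta -> inf) often used for abundance data.
"""

from __future__ import annotations

import numpy as np

from .core import ProbabilityVector

__all__ = [
    "ordered_matrix",
    "ordered_matrix_inv",
    "theta_from_omega",
    "omega_from_theta",
    "zm_pmf",
    "zm_log_pmf_table",
]

#: negative successive differences up to this absolute tolerance still count
#: as nonincreasing (and negative omega within it are clipped to 0)
MONOTONE_TOL = 1e-10


def ordered_matrix(k: int) -> np.ndarray:
    """The (k+1)x(k+1) matrix A_k mapping the simplex onto the ordered cone."""
    if k < 1:
        raise ValueError("k must be >= 1")
    j = np.arange(1, k + 2)
    A = np.triu(np.ones((k + 1, k + 1))) / j
    return A


def ordered_matrix_inv(k: int) -> np.ndarray:
    """Inverse of A_k: diagonal i, superdiagonal -i (1-based i)."""
    i = np.arange(1, k + 2)
    Ainv = np.diag(i).astype(float)
    Ainv[np.arange(k), np.arange(1, k + 1)] = -i[:-1]
    return Ainv


def theta_from_omega(omega) -> ProbabilityVector:
    """Map a simplex point omega to the ordered cone: theta_i = sum_{j>=i} omega_j / j."""
    w = np.asarray(ProbabilityVector(omega))
    theta = ordered_matrix(w.size - 1) @ w
    return ProbabilityVector(theta)


def theta_from_omega_many(omegas: np.ndarray) -> np.ndarray:
    """Vectorized theta_from_omega for an (N, k+1) array of simplex points."""
    omegas = np.atleast_2d(np.asarray(omegas, dtype=float))
    return omegas @ ordered_matrix(omegas.shape[1] - 1).T


def omega_from_theta(theta) -> ProbabilityVector:
    """Invert the cone map: omega_i = i (theta_i - theta_{i+1}), omega_{k+1} = (k+1) theta_{k+1}.

    Raises for input that is not nonincreasing beyond ``MONOTONE_TOL``; tiny
    negative omega values within tolerance are clipped and renormalized.
    """
    t = np.asarray(ProbabilityVector(theta))
    diffs = np.diff(t)
    bad = np.nonzero(diffs > MONOTONE_TOL)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"theta is not nonincreasing: theta[{i}] = {t[i]:.6g} < "
            f"theta[{i + 1}] = {t[i + 1]:.6g}")
    w = ordered_matrix_inv(t.size - 1) @ t
    w = np.clip(w, 0.0, None)
    return ProbabilityVector(w / w.sum())


def zm_pmf(k: int, alpha: float, beta: float) -> ProbabilityVector:
    """Zipf-Mandelbrot pmf on k+1 cells: theta_i proportional to (alpha + i)^(-beta)."""
    if not (alpha > -1):
        raise ValueError("alpha must be > -1")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    i = np.arange(1, k + 2)
    logw = -beta * np.log(alpha + i)
    logw -= logw.max()
    w = np.exp(logw)
    return ProbabilityVector(w / w.sum())


def zm_log_pmf_table(k: int, alphas: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """log pmf for every (alpha, beta) pair; shape (len(alphas), k+1).

    ``alphas`` and ``betas`` are paired element-wise (one row per family
    member), which is how the distance-table construction consumes them.
    """
    alphas = np.asarray(alphas, dtype=float)[:, None]
    betas = np.asarray(betas, dtype=float)[:, None]
    i = np.arange(1, k + 2)[None, :]
    logw = -betas * np.log(alphas + i)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return np.log(w / w.sum(axis=1, keepdims=True))
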