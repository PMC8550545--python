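"""Constraint regions Theta inside the simplex.

Each region knows three things: membership, the Kullback-Leibler distance
``d(theta) = inf_{theta* in Theta} KL(theta || theta*)`` used by the
measure-zero checking path, and (where a closed form exists) its content
under the uniform prior on the full simplex.  Provided regions:

* trine ellipses from qubit state estimation (positive measure, analytic
  content ``a sqrt(1-2a) pi``);
* the tetrahedron / cross-hairs / Pauli measurement models (quadratic-ball
  and linear-equality constraints);
* Hardy-Weinberg equilibrium surfaces for ``l`` alleles (measure zero; the
  KL minimizer is the allele-frequency plug-in, exact for every ``l``);
* the ordered-probability cone (positive measure ``1/(k+1)!``);
* the Zipf-Mandelbrot family, with the distance computed by minimizing over
  a table of family members.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from sklearn.isotonic import IsotonicRegression

from .core import ProbabilityVector, kl_divergence_many
from .ordered import MONOTONE_TOL, zm_log_pmf_table

__all__ = [
    "ConstraintRegion",
    "TrineGeometry",
    "TrineRegion",
    "trine_region",
    "quantum_region",
    "HWERegion",
    "hwe_region",
    "hwe_theta_from_omega",
    "hwe_allele_frequencies",
    "OrderedRegion",
    "ordered_region",
    "ZMRegion",
    "zm_region",
    "region_from_config",
]

#: d(theta) below this counts as membership for distance-defined regions
DISTANCE_MEMBERSHIP_TOL = 1e-10


class ConstraintRegion(ABC):
    """A subset Theta of the k-simplex with membership and KL distance."""

    name: str = "region"
    k: int
    has_positive_measure: bool = False

    @property
    def analytic_prior_mass(self) -> float | None:
        """Exact uniform-prior content of the region, if known."""
        return None

    @abstractmethod
    def contains(self, theta) -> bool:
        """Is theta a member of the region?"""

    def contains_many(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        return np.array([self.contains(t) for t in thetas], dtype=bool)

    @abstractmethod
    def distance(self, theta) -> float:
        """KL projection distance inf_{theta* in Theta} KL(theta || theta*)."""

    def distance_many(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        return np.array([self.distance(t) for t in thetas], dtype=float)

    def _check_dim(self, theta) -> np.ndarray:
        t = np.asarray(ProbabilityVector(theta))
        if t.size != self.k + 1:
            raise ValueError(
                f"{self.name} lives on {self.k + 1} cells, got {t.size}")
        return t


# ---------------------------------------------------------------------------
# Trine


class TrineGeometry:
    """Ellipse geometry of a trine measurement at detector angle phi0.

    With ``a = 0.5 sin^2(arccos(cot(2 phi0)))`` the feasible set in the
    first two coordinates is ``(theta - c)^t C (theta - c) <= 1`` for
    ``c = (a, (1-a)/2)`` and ``C = (1-2a)^(-1) [[(1-1/a)^2, 2], [2, 4]]``,
    positive definite for a in (0, 1/2).
    """

    def __init__(self, phi0: float):
        cot = 1.0 / math.tan(2 * phi0)
        if not -1.0 <= cot <= 1.0:
            raise ValueError(
                f"phi0 = {phi0!r} is outside the admissible range "
                "(cot(2 phi0) must lie in [-1, 1])")
        self.phi0 = float(phi0)
        self.a = 0.5 * math.sin(math.acos(cot)) ** 2
        if not 0.0 < self.a < 0.5:
            raise ValueError(f"phi0 = {phi0!r} gives degenerate a = {self.a!r}")
        a = self.a
        self.c = 0.5 * np.array([2 * a, 1 - a])
        self.C = np.array([[(1 - 1 / a) ** 2, 2.0], [2.0, 4.0]]) / (1 - 2 * a)
        # S with S^t C S = I maps the unit disk onto the ellipse
        evals, evecs = np.linalg.eigh(self.C)
        self.S = evecs @ np.diag(evals ** -0.5) @ evecs.T

    def quadratic_form(self, theta12: np.ndarray) -> np.ndarray:
        """(theta - c)^t C (theta - c) for rows of first-two-coordinate points."""
        z = np.atleast_2d(theta12) - self.c
        return np.einsum("ni,ij,nj->n", z, self.C, z)


class TrineRegion(ConstraintRegion):
    """The trine model ellipse on the 2-simplex; positive prior measure."""

    has_positive_measure = True
    k = 2

    def __init__(self, phi0: float):
        self.geometry = TrineGeometry(phi0)
        self.name = f"trine(phi0={phi0:.6g})"

    @property
    def analytic_prior_mass(self) -> float:
        # uniform density on Theta_2 in (theta1, theta2) coordinates is 2,
        # so the content is 2 * ellipse area = 2 * pi / sqrt(det C)
        # = a sqrt(1 - 2a) pi.
        a = self.geometry.a
        return a * math.sqrt(1 - 2 * a) * math.pi

    def contains(self, theta) -> bool:
        t = self._check_dim(theta)
        return bool(self.geometry.quadratic_form(t[:2][None, :])[0] <= 1.0)

    def contains_many(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        return self.geometry.quadratic_form(thetas[:, :2]) <= 1.0

    def distance(self, theta) -> float:
        """Numerical KL projection onto the ellipse (diagnostic use)."""
        t = self._check_dim(theta)
        if self.contains(t):
            return 0.0
        g = self.geometry

        def objective(z):
            p12 = g.c + g.S @ z
            p = np.array([p12[0], p12[1], 1.0 - p12.sum()])
            if np.any(p <= 0):
                return np.inf
            return float(kl_divergence_many(t[None, :], p[None, :])[0])

        best = np.inf
        for z0 in ([0.0, 0.0], [0.5, 0.0], [0.0, 0.5], [-0.5, 0.0], [0.0, -0.5]):
            res = minimize(objective, z0, method="SLSQP",
                           constraints=[{"type": "ineq",
                                         "fun": lambda z: 1.0 - z @ z}],
                           options={"maxiter": 200, "ftol": 1e-12})
            if res.fun < best:
                best = float(res.fun)
        return max(best, 0.0)


def trine_region(phi0: float) -> TrineRegion:
    """Trine ellipse region for detector angle ``phi0`` (radians)."""
    return TrineRegion(phi0)


# ---------------------------------------------------------------------------
# Quantum measurement models with quadratic-ball constraints


class _BallRegion(ConstraintRegion):
    """sum theta_i^2 <= ball_bound plus optional pairwise-sum equalities.

    The equality constraints (cross-hairs, Pauli) say consecutive pairs sum
    to ``pair_sum``; they cut the region down to measure zero, in which case
    the distance is minimized over the free coordinates of the affine slice.
    """

    def __init__(self, name: str, k: int, ball_bound: float,
                 pair_sum: float | None = None):
        self.name = name
        self.k = k
        self.ball_bound = ball_bound
        self.pair_sum = pair_sum
        self.has_positive_measure = pair_sum is None

    def contains(self, theta) -> bool:
        t = self._check_dim(theta)
        if self.pair_sum is not None:
            pairs = t.reshape(-1, 2).sum(axis=1)
            if not np.allclose(pairs, self.pair_sum, atol=1e-10):
                return False
        return bool(t @ t <= self.ball_bound + 1e-12)

    def contains_many(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        ok = (thetas ** 2).sum(axis=1) <= self.ball_bound + 1e-12
        if self.pair_sum is not None:
            pairs = thetas.reshape(thetas.shape[0], -1, 2).sum(axis=2)
            ok &= np.all(np.abs(pairs - self.pair_sum) <= 1e-10, axis=1)
        return ok

    def distance(self, theta) -> float:
        t = self._check_dim(theta)
        if self.contains(t):
            return 0.0
        m = self.k + 1

        if self.pair_sum is None:
            # full-dimensional ball: optimize over the whole simplex
            def objective(q):
                if np.any(q <= 0):
                    return np.inf
                return float(kl_divergence_many(t[None, :], q[None, :])[0])

            cons = [
                {"type": "eq", "fun": lambda q: q.sum() - 1.0},
                {"type": "ineq", "fun": lambda q: self.ball_bound - q @ q},
            ]
            x0 = np.full(m, 1.0 / m)
            res = minimize(objective, x0, method="SLSQP", constraints=cons,
                           bounds=[(1e-12, 1.0)] * m,
                           options={"maxiter": 300, "ftol": 1e-12})
            return max(float(res.fun), 0.0)

        # equality-constrained slice: free coordinates are the first member
        # of each pair, the second is pair_sum - first
        s = self.pair_sum

        def unpack(x):
            q = np.empty(m)
            q[0::2] = x
            q[1::2] = s - x
            return q

        def objective(x):
            q = unpack(x)
            if np.any(q <= 0):
                return np.inf
            return float(kl_divergence_many(t[None, :], q[None, :])[0])

        cons = [{"type": "ineq",
                 "fun": lambda x: self.ball_bound - unpack(x) @ unpack(x)}]
        best = np.inf
        for x0 in (np.full(m // 2, s / 2), np.clip(t[0::2], 1e-6, s - 1e-6)):
            res = minimize(objective, x0, method="SLSQP", constraints=cons,
                           bounds=[(1e-12, s - 1e-12)] * (m // 2),
                           options={"maxiter": 300, "ftol": 1e-12})
            if res.fun < best:
                best = float(res.fun)
        return max(best, 0.0)


_QUANTUM_REGIONS = {
    "tetrahedron": dict(k=3, ball_bound=1.0 / 3.0, pair_sum=None),
    "cross_hairs": dict(k=3, ball_bound=3.0 / 8.0, pair_sum=0.5),
    "pauli": dict(k=5, ball_bound=2.0 / 9.0, pair_sum=1.0 / 3.0),
}


def quantum_region(name: str) -> ConstraintRegion:
    """One of the quantum measurement models: tetrahedron, cross_hairs, pauli."""
    try:
        kw = _QUANTUM_REGIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown quantum region {name!r}; choose from "
            f"{sorted(_QUANTUM_REGIONS)}") from None
    return _BallRegion(name, **kw)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium


def _genotype_index(l: int):
    """Pairs (i, j), 0-based, i <= j, in row-major upper-triangle order."""
    return [(i, j) for i in range(l) for j in range(i, l)]


def hwe_theta_from_omega(omega: np.ndarray) -> np.ndarray:
    """Genotype probabilities under HWE: theta_ii = w_i^2, theta_ij = 2 w_i w_j.

    ``omega`` may be a single allele-frequency vector or an (N, l) array;
    output rows follow the upper-triangle genotype order.
    """
    w = np.atleast_2d(np.asarray(omega, dtype=float))
    l = w.shape[1]
    idx = _genotype_index(l)
    cols = [w[:, i] * w[:, j] * (1.0 if i == j else 2.0) for i, j in idx]
    out = np.stack(cols, axis=1)
    return out[0] if np.asarray(omega).ndim == 1 else out


def hwe_allele_frequencies(thetas: np.ndarray, l: int) -> np.ndarray:
    """Allele frequencies omega_i = theta_ii + 0.5 sum_{j != i} theta_ij.

    This is the exact KL minimizer of KL(theta || HWE(omega)): the
    omega-dependent part of the divergence is -sum_i m_i log(omega_i) with
    m_i the expected allele counts, maximized on the simplex at
    omega proportional to m.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    idx = _genotype_index(l)
    w = np.zeros((thetas.shape[0], l))
    for cell, (i, j) in enumerate(idx):
        if i == j:
            w[:, i] += thetas[:, cell]
        else:
            w[:, i] += 0.5 * thetas[:, cell]
            w[:, j] += 0.5 * thetas[:, cell]
    return w


class HWERegion(ConstraintRegion):
    """The Hardy-Weinberg surface for l alleles inside the genotype simplex."""

    has_positive_measure = False

    def __init__(self, l: int):
        if l < 2:
            raise ValueError("need at least 2 alleles")
        self.l = l
        self.k = l * (l + 1) // 2 - 1
        self.name = f"hwe(l={l})"

    def contains(self, theta) -> bool:
        return self.distance(theta) <= DISTANCE_MEMBERSHIP_TOL

    def contains_many(self, thetas: np.ndarray) -> np.ndarray:
        return self.distance_many(thetas) <= DISTANCE_MEMBERSHIP_TOL

    def distance(self, theta) -> float:
        t = self._check_dim(theta)
        return float(self.distance_many(t[None, :])[0])

    def distance_many(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        if thetas.shape[1] != self.k + 1:
            raise ValueError(
                f"expected {self.k + 1} genotype cells, got {thetas.shape[1]}")
        w = hwe_allele_frequencies(thetas, self.l)
        return kl_divergence_many(thetas, hwe_theta_from_omega(w))

    def distance_numeric(self, theta) -> float:
        """1-D/numeric minimization over omega; validation oracle for the plug-in."""
        t = self._check_dim(theta)
        if self.l == 2:
            res = minimize_scalar(
                lambda w: float(kl_divergence_many(
                    t[None, :], hwe_theta_from_omega(np.array([w, 1 - w]))[None, :])[0]),
                bounds=(1e-9, 1 - 1e-9), method="bounded",
                options={"xatol": 1e-12})
            return float(res.fun)

        def objective(w_free):
            w = np.append(w_free, 1.0 - w_free.sum())
            if np.any(w <= 0):
                return np.inf
            return float(kl_divergence_many(
                t[None, :], hwe_theta_from_omega(w)[None, :])[0])

        w0 = hwe_allele_frequencies(t[None, :], self.l)[0]
        # perturb the start so the oracle does not just sit at the plug-in
        x0 = np.clip(w0[:-1] + 0.01, 1e-6, 1 - 1e-6)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        return float(res.fun)


def hwe_region(l: int) -> HWERegion:
    """Hardy-Weinberg equilibrium region for ``l`` alleles."""
    return HWERegion(l)


# ---------------------------------------------------------------------------
# Ordered probabilities


class OrderedRegion(ConstraintRegion):
    """The monotone cone theta_1 >= ... >= theta_{k+1}; prior mass 1/(k+1)!."""

    has_positive_measure = True

    def __init__(self, k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.name = f"ordered(k={k})"
        self._iso = IsotonicRegression(increasing=False)

    @property
    def analytic_prior_mass(self) -> float:
        # uniform theta is exchangeable: each of the (k+1)! orderings is
        # equally likely
        return 1.0 / math.factorial(self.k + 1)

    def contains(self, theta) -> bool:
        t = self._check_dim(theta)
        return bool(np.all(np.diff(t) <= MONOTONE_TOL))

    def contains_many(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        return np.all(np.diff(thetas, axis=1) <= MONOTONE_TOL, axis=1)

    def distance(self, theta) -> float:
        """KL projection onto the cone.

        The projection is the pool-adjacent-violators fit: the KKT system of
        min -sum theta_i log(q_i) over nonincreasing simplex q forces q
        constant on pooled blocks with value equal to the block mean of theta.
        """
        t = self._check_dim(theta)
        x = np.arange(t.size)
        q = self._iso.fit_transform(x, t)
        q = np.clip(q, 0.0, None)
        q /= q.sum()
        return float(kl_divergence_many(t[None, :], q[None, :])[0])


def ordered_region(k: int) -> OrderedRegion:
    """Ordered-probability cone on the k-simplex."""
    return OrderedRegion(k)


# ---------------------------------------------------------------------------
# Zipf-Mandelbrot


class ZMRegion(ConstraintRegion):
    """The Zipf-Mandelbrot family, a measure-zero curve in the ordered cone.

    The distance is computed by tabling family members on a (beta, alpha)
    grid and minimizing KL(theta || ZM(alpha, beta)) over the table:
    ``d(theta) = min_g [ sum_i theta_i log theta_i - theta . logpmf_g ]``.
    Per the redundancy of the parameterization, for each beta the alpha grid
    stops once ZM(alpha, beta) is within ``delta/10`` KL of uniform (large
    alpha approaches uniformity, and beta = 0 is exactly uniform).
    """

    has_positive_measure = False

    def __init__(self, k: int, beta_max: float = 6.0, beta_step: float = 0.02,
                 n_alpha: int = 25, alpha_max: float = 1e4, delta: float = 0.02):
        self.k = k
        self.name = f"zm(k={k})"
        betas = np.arange(0.0, beta_max + beta_step / 2, beta_step)
        alpha_grid = np.geomspace(0.01, alpha_max + 1, n_alpha) - 1.0
        uniform = np.full(k + 1, 1.0 / (k + 1))
        pairs_a, pairs_b = [], []
        for b in betas:
            if b == 0.0:
                pairs_a.append(0.0)
                pairs_b.append(0.0)  # uniform once; every alpha is redundant
                continue
            for a in alpha_grid:
                pairs_a.append(a)
                pairs_b.append(b)
                zm = np.exp(zm_log_pmf_table(k, np.array([a]), np.array([b]))[0])
                if float(kl_divergence_many(zm[None, :], uniform)[0]) < delta / 10:
                    break
        if not pairs_a:
            raise ValueError("empty Zipf-Mandelbrot grid")
        self.alphas = np.array(pairs_a)
        self.betas = np.array(pairs_b)
        self._log_table = zm_log_pmf_table(k, self.alphas, self.betas)

    def contains(self, theta) -> bool:
        return self.distance(theta) <= DISTANCE_MEMBERSHIP_TOL

    def contains_many(self, thetas: np.ndarray) -> np.ndarray:
        return self.distance_many(thetas) <= DISTANCE_MEMBERSHIP_TOL

    def distance(self, theta) -> float:
        t = self._check_dim(theta)
        return float(self.distance_many(t[None, :])[0])

    def distance_many(self, thetas: np.ndarray, chunk: int = 4096) -> np.ndarray:
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        with np.errstate(divide="ignore", invalid="ignore"):
            neg_ent = np.where(thetas > 0, thetas * np.log(thetas), 0.0).sum(axis=1)
        out = np.empty(thetas.shape[0])
        for lo in range(0, thetas.shape[0], chunk):
            block = thetas[lo:lo + chunk]
            cross = block @ self._log_table.T  # (chunk, grid)
            out[lo:lo + chunk] = neg_ent[lo:lo + chunk] - cross.max(axis=1)
        return np.clip(out, 0.0, None)


def zm_region(k: int, **grid_kwargs) -> ZMRegion:
    """Zipf-Mandelbrot region with a tabled (alpha, beta) grid."""
    return ZMRegion(k, **grid_kwargs)


# ---------------------------------------------------------------------------
# Config-driven construction


def region_from_config(config: dict) -> ConstraintRegion:
    """Build a region from a config block, e.g. {"region": "trine", "phi0": 0.5236}."""
    cfg = dict(config)
    kind = cfg.pop("region", None)
    if kind == "trine":
        return trine_region(float(cfg["phi0"]))
    if kind in _QUANTUM_REGIONS:
        return quantum_region(kind)
    if kind == "hwe":
        return hwe_region(int(cfg.get("l", cfg.get("alleles", 2))))
    if kind == "ordered":
        return ordered_region(int(cfg["k"]))
    if kind == "zm":
        k = int(cfg.pop("k"))
        return zm_region(k, **cfg)
    raise ValueError(f"unknown region kind {kind!r}")
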