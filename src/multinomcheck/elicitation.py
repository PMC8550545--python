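"""Dirichlet prior elicitation from probability bounds.

Two elicitation routes are provided, both producing a Dirichlet in the
mode/concentration form ``alpha_i = 1 + tau * xi_i`` (all ``alpha_i >= 1``
so the density has no boundary singularities):

* **bounds on allele (or genotype) frequencies** -- lower bounds ``a_i``
  define the subsimplex ``{omega : omega_i >= a_i}``; the prior mode is its
  centroid and ``tau`` is the smallest concentration giving the subsimplex
  coverage ``gamma`` (exact Beta CDF for two alleles, Monte Carlo
  otherwise).  Genotype-probability bounds ``c_i <= theta_ii`` reduce to the
  same problem with ``a_i = sqrt(c_i)``.
* **an interval for ordered probabilities** -- an equispaced nonincreasing
  mode ``theta*_i = theta*_1 - (i-1) eps`` (feasible iff
  ``0 <= eps <= 2/(k(k+1))``) maps through the ordered-cone bijection to a
  Dirichlet mode ``xi_i = i eps`` (``xi_{k+1} = 1 - k(k+1) eps / 2``) on
  omega, and ``tau`` is the smallest concentration for which
  ``Pi(l < theta_{k+1}, theta_1 < u) >= gamma``.

The smallest-tau searches bracket by doubling and then bisect, using common
random numbers across tau so the Monte Carlo coverage curve is monotone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist

from .core import DirichletSpec, ProbabilityVector, RngLike, ensure_rng
from .ordered import ordered_matrix

__all__ = [
    "BoundsSpec",
    "ElicitedPrior",
    "mode_from_bounds",
    "tau_for_bounds",
    "equispaced_ordered_mode",
    "tau_for_interval",
    "grouped_bounds",
]

TAU_MIN = 0.05
TAU_MAX = 1e4


@dataclass
class BoundsSpec:
    """Expert bounds with joint coverage gamma.

    flavor 'allele': lower bounds a_i on each of the l frequencies
    (sum a_i <= 1; the implied upper bounds are b_i = 1 - sum_{j!=i} a_j).
    flavor 'genotype': lower bounds c_i on the homozygote probabilities,
    converted to allele bounds a_i = sqrt(c_i).
    flavor 'ordered_interval': a single interval 0 <= l < u <= 1 believed to
    contain every ordered cell probability.
    """

    flavor: str
    a: np.ndarray | None = None
    l: float | None = None
    u: float | None = None
    gamma: float = 0.99

    @classmethod
    def allele(cls, a, gamma: float = 0.99) -> "BoundsSpec":
        a = np.asarray(a, dtype=float)
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("bounds must lie in [0, 1]")
        if a.sum() > 1:
            raise ValueError(
                f"lower bounds sum to {a.sum():.4g} > 1; the bounds are "
                "infeasible -- this is easily satisfied by weakening some of "
                "the bounds")
        return cls(flavor="allele", a=a, gamma=gamma)

    @classmethod
    def genotype(cls, c, gamma: float = 0.99) -> "BoundsSpec":
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("genotype bounds must be nonnegative")
        a = np.sqrt(c)
        if a.sum() > 1:  # (sum sqrt(c_i))^2 <= 1 is the stated feasibility
            raise ValueError("(sum sqrt(c_i))^2 exceeds 1; bounds infeasible")
        return cls.allele(a, gamma=gamma)

    @classmethod
    def ordered_interval(cls, l: float, u: float,
                         gamma: float = 0.99) -> "BoundsSpec":
        if not (0.0 <= l < u <= 1.0):
            raise ValueError("need 0 <= l < u <= 1")
        return cls(flavor="ordered_interval", l=l, u=u, gamma=gamma)


@dataclass
class ElicitedPrior:
    """An elicited Dirichlet prior plus the provenance of the search."""

    spec: DirichletSpec
    tau: float
    mode: ProbabilityVector
    gamma: float
    coverage: float
    bounds: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)

    def __repr__(self) -> str:
        return (f"ElicitedPrior(tau={self.tau:.4g}, "
                f"alpha={np.round(self.spec.alpha, 4).tolist()}, "
                f"coverage={self.coverage:.4f} >= gamma={self.gamma})")


def mode_from_bounds(spec: BoundsSpec) -> ProbabilityVector:
    """Centroid of the subsimplex {omega : omega_i >= a_i}.

    The subsimplex is a shrunken copy of the full simplex (equal edges), so
    its centroid is ``a_i + (1 - sum_j a_j) / l``.  For two alleles this is
    ((a_1 + 1 - a_2)/2, (a_2 + 1 - a_1)/2).
    """
    if spec.flavor not in ("allele", "genotype"):
        raise ValueError("mode_from_bounds expects allele/genotype bounds")
    a = spec.a
    slack = 1.0 - a.sum()
    return ProbabilityVector(a + slack / a.size)


def _smallest_tau(coverage, gamma: float, tol: float = 1e-3):
    """Bracket by doubling, then bisect; coverage must be nondecreasing in tau."""
    trace = []
    lo = None
    hi = None
    tau = TAU_MIN
    while tau <= TAU_MAX:
        c = coverage(tau)
        trace.append((tau, c))
        if c >= gamma:
            hi = tau
            break
        lo = tau
        tau *= 2.0
    if hi is None:
        raise ValueError(
            f"coverage gamma = {gamma} unattainable on tau <= {TAU_MAX:g}; "
            f"maximum achieved was {trace[-1][1]:.4f}")
    if lo is None:  # already covered at the grid minimum
        return TAU_MIN, trace[-1][1], trace
    while hi - lo > tol * hi:
        mid = 0.5 * (lo + hi)
        c = coverage(mid)
        trace.append((mid, c))
        if c >= gamma:
            hi = mid
        else:
            lo = mid
    return hi, coverage(hi), trace


def tau_for_bounds(spec: BoundsSpec, mode: ProbabilityVector | None = None,
                   n_draws: int = 100_000,
                   rng: RngLike = None) -> ElicitedPrior:
    """Smallest tau giving the bounds subsimplex prior coverage gamma.

    Two alleles use the exact Beta CDF; more use Monte Carlo with a fixed
    seed shared across tau values (common random numbers).
    """
    if spec.flavor not in ("allele", "genotype"):
        raise ValueError("tau_for_bounds expects allele/genotype bounds")
    xi = mode_from_bounds(spec) if mode is None else ProbabilityVector(mode)
    xiv = np.asarray(xi)
    a = spec.a
    if np.any(xiv < a):
        raise ValueError("the mode must lie inside the bounds subsimplex")
    l = a.size

    if l == 2:
        lo_b, hi_b = a[0], 1.0 - a[1]

        def coverage(tau):
            a1, a2 = 1.0 + tau * xiv[0], 1.0 + tau * xiv[1]
            return float(beta_dist.cdf(hi_b, a1, a2) - beta_dist.cdf(lo_b, a1, a2))
    else:
        seed = int(ensure_rng(rng).integers(2**31))

        def coverage(tau):
            draws = np.random.default_rng(seed).dirichlet(1.0 + tau * xiv,
                                                          n_draws)
            return float(np.all(draws >= a[None, :], axis=1).mean())

    tau, cov, trace = _smallest_tau(coverage, spec.gamma)
    return ElicitedPrior(
        spec=DirichletSpec.from_mode_concentration(xiv, tau), tau=tau,
        mode=xi, gamma=spec.gamma, coverage=cov,
        bounds={"a": a.tolist()}, trace=trace)


def equispaced_ordered_mode(k: int, epsilon: float):
    """Equispaced nonincreasing mode and its omega-space Dirichlet mode.

    Returns (theta_star, xi): theta*_i = theta*_1 - (i-1) eps with
    theta*_1 = k eps / 2 + 1/(k+1), and xi_i = i eps (i <= k),
    xi_{k+1} = 1 - k(k+1) eps / 2, so that A_k xi = theta*.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eps_max = 2.0 / (k * (k + 1))
    if not (0.0 <= epsilon <= eps_max + 1e-15):
        raise ValueError(f"epsilon must lie in [0, {eps_max:.6g}]")
    theta1 = k * epsilon / 2.0 + 1.0 / (k + 1)
    theta_star = theta1 - epsilon * np.arange(k + 1)
    xi = np.append(epsilon * np.arange(1, k + 1),
                   1.0 - k * (k + 1) * epsilon / 2.0)
    return ProbabilityVector(np.clip(theta_star, 0.0, None)), ProbabilityVector(xi)


def tau_for_interval(xi: ProbabilityVector, *, l: float, u: float,
                     gamma: float = 0.99, n_draws: int = 100_000,
                     rng: RngLike = None) -> ElicitedPrior:
    """Smallest tau with Pi(l < theta_{k+1}, theta_1 < u) >= gamma.

    ``xi`` is the omega-space Dirichlet mode; under the cone bijection
    theta_1 = sum_i omega_i / i and theta_{k+1} = omega_{k+1}/(k+1), so the
    coverage is a plain Monte Carlo probability over Dirichlet(1 + tau xi)
    draws, with common random numbers across tau.
    """
    xiv = np.asarray(ProbabilityVector(xi))
    k = xiv.size - 1
    theta_star = ordered_matrix(k) @ xiv
    if not (l < theta_star[-1] + 1e-15 and theta_star[0] < u + 1e-15):
        raise ValueError(
            f"need l < theta*_(k+1) <= theta*_1 < u, got l={l}, "
            f"theta*_(k+1)={theta_star[-1]:.6g}, theta*_1={theta_star[0]:.6g}, "
            f"u={u}")
    inv_i = 1.0 / np.arange(1, k + 2)
    seed = int(ensure_rng(rng).integers(2**31))

    def coverage(tau):
        w = np.random.default_rng(seed).dirichlet(1.0 + tau * xiv, n_draws)
        th1 = w @ inv_i
        thk = w[:, -1] / (k + 1)
        return float(((thk > l) & (th1 < u)).mean())

    tau, cov, trace = _smallest_tau(coverage, gamma)
    return ElicitedPrior(
        spec=DirichletSpec.from_mode_concentration(xiv, tau), tau=tau,
        mode=ProbabilityVector(xiv), gamma=gamma, coverage=cov,
        bounds={"l": l, "u": u}, trace=trace)


def grouped_bounds(spec: BoundsSpec, k: int, m: int) -> BoundsSpec:
    """Interval bounds implied for the stride-grouped ordered problem.

    With m groups of (up to) g = ceil((k+1)/m) members, group j sums cells
    j, j+m, j+2m, ...; the ordering of the group sums is preserved.  Each
    cell satisfies both theta_i > l (the elicited interval) and the ceiling
    theta_i <= 1/i, so the group sums satisfy

        u' = u + sum_{r=1..g-1} 1/(1 + r m)   (first group's extra ceilings)
        l' = g l                              (last group's elicited floors)

    which at k+1 = 18, m = 9 (pairs) gives u + 1/10 and 2l.  When m = k+1
    (no grouping) the bounds are unchanged.  These implied bounds are a
    diagnostic on the grouped problem; the grouped prior itself reuses the
    concentration elicited on the full problem (see grouped_conflict_check).
    """
    if spec.flavor != "ordered_interval":
        raise ValueError("grouped_bounds expects ordered_interval bounds")
    if m < 2 or m > k + 1:
        raise ValueError("need 2 <= m <= k+1 groups")
    g = math.ceil((k + 1) / m)
    u_new = spec.u + sum(1.0 / (1 + r * m) for r in range(1, g))
    l_new = g * spec.l
    return BoundsSpec.ordered_interval(l=l_new, u=min(u_new, 1.0),
                                       gamma=spec.gamma)
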