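"""Prior-data conflict checks via the prior predictive of the cell counts.

Given a prior Pi on theta (possibly through a map, e.g. allele frequencies
under Hardy-Weinberg or the ordered-cone bijection), the prior predictive of
the counts is

    m_T(t) = multinom(n; t) * Integral prod_j theta_j^{t_j} pi(theta) dtheta

and the conflict check reports the tail probability
``M_T( m_T(t) <= m_T(T(x)) )``: the prior probability, before seeing data,
of counts no more prior-plausible than the observed ones.  A small value
says the observed counts sit in the tails of the prior predictive, i.e. the
prior puts its mass in the wrong part of the parameter space.

m_T is closed-form for Dirichlet priors on theta and for Dirichlet priors on
allele frequencies under HWE; for the trine and ordered-cone priors it is
estimated by importance sampling in a nested Monte Carlo loop.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import (CellCounts, DirichletSpec, ProbabilityVector, RngLike,
                   ensure_rng)
from .ordered import (ordered_matrix, ordered_matrix_inv,
                      theta_from_omega_many)
from .regions import (OrderedRegion, TrineGeometry, hwe_theta_from_omega)

__all__ = [
    "ConflictReport",
    "hwe_log_mT",
    "dirichlet_log_mT",
    "trine_prior_sampler",
    "TrinePrior",
    "importance_log_mT",
    "convex_boundary_mode",
    "stride_group_counts",
    "HWEPriorPredictive",
    "DirichletPriorPredictive",
    "TrinePriorPredictive",
    "OrderedPriorPredictive",
    "tail_probability",
    "grouped_conflict_check",
    "conflict_convergence_experiment",
]

#: log m_T ties in the tail probability are compared to this tolerance
LOG_TIE_TOL = 1e-12
#: default flag cutoff: tail probabilities below this are reported as conflict
CONFLICT_CUTOFF = 0.05
#: importance-sampling effective sample sizes below this fraction trigger a warning
ESS_FLOOR_FRACTION = 0.01


@dataclass
class ConflictReport:
    """Result of a prior-data conflict check."""

    tail_probability: float
    log_mT_observed: float
    n_outer: int
    n_inner: int
    mc_se: float
    conflict: bool
    cutoff: float = CONFLICT_CUTOFF
    settings: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def summary(self) -> str:
        return (f"tail probability : {self.tail_probability:.4f} "
                f"(MC SE {self.mc_se:.4f})\n"
                f"log m_T(observed): {self.log_mT_observed:.4f}\n"
                f"conflict (<{self.cutoff:g})   : {self.conflict}")


def _log_multinomial_coef(t: np.ndarray) -> np.ndarray:
    t = np.atleast_2d(np.asarray(t, dtype=float))
    return gammaln(t.sum(axis=1) + 1.0) - gammaln(t + 1.0).sum(axis=1)


def _log_beta_fn(alpha: np.ndarray) -> np.ndarray:
    """Multivariate log Beta function over the last axis."""
    alpha = np.asarray(alpha, dtype=float)
    return gammaln(alpha).sum(axis=-1) - gammaln(alpha.sum(axis=-1))


def _log_dirichlet_pdf(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet log density (support violations give -inf)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    alpha = np.asarray(alpha, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = ((alpha - 1.0) * np.log(x)).sum(axis=1) - _log_beta_fn(alpha)
    lp = np.where(np.any((x <= 0) & (alpha != 1.0), axis=1), -np.inf, lp)
    return np.nan_to_num(lp, nan=-np.inf, posinf=-np.inf)


# ---------------------------------------------------------------------------
# Closed forms


def hwe_log_mT(counts, prior: DirichletSpec) -> float:
    """Exact log prior predictive of genotype counts under HWE.

    The prior is a Dirichlet on the ``l`` allele frequencies.  Substituting
    theta_ii = w_i^2 and theta_ij = 2 w_i w_j turns the integrand into a
    polynomial in w, integrated exactly by a ratio of multivariate Beta
    functions:

        m_T(t) = multinom(n; t) * 2^{sum_{i<j} t_ij}
                 * B(alpha + e) / B(alpha),
        e_i = 2 t_ii + sum_{j != i} t_ij   (allele counts).
    """
    counts = counts if isinstance(counts, CellCounts) else CellCounts(counts)
    alpha = prior.alpha
    l = alpha.size
    if counts.k + 1 != l * (l + 1) // 2:
        raise ValueError(
            f"{counts.k + 1} cells do not index genotypes of {l} alleles")
    t = np.asarray(counts, dtype=float)
    e = np.zeros(l)
    het = 0.0
    cell = 0
    for i in range(l):
        for j in range(i, l):
            if i == j:
                e[i] += 2 * t[cell]
            else:
                e[i] += t[cell]
                e[j] += t[cell]
                het += t[cell]
            cell += 1
    return float(_log_multinomial_coef(t)[0] + het * math.log(2)
                 + _log_beta_fn(alpha + e) - _log_beta_fn(alpha))


def _hwe_log_mT_many(ts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Vectorized hwe_log_mT for an (N, cells) count array."""
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    l = alpha.size
    e = np.zeros((ts.shape[0], l))
    het = np.zeros(ts.shape[0])
    cell = 0
    for i in range(l):
        for j in range(i, l):
            if i == j:
                e[:, i] += 2 * ts[:, cell]
            else:
                e[:, i] += ts[:, cell]
                e[:, j] += ts[:, cell]
                het += ts[:, cell]
            cell += 1
    return (_log_multinomial_coef(ts) + het * math.log(2)
            + _log_beta_fn(alpha[None, :] + e) - _log_beta_fn(alpha))


def dirichlet_log_mT(counts, prior: DirichletSpec) -> float:
    """Exact log prior predictive under a Dirichlet prior directly on theta."""
    counts = counts if isinstance(counts, CellCounts) else CellCounts(counts)
    if counts.k != prior.k:
        raise ValueError("counts and prior dimension mismatch")
    t = np.asarray(counts, dtype=float)
    return float(_log_multinomial_coef(t)[0]
                 + _log_beta_fn(prior.alpha + t) - _log_beta_fn(prior.alpha))


def _dirichlet_log_mT_many(ts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    return (_log_multinomial_coef(ts)
            + _log_beta_fn(alpha[None, :] + ts) - _log_beta_fn(alpha))


# ---------------------------------------------------------------------------
# Trine prior (Hilbert-Schmidt measure pushed onto the simplex)


def trine_prior_sampler(geometry: TrineGeometry, size: int,
                        rng: RngLike = None) -> np.ndarray:
    """Draws from the trine prior pi(theta) prop. (1 - (theta-c)^t C (theta-c))^(1/2).

    Uses the polar representation theta_{1:2} = c + S r^(1/2) (cos w, sin w)
    with w ~ U(0, 2 pi) independent of r ~ beta(3/2, 3/2) and S the matrix
    root satisfying S^t C S = I (the root of C^{-1}; the transformation must
    invert C for the quadratic form of a draw to equal r).
    """
    gen = ensure_rng(rng)
    w = gen.uniform(0.0, 2 * math.pi, size)
    r = gen.beta(1.5, 1.5, size)
    z = np.sqrt(r)[:, None] * np.stack([np.cos(w), np.sin(w)], axis=1)
    t12 = geometry.c + z @ geometry.S.T
    return np.column_stack([t12, 1.0 - t12.sum(axis=1)])


class TrinePrior:
    """The trine prior as a density on the simplex."""

    def __init__(self, phi0: float):
        self.geometry = TrineGeometry(phi0)
        # normalizer of (1 - Q)^{1/2} over the ellipse, by the polar
        # substitution: Z = (2 pi / 3) |det S| with |det S| = det(C)^{-1/2}
        det_S = 1.0 / math.sqrt(np.linalg.det(self.geometry.C))
        self.log_norm = math.log(2 * math.pi / 3.0) + math.log(det_S)

    def sample(self, size: int, rng: RngLike = None) -> np.ndarray:
        return trine_prior_sampler(self.geometry, size, rng)

    def log_density_unnorm(self, thetas: np.ndarray) -> np.ndarray:
        """log pi + log_norm, in (theta1, theta2) coordinates."""
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        q = self.geometry.quadratic_form(thetas[:, :2])
        with np.errstate(invalid="ignore"):
            lp = 0.5 * np.log(1.0 - q)
        return np.where(q < 1.0, lp, -np.inf)

    def log_density(self, thetas: np.ndarray) -> np.ndarray:
        return self.log_density_unnorm(thetas) - self.log_norm


def _log_likelihood(draws: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Row-wise log prod theta_j^{t_j}; -inf on support violations."""
    with np.errstate(divide="ignore"):
        ll = np.where(t[None, :] > 0,
                      t[None, :] * np.log(np.where(draws > 0, draws, 1.0)),
                      0.0).sum(axis=1)
    return np.where(np.all((draws > 0) | (t[None, :] == 0), axis=1), ll, -np.inf)


def importance_log_mT(counts, prior, n_inner: int = 10_000,
                      proposal: DirichletSpec | None = None,
                      rng: RngLike = None) -> tuple[float, float]:
    """Importance-sampling estimate of log m_T under a simplex-density prior.

    ``prior`` must expose ``log_density_unnorm(thetas)`` and, if the
    normalizer is known, ``log_norm`` (otherwise estimates are shifted by a
    constant common to every count vector, which cancels in the tail
    probability's comparisons).  The estimator averages the stable ratio
    ``L(theta) pi(theta) / q(theta)`` over draws from the proposal ``q``,
    which defaults to Dirichlet(t+1) -- the uniform-prior posterior, tracking
    the likelihood's concentration.  Draws outside the prior's support get
    zero weight.  Returns (log m_T estimate, effective sample size of the
    integrand weights); an ESS below 1% of ``n_inner`` triggers a warning.
    """
    counts = counts if isinstance(counts, CellCounts) else CellCounts(counts)
    t = np.asarray(counts, dtype=float)
    if proposal is None:
        proposal = DirichletSpec(t + 1.0)
    gen = ensure_rng(rng)
    draws = gen.dirichlet(proposal.alpha, n_inner)
    log_prior = (prior.log_density_unnorm(draws)
                 - getattr(prior, "log_norm", 0.0))
    vals = _log_likelihood(draws, t) + log_prior - _log_dirichlet_pdf(
        draws, proposal.alpha)
    finite = np.isfinite(vals)
    if not finite.any():
        warnings.warn("importance weights are identically zero: the proposal "
                      "never hits the prior's support", RuntimeWarning)
        return float("-inf"), 0.0
    log_int = logsumexp(vals) - math.log(n_inner)
    v = np.exp(vals - vals[finite].max())
    ess = float(v.sum() ** 2 / (v ** 2).sum())
    if ess < ESS_FLOOR_FRACTION * n_inner:
        warnings.warn(
            f"importance sampling ESS = {ess:.1f} of {n_inner} draws; the "
            "estimate is unreliable", RuntimeWarning)
    return float(_log_multinomial_coef(t)[0] + log_int), ess


def convex_boundary_mode(prior_mode, freq, region: OrderedRegion,
                         tol: float = 1e-12) -> ProbabilityVector:
    """Pull a frequency vector to the boundary of the ordered cone.

    Returns the convex combination ``lam * prior_mode + (1 - lam) * freq``
    with the smallest ``lam`` that lies in the (closed) cone -- i.e. the
    point of entry on the segment from the raw frequencies to the prior
    mode.  If ``freq`` is already in the cone it is returned unchanged.
    """
    mode = np.asarray(ProbabilityVector(prior_mode))
    f = np.asarray(ProbabilityVector(freq))
    if region.contains(f):
        return ProbabilityVector(f)
    if not region.contains(mode):
        raise ValueError("prior_mode must lie in the ordered cone")
    lo, hi = 0.0, 1.0  # lo: outside, hi: inside
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if region.contains(mid * mode + (1 - mid) * f):
            hi = mid
        else:
            lo = mid
    return ProbabilityVector(hi * mode + (1 - hi) * f)


def stride_group_counts(counts, m: int) -> CellCounts:
    """Group k+1 cells into m groups by stride: group j = cells j, j+m, j+2m, ...

    Unlike consecutive grouping this pattern preserves the monotone ordering
    of the group sums when the cell probabilities are ordered, which is what
    the grouped conflict check needs.  When m does not divide k+1 the final
    strides simply have one member fewer.
    """
    counts = counts if isinstance(counts, CellCounts) else CellCounts(counts)
    if m < 2:
        raise ValueError("need at least 2 groups")
    c = np.asarray(counts)
    if m > c.size:
        raise ValueError("more groups than cells")
    return CellCounts([int(c[j::m].sum()) for j in range(m)])


def _stride_group_thetas(thetas: np.ndarray, m: int) -> np.ndarray:
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    return np.stack([thetas[:, j::m].sum(axis=1) for j in range(m)], axis=1)


# ---------------------------------------------------------------------------
# Prior predictive models


class _PriorPredictive:
    """Common machinery: sample theta, then t ~ multinomial(n, theta)."""

    n: int
    n_inner: int = 0

    def sample_theta(self, size: int, rng: RngLike = None) -> np.ndarray:
        raise NotImplementedError

    def log_mT(self, counts, rng: RngLike = None) -> float:
        raise NotImplementedError

    def log_mT_many(self, ts: np.ndarray, rng: RngLike = None) -> np.ndarray:
        return np.array([self.log_mT(CellCounts(row), rng) for row in ts])


class HWEPriorPredictive(_PriorPredictive):
    """Dirichlet prior on allele frequencies; closed-form m_T."""

    def __init__(self, prior: DirichletSpec, n: int):
        self.prior = prior
        self.n = n

    def sample_theta(self, size, rng=None):
        w = ensure_rng(rng).dirichlet(self.prior.alpha, size)
        return hwe_theta_from_omega(w)

    def log_mT(self, counts, rng=None):
        return hwe_log_mT(counts, self.prior)

    def log_mT_many(self, ts, rng=None):
        return _hwe_log_mT_many(ts, self.prior.alpha)


class DirichletPriorPredictive(_PriorPredictive):
    """Dirichlet prior directly on theta; closed-form m_T."""

    def __init__(self, prior: DirichletSpec, n: int):
        self.prior = prior
        self.n = n

    def sample_theta(self, size, rng=None):
        return ensure_rng(rng).dirichlet(self.prior.alpha, size)

    def log_mT(self, counts, rng=None):
        return dirichlet_log_mT(counts, self.prior)

    def log_mT_many(self, ts, rng=None):
        return _dirichlet_log_mT_many(ts, self.prior.alpha)


class TrinePriorPredictive(_PriorPredictive):
    """Trine (Hilbert-Schmidt) prior; m_T by importance sampling.

    For each count vector the integral is estimated with ``n_inner`` draws
    from the Dirichlet(t+1) proposal (which mimics the likelihood's
    concentration near the observed frequencies), self-normalized against
    the unnormalized trine density.
    """

    def __init__(self, phi0: float, n: int, n_inner: int = 10_000):
        self.prior = TrinePrior(phi0)
        self.n = n
        self.n_inner = n_inner

    def sample_theta(self, size, rng=None):
        return self.prior.sample(size, rng)

    def log_mT(self, counts, rng=None):
        val, _ = importance_log_mT(counts, self.prior,
                                   n_inner=self.n_inner, rng=rng)
        return val


class OrderedPriorPredictive(_PriorPredictive):
    """Lemma-style ordered-cone prior: omega ~ Dirichlet(alpha), theta = A omega.

    m_T is estimated by importance sampling in omega-space, where both the
    prior and the proposal are ordinary Dirichlets.  The proposal is a
    Dirichlet with concentration ``tau_proposal`` whose mode maps to the
    observed frequencies pulled back to the boundary of the cone (the convex
    combination of the prior mode and t/n that just enters the cone), so
    every proposal draw stays inside the prior's support.

    ``tau_proposal`` may also be a sequence of concentrations, in which case
    each m_T evaluation is run at every concentration and the largest
    estimate kept.  This is the tuning heuristic for the proposal: the IS
    estimate of log m_T is biased downward when the proposal mixes poorly
    (Jensen), so the concentration at which smaller and larger values both
    give smaller estimates is the best-mixed one.
    """

    def __init__(self, omega_prior: DirichletSpec, n: int,
                 n_inner: int = 10_000,
                 tau_proposal: float | tuple = 60.0):
        self.prior = omega_prior
        self.n = n
        self.n_inner = n_inner
        self.tau_grid = (tuple(tau_proposal)
                         if np.iterable(tau_proposal) else (float(tau_proposal),))
        self.tau_proposal = self.tau_grid[0]
        self.k = omega_prior.k
        self._region = OrderedRegion(self.k)
        self._A = ordered_matrix(self.k)
        self._Ainv = ordered_matrix_inv(self.k)

    @property
    def theta_mode(self) -> np.ndarray:
        """Prior mode mapped into the cone (mean used for the uniform prior)."""
        if np.all(self.prior.alpha > 1.0):
            xi = np.asarray(self.prior.mode)
        else:
            xi = self.prior.mean
        return self._A @ xi

    def sample_theta(self, size, rng=None):
        w = ensure_rng(rng).dirichlet(self.prior.alpha, size)
        return theta_from_omega_many(w)

    def _proposal_xi(self, counts) -> np.ndarray:
        t = np.asarray(counts, dtype=float)
        freq = t / t.sum()
        # zero-frequency cells are nudged inside the simplex before the pull-back
        freq = np.clip(freq, 1e-9, None)
        freq /= freq.sum()
        boundary = convex_boundary_mode(self.theta_mode, freq, self._region)
        xi = np.clip(self._Ainv @ np.asarray(boundary), 0.0, None)
        return xi / xi.sum()

    def _log_mT_at(self, t: np.ndarray, prop_alpha: np.ndarray,
                   gen: np.random.Generator) -> float:
        w = gen.dirichlet(prop_alpha, self.n_inner)
        thetas = theta_from_omega_many(w)
        vals = (_log_likelihood(thetas, t)
                + _log_dirichlet_pdf(w, self.prior.alpha)
                - _log_dirichlet_pdf(w, prop_alpha))
        return float(_log_multinomial_coef(t)[0]
                     + logsumexp(vals) - math.log(self.n_inner))

    def log_mT(self, counts, rng=None):
        counts = counts if isinstance(counts, CellCounts) else CellCounts(counts)
        t = np.asarray(counts, dtype=float)
        if t.sum() == 0:
            return 0.0
        gen = ensure_rng(rng)
        xi = self._proposal_xi(counts)
        return max(self._log_mT_at(t, 1.0 + tau * xi, gen)
                   for tau in self.tau_grid)


# ---------------------------------------------------------------------------
# The tail probability and its workflows


def tail_probability(model: _PriorPredictive, observed,
                     n_outer: int = 1_000, rng: RngLike = None,
                     cutoff: float = CONFLICT_CUTOFF) -> ConflictReport:
    """Eq.-style prior-data conflict check: M_T(m_T(t) <= m_T(T(x))).

    Draws theta from the prior and t ~ multinomial(n, theta) ``n_outer``
    times, evaluates log m_T for each simulated count vector and reports the
    fraction at or below log m_T of the observed counts (ties included).
    """
    observed = observed if isinstance(observed, CellCounts) else CellCounts(observed)
    if observed.n != model.n:
        raise ValueError(
            f"observed n = {observed.n} but the model was built for n = {model.n}")
    gen = ensure_rng(rng)
    thetas = model.sample_theta(n_outer, gen)
    ts = gen.multinomial(model.n, thetas)
    log_m = model.log_mT_many(ts, gen)
    log_obs = model.log_mT(observed, gen)
    tail = float((log_m <= log_obs + LOG_TIE_TOL).mean())
    se = math.sqrt(max(tail * (1 - tail), 0.0) / n_outer)
    return ConflictReport(
        tail_probability=tail, log_mT_observed=float(log_obs),
        n_outer=n_outer, n_inner=getattr(model, "n_inner", 0), mc_se=se,
        conflict=tail < cutoff, cutoff=cutoff,
        settings={"model": type(model).__name__, "n": model.n})


def grouped_conflict_check(observed, *, l: float, u: float,
                           epsilon: float = 0.0, gamma: float = 0.99,
                           m: int, tau: float | None = None,
                           n_outer: int = 1_000, n_inner: int = 10_000,
                           tau_proposal: float | tuple = (20.0, 60.0, 180.0),
                           n_pm_draws: int = 10_000,
                           rng: RngLike = None) -> ConflictReport:
    """Conflict check for the ordered model after stride grouping to m groups.

    The elicited information lives on the full k+1-cell problem: an
    equispaced mode with spacing ``epsilon`` and the belief that every cell
    probability lies in (l, u) with probability ``gamma``, which fixes the
    concentration ``tau`` (elicited here unless supplied).  Grouping to m
    stride groups preserves the ordering, and the grouped prior is obtained
    through the cone bijection with the regrouped mode (spacing g*epsilon
    for group size g) and the *same* concentration -- the grouped problem
    reuses the elicited degree of belief rather than re-eliciting it.

    The report's settings carry the implied grouped interval (a diagnostic;
    see :func:`multinomcheck.elicitation.grouped_bounds`) and ``p_in_cone``,
    the proportion of full-prior-predictive frequency vectors whose grouped
    version lands inside the reduced cone -- the quantity used to decide how
    far to group before importance sampling becomes reliable.
    """
    from .elicitation import (BoundsSpec, equispaced_ordered_mode,
                              grouped_bounds, tau_for_interval)

    observed = observed if isinstance(observed, CellCounts) else CellCounts(observed)
    k = observed.k
    gen = ensure_rng(rng)

    _, xi_full = equispaced_ordered_mode(k, epsilon)
    if tau is None:
        tau = tau_for_interval(xi_full, l=l, u=u, gamma=gamma, rng=gen).tau

    g = math.ceil((k + 1) / m)
    eps_grouped = g * epsilon
    _, xi = equispaced_ordered_mode(m - 1, eps_grouped)
    model = OrderedPriorPredictive(
        DirichletSpec.from_mode_concentration(np.asarray(xi), tau),
        observed.n, n_inner=n_inner, tau_proposal=tau_proposal)
    grouped_obs = stride_group_counts(observed, m)
    report = tail_probability(model, grouped_obs, n_outer=n_outer, rng=gen)

    # p_m: grouped frequencies of the FULL prior predictive inside the cone
    full = OrderedPriorPredictive(
        DirichletSpec.from_mode_concentration(np.asarray(xi_full), tau),
        observed.n)
    freqs = gen.multinomial(observed.n,
                            full.sample_theta(n_pm_draws, gen)) / observed.n
    p_in_cone = float(OrderedRegion(m - 1).contains_many(
        _stride_group_thetas(freqs, m)).mean())

    gspec = grouped_bounds(BoundsSpec.ordered_interval(l=l, u=u, gamma=gamma),
                           k, m)
    report.settings.update({
        "m": m, "tau": tau, "epsilon_grouped": eps_grouped,
        "l_grouped": gspec.l, "u_grouped": gspec.u,
        "p_in_cone": p_in_cone,
    })
    return report


def conflict_convergence_experiment(prior: DirichletSpec, theta_true,
                                    n_grid, reps: int = 10,
                                    n_outer: int = 1_000,
                                    n_limit_draws: int = 100_000,
                                    rng: RngLike = None) -> dict:
    """Empirical check that the tail probability converges to
    Pi(pi(theta) <= pi(theta_true)) as n grows.

    For each n in ``n_grid``, simulates ``reps`` data sets from
    multinomial(n, theta_true), computes the conflict tail probability for
    each (closed-form Dirichlet m_T) and records the mean.  The limiting
    target is computed by Monte Carlo over the prior.
    """
    theta_true = np.asarray(ProbabilityVector(theta_true))
    gen = ensure_rng(rng)

    draws = gen.dirichlet(prior.alpha, n_limit_draws)
    lp = _log_dirichlet_pdf(draws, prior.alpha)
    lp_true = float(_log_dirichlet_pdf(theta_true[None, :], prior.alpha)[0])
    target = float((lp <= lp_true + LOG_TIE_TOL).mean())

    means = []
    for n in n_grid:
        vals = []
        for _ in range(reps):
            t = CellCounts(gen.multinomial(int(n), theta_true))
            model = DirichletPriorPredictive(prior, int(n))
            vals.append(tail_probability(model, t, n_outer=n_outer,
                                         rng=gen).tail_probability)
        means.append(float(np.mean(vals)))
    return {"n": [int(n) for n in n_grid], "mean_tail": means,
            "limit_target": target}
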