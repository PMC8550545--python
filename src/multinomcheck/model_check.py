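"""Relative-belief model checking for constrained multinomials.

The check compares the uniform prior on the full simplex with the
Dirichlet(T+1) posterior it induces given the observed counts T:

* positive-measure region: ``RB = Pi_k(Theta | T) / Pi_k(Theta)``; values
  above 1 are evidence in favor of the constraint, below 1 against; the
  strength of the (binary) evidence is the posterior content itself.
* measure-zero region: the prior and posterior distributions of the KL
  distance ``d(theta)`` are compared on ``[0, delta)``:
  ``RB_d([0, delta) | T)`` estimates the limiting relative belief ratio at
  d = 0, and the strength is the posterior probability of the union of
  distance bins whose own bin-RB does not exceed the first bin's.

Both paths are plain Monte Carlo and every estimate carries its simulation
standard error; verdicts within one MC standard error of RB = 1 are labelled
neutral rather than forced to a side.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import (CellCounts, DirichletSpec, RngLike, ensure_rng,
                   sample_dirichlet, sample_multinomial, spawn_seeds)
from .regions import ConstraintRegion

__all__ = [
    "EvidenceReport",
    "check_positive_measure",
    "check_distance",
    "group_counts",
    "choose_grouping",
    "evidence_error_probabilities",
]


@dataclass
class EvidenceReport:
    """Result of a relative-belief model check."""

    rb: float
    strength: float
    prior_content: float
    posterior_content: float
    verdict: str  # evidence_for / evidence_against / neutral
    delta: float | None = None
    n_prior_draws: int = 0
    n_posterior_draws: int = 0
    mc_se: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def summary(self) -> str:
        lines = [
            f"relative belief ratio : {self.rb:.6g}",
            f"strength              : {self.strength:.4f}",
            f"prior content         : {self.prior_content:.6g}",
            f"posterior content     : {self.posterior_content:.6g}",
            f"verdict               : {self.verdict}",
        ]
        if self.delta is not None:
            lines.insert(0, f"delta                 : {self.delta}")
        return "\n".join(lines)


def _verdict(rb: float, rb_se: float) -> str:
    if not math.isfinite(rb) and rb > 1:
        return "evidence_for"
    if abs(rb - 1.0) <= rb_se:
        return "neutral"
    return "evidence_for" if rb > 1.0 else "evidence_against"


def _proportion_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 0.0) / n) if n > 0 else float("nan")


def check_positive_measure(region: ConstraintRegion, counts: CellCounts,
                           n_draws: int = 100_000,
                           rng: RngLike = None) -> EvidenceReport:
    """Relative belief ratio of a positive-measure region.

    The prior content is the region's closed form when available, otherwise
    Monte Carlo under the uniform Dirichlet(1,...,1); the posterior content
    is always Monte Carlo under Dirichlet(T+1).
    """
    if not region.has_positive_measure:
        raise ValueError(
            f"{region.name} has prior measure zero; use check_distance")
    counts = counts if isinstance(counts, CellCounts) else CellCounts(counts)
    if counts.k != region.k:
        raise ValueError(
            f"counts have {counts.k + 1} cells, region expects {region.k + 1}")
    gen = ensure_rng(rng)

    mc_se: dict[str, float] = {}
    n_prior = 0
    prior_mass = region.analytic_prior_mass
    if prior_mass is None:
        draws = sample_dirichlet(DirichletSpec.uniform(region.k), n_draws, gen)
        prior_mass = float(region.contains_many(draws).mean())
        n_prior = n_draws
        mc_se["prior_content"] = _proportion_se(prior_mass, n_draws)
        if prior_mass == 0.0:
            raise ValueError(
                f"no prior draws landed in {region.name} at n_draws={n_draws}; "
                "the region content is too small for the content path -- use "
                "check_distance instead")
    else:
        mc_se["prior_content"] = 0.0

    post = sample_dirichlet(DirichletSpec(counts.counts + 1), n_draws, gen)
    post_mass = float(region.contains_many(post).mean())
    mc_se["posterior_content"] = _proportion_se(post_mass, n_draws)

    rb = post_mass / prior_mass
    # first-order error propagation for the ratio
    rel = 0.0
    if post_mass > 0:
        rel += (mc_se["posterior_content"] / post_mass) ** 2
    if n_prior and prior_mass > 0:
        rel += (mc_se["prior_content"] / prior_mass) ** 2
    mc_se["rb"] = rb * math.sqrt(rel)

    return EvidenceReport(
        rb=rb, strength=post_mass, prior_content=prior_mass,
        posterior_content=post_mass, verdict=_verdict(rb, mc_se["rb"]),
        n_prior_draws=n_prior, n_posterior_draws=n_draws, mc_se=mc_se,
        settings={"region": region.name, "path": "positive_measure"})


MAX_BINS = 100_000


def _binned_rb(d_prior: np.ndarray, d_post: np.ndarray, delta: float):
    """Bin both distance samples on [0, delta), [delta, 2 delta), ...

    Returns (bin prior fractions, bin posterior fractions).  Bins are
    anchored at 0 with width exactly delta; beyond MAX_BINS the far tail is
    merged into a single final bin (it carries negligible posterior mass and
    its bin-RB enters the strength comparison as one unit).
    """
    top = max(d_prior.max(initial=0.0), d_post.max(initial=0.0))
    n_bins = min(max(int(math.ceil((top + 1e-15) / delta)), 1), MAX_BINS)
    idx_prior = np.minimum((d_prior / delta).astype(np.int64), n_bins - 1)
    idx_post = np.minimum((d_post / delta).astype(np.int64), n_bins - 1)
    p_prior = np.bincount(idx_prior, minlength=n_bins) / d_prior.size
    p_post = np.bincount(idx_post, minlength=n_bins) / d_post.size
    return p_prior, p_post


def check_distance(region: ConstraintRegion, counts: CellCounts, delta: float,
                   n_draws: int = 100_000,
                   rng: RngLike = None) -> EvidenceReport:
    """Distance-based relative belief check for (effectively) measure-zero regions.

    ``delta`` is the practical-equivalence cutoff on the KL distance: values
    of d(theta) below delta count as "the constraint holds to within the
    tolerated relative error in the cell probabilities".
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    counts = counts if isinstance(counts, CellCounts) else CellCounts(counts)
    if counts.k != region.k:
        raise ValueError(
            f"counts have {counts.k + 1} cells, region expects {region.k + 1}")
    gen = ensure_rng(rng)

    prior_draws = sample_dirichlet(DirichletSpec.uniform(region.k), n_draws, gen)
    post_draws = sample_dirichlet(DirichletSpec(counts.counts + 1), n_draws, gen)
    d_prior = region.distance_many(prior_draws)
    d_post = region.distance_many(post_draws)

    p_prior, p_post = _binned_rb(d_prior, d_post, delta)
    if p_prior[0] == 0.0:
        raise ValueError(
            f"no prior draws of d(theta) fell in [0, {delta}); increase "
            "n_draws or delta")
    rb0 = p_post[0] / p_prior[0]

    # strength: posterior content of the bins with bin-RB <= the first bin's
    with np.errstate(divide="ignore", invalid="ignore"):
        bin_rb = p_post / p_prior
    eligible = np.zeros_like(bin_rb, dtype=bool)
    seen = (p_prior > 0) | (p_post > 0)
    eligible[seen & (p_prior > 0)] = bin_rb[seen & (p_prior > 0)] <= rb0
    # empty-prior bins with posterior mass have infinite bin-RB: excluded
    strength = float(p_post[eligible].sum())

    mc_se = {
        "prior_first_bin": _proportion_se(p_prior[0], n_draws),
        "posterior_first_bin": _proportion_se(p_post[0], n_draws),
    }
    rel = 0.0
    if p_post[0] > 0:
        rel += (mc_se["posterior_first_bin"] / p_post[0]) ** 2
    rel += (mc_se["prior_first_bin"] / p_prior[0]) ** 2
    mc_se["rb"] = rb0 * math.sqrt(rel)

    return EvidenceReport(
        rb=float(rb0), strength=strength,
        prior_content=float(p_prior[0]), posterior_content=float(p_post[0]),
        verdict=_verdict(rb0, mc_se["rb"]), delta=delta,
        n_prior_draws=n_draws, n_posterior_draws=n_draws, mc_se=mc_se,
        settings={"region": region.name, "path": "distance"})


def distance_density_plot(region: ConstraintRegion, counts: CellCounts,
                          delta: float, path: str, n_draws: int = 100_000,
                          rng: RngLike = None) -> None:
    """Density histograms of the prior and posterior distance distributions.

    The check itself uses the raw histograms with no smoothing; this plot is
    presentation only.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = counts if isinstance(counts, CellCounts) else CellCounts(counts)
    gen = ensure_rng(rng)
    d_prior = region.distance_many(
        sample_dirichlet(DirichletSpec.uniform(region.k), n_draws, gen))
    d_post = region.distance_many(
        sample_dirichlet(DirichletSpec(counts.counts + 1), n_draws, gen))
    top = max(d_prior.max(), d_post.max())
    edges = np.arange(0.0, top + delta, delta)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(d_prior, bins=edges, density=True, histtype="step",
            linestyle="--", label="prior")
    ax.hist(d_post, bins=edges, density=True, histtype="step",
            label="posterior")
    ax.set_xlabel(r"$d(\theta)$")
    ax.set_ylabel("density")
    ax.set_title(f"{region.name}: prior vs posterior distance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def group_counts(counts: CellCounts, group_size: int) -> CellCounts:
    """Sum consecutive cells left to right; a final short group keeps the rest."""
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    counts = counts if isinstance(counts, CellCounts) else CellCounts(counts)
    c = np.asarray(counts)
    if group_size == 1:
        return CellCounts(c)
    sums = [int(c[i:i + group_size].sum()) for i in range(0, c.size, group_size)]
    return CellCounts(sums)


def choose_grouping(counts: CellCounts, n_draws: int = 10_000,
                    rel_se_max: float = 0.25,
                    rng: RngLike = None) -> int:
    """Pick the number of groups for the ordered-cone check.

    Walks from the finest consecutive grouping (size-1 groups) to coarser
    ones and returns the largest group count m whose grouped posterior
    monotonicity content is estimable at ``n_draws`` draws: a nonzero
    estimate with relative standard error below ``rel_se_max``.  Falls back
    to m = 2 when nothing finer qualifies.
    """
    counts = counts if isinstance(counts, CellCounts) else CellCounts(counts)
    gen = ensure_rng(rng)
    m_cells = counts.k + 1
    seen = set()
    for size in range(1, m_cells):
        grouped = group_counts(counts, size)
        m = grouped.k + 1
        if m < 2 or m in seen:
            continue
        seen.add(m)
        draws = sample_dirichlet(DirichletSpec(grouped.counts + 1), n_draws, gen)
        from .ordered import MONOTONE_TOL  # local import to avoid a cycle
        p = float(np.all(np.diff(draws, axis=1) <= MONOTONE_TOL, axis=1).mean())
        if p > 0 and _proportion_se(p, n_draws) / p <= rel_se_max:
            return m
    return 2


def evidence_error_probabilities(region: ConstraintRegion, n: int,
                                 d0: float, band: float | None = None,
                                 n_sim: int = 200, delta: float = 0.01,
                                 n_draws: int = 10_000,
                                 rng: RngLike = None,
                                 max_tries: int = 2_000_000):
    """Prior error probabilities of the distance check.

    Conditionally on ``d(theta)`` lying in the band ``[d0, d0 + band)``
    (an MC approximation to conditioning on the measure-zero event
    ``d(theta) = d0``), simulate theta from the uniform prior, counts from
    multinomial(n, theta), run the distance check on each count vector and
    report

    * ``p_favor_at_d0``: probability of evidence in favor (RB > 1) given the
      model is off by d0, and
    * ``p_against_at_0``: probability of evidence against (RB < 1) given the
      model holds (d = 0 band).

    Returns a dict with both estimates and their MC standard errors.  The
    default band is delta/2, narrow enough that "d in [0, band)" is a fair
    stand-in for "the model holds".
    """
    if band is None:
        band = delta / 2.0
    if band <= 0:
        raise ValueError("band must be positive")
    gen = ensure_rng(rng)
    child = spawn_seeds(int(gen.integers(2**31)), n_sim)

    def _accept(lo: float) -> np.ndarray:
        out = []
        tries = 0
        while len(out) < n_sim:
            batch = sample_dirichlet(DirichletSpec.uniform(region.k), 4096, gen)
            d = region.distance_many(batch)
            keep = batch[(d >= lo) & (d < lo + band)]
            out.extend(keep)
            tries += 4096
            if tries >= max_tries and not out:
                raise RuntimeError(
                    f"acceptance rate into [{lo}, {lo + band}) is below "
                    f"{n_sim / max_tries:.2e}; widen the band")
        return np.array(out[:n_sim])

    results = {}
    for key, lo, side in (("p_favor_at_d0", d0, "for"),
                          ("p_against_at_0", 0.0, "against")):
        thetas = _accept(lo)
        hits = 0
        for i, theta in enumerate(thetas):
            t = sample_multinomial(theta, n, child[i] if n > 0 else gen)
            rep = check_distance(region, t, delta, n_draws=n_draws, rng=gen)
            if side == "for" and rep.rb > 1:
                hits += 1
            elif side == "against" and rep.rb < 1:
                hits += 1
        p = hits / n_sim
        results[key] = p
        results[key + "_se"] = _proportion_se(p, n_sim)
    results["settings"] = {"n": n, "d0": d0, "band": band, "n_sim": n_sim,
                           "delta": delta, "n_draws": n_draws}
    return results
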