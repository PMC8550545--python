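"""Prior predictive m_T, importance sampling and the conflict tail probability."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist

from multinomcheck import (CellCounts, DirichletPriorPredictive, DirichletSpec,
                           HWEPriorPredictive, OrderedPriorPredictive,
                           TrinePriorPredictive, convex_boundary_mode,
                           dirichlet_log_mT, grouped_conflict_check,
                           hwe_log_mT, ordered_region, stride_group_counts,
                           tail_probability, trine_prior_sampler)
from multinomcheck.prior_check import (TrinePrior, _log_likelihood,
                                       _log_multinomial_coef,
                                       importance_log_mT)
from multinomcheck.regions import TrineGeometry


def _genotype_vectors(n):
    """All (t11, t12, t22) with total n."""
    for t11 in range(n + 1):
        for t12 in range(n + 1 - t11):
            yield (t11, t12, n - t11 - t12)


class TestHWEClosedForm:
    def test_single_draw_uniform_prior_is_thirds(self):
        # n = 1 under a flat beta(1,1): each genotype has mass
        # integral of w^2, 2w(1-w), (1-w)^2 = 1/3 each
        prior = DirichletSpec([1.0, 1.0])
        for t in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
            assert math.exp(hwe_log_mT(t, prior)) == pytest.approx(1 / 3)

    def test_empty_sample_has_mass_one(self):
        assert hwe_log_mT((0, 0, 0), DirichletSpec([2.0, 3.0])) == 0.0

    def test_exact_value_ccr5(self, ccr5):
        # frozen from the closed form; cross-checked below against quadrature
        val = math.exp(hwe_log_mT(ccr5.counts, DirichletSpec([11.35, 25.15])))
        assert val == pytest.approx(7.0776e-6, rel=1e-4)

    def test_matches_numerical_quadrature(self, ccr5):
        t11, t12, t22 = (int(v) for v in ccr5.counts)
        a1, a2 = 11.35, 25.15

        def integrand(w):
            return ((w**2) ** t11 * (2 * w * (1 - w)) ** t12
                    * ((1 - w) ** 2) ** t22 * beta_dist.pdf(w, a1, a2))

        # the integrand peaks near w = 0.1; split the domain for accuracy
        quad = sum(integrate.quad(integrand, lo, hi, limit=200)[0]
                   for lo, hi in [(0, 0.05), (0.05, 0.2), (0.2, 1.0)])
        coef = math.exp(float(
            _log_multinomial_coef(np.array([[t11, t12, t22]], float))[0]))
        assert math.exp(hwe_log_mT(ccr5.counts, DirichletSpec([a1, a2]))) == \
            pytest.approx(coef * quad, rel=1e-6)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    @pytest.mark.parametrize("alpha", [(1.0, 1.0), (11.35, 25.15), (2.0, 0.5)])
    def test_normalization_by_enumeration(self, n, alpha):
        prior = DirichletSpec(alpha)
        total = sum(math.exp(hwe_log_mT(t, prior))
                    for t in _genotype_vectors(n))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_three_allele_normalization(self):
        prior = DirichletSpec([2.0, 1.0, 1.5])
        cells = 6  # genotypes of 3 alleles
        total = 0.0
        for t in itertools.product(range(3), repeat=cells):
            if sum(t) == 2:
                total += math.exp(hwe_log_mT(t, prior))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            hwe_log_mT((1, 2, 3, 4), DirichletSpec([1, 1]))


class TestDirichletClosedForm:
    @pytest.mark.parametrize("n", [1, 3])
    def test_normalization_by_enumeration(self, n):
        prior = DirichletSpec([2.0, 1.0, 0.5])
        total = sum(math.exp(dirichlet_log_mT(t, prior))
                    for t in _genotype_vectors(n))  # same simplex of counts
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_uniform_prior_n1_is_symmetric(self):
        prior = DirichletSpec.uniform(2)
        vals = {math.exp(dirichlet_log_mT(t, prior))
                for t in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]}
        assert all(v == pytest.approx(1 / 3) for v in vals)


class TestTrinePrior:
    def test_every_draw_is_a_member(self):
        geom = TrineGeometry(math.pi / 6)
        draws = trine_prior_sampler(geom, 5_000, rng=1)
        assert np.all(geom.quadratic_form(draws[:, :2]) <= 1.0 + 1e-12)
        assert np.all(draws >= -1e-12) and np.allclose(draws.sum(1), 1.0)

    def test_quadratic_form_mean_is_half(self):
        # Q(theta) = r by construction and r ~ beta(3/2, 3/2) has mean 1/2
        geom = TrineGeometry(math.pi / 6)
        draws = trine_prior_sampler(geom, 200_000, rng=2)
        q = geom.quadratic_form(draws[:, :2])
        assert q.mean() == pytest.approx(0.5, abs=0.005)

    def test_seed_reproducibility(self):
        geom = TrineGeometry(math.pi / 6)
        assert np.array_equal(trine_prior_sampler(geom, 10, rng=3),
                              trine_prior_sampler(geom, 10, rng=3))

    def test_importance_estimate_matches_quadrature(self):
        # independent 2-D grid quadrature of m_T(3,2,1), frozen
        prior = TrinePrior(math.pi / 6)
        est, ess = importance_log_mT([3, 2, 1], prior, n_inner=50_000, rng=4)
        assert est == pytest.approx(-2.8574, abs=0.01)
        assert ess > 1_000

    def test_support_mismatch_warns(self):
        prior = TrinePrior(2 * math.pi / 9)
        # all counts at the third vertex, far outside the thin ellipse
        with pytest.warns(RuntimeWarning, match="support|ESS"):
            val, ess = importance_log_mT([0, 0, 50], prior,
                                         n_inner=500, rng=5)
        assert ess < 5 or val == -math.inf


class TestConvexBoundaryMode:
    def test_in_cone_frequency_returned_unchanged(self):
        cone = ordered_region(3)
        freq = [0.4, 0.3, 0.2, 0.1]
        assert np.allclose(np.asarray(
            convex_boundary_mode([0.25] * 4, freq, cone)), freq)

    def test_mode_equals_freq(self):
        cone = ordered_region(2)
        out = convex_boundary_mode([0.5, 0.3, 0.2], [0.5, 0.3, 0.2], cone)
        assert np.allclose(np.asarray(out), [0.5, 0.3, 0.2])

    def test_non_monotone_pulled_to_boundary(self):
        cone = ordered_region(2)
        out = np.asarray(convex_boundary_mode([1 / 3] * 3, [0.2, 0.5, 0.3],
                                              cone))
        assert cone.contains(out)
        # the entry point has (at least) one active tie
        assert np.min(np.abs(np.diff(out))) < 1e-6

    def test_mode_outside_cone_rejected(self):
        with pytest.raises(ValueError):
            convex_boundary_mode([0.2, 0.5, 0.3], [0.1, 0.2, 0.7],
                                 ordered_region(2))


class TestStrideGrouping:
    def test_fly_pairs(self, fly):
        grouped = stride_group_counts(fly.counts, 9)
        assert list(grouped) == [148, 99, 37, 31, 21, 12, 5, 5, 5]
        assert grouped.n == fly.counts.n

    def test_preserves_monotone_order(self, rng):
        cone18, cone6 = ordered_region(17), ordered_region(5)
        from multinomcheck.ordered import theta_from_omega_many
        thetas = theta_from_omega_many(rng.dirichlet([1.0] * 18, 200))
        from multinomcheck.prior_check import _stride_group_thetas
        grouped = _stride_group_thetas(thetas, 6)
        assert cone6.contains_many(grouped).all()

    def test_bad_group_count(self, fly):
        with pytest.raises(ValueError):
            stride_group_counts(fly.counts, 1)
        with pytest.raises(ValueError):
            stride_group_counts(CellCounts([1, 2]), 5)


class TestTailProbability:
    def test_single_draw_uniform_prior_all_tied(self):
        # n = 1, flat prior: every outcome has m_T = 1/3, so the tail is 1
        model = HWEPriorPredictive(DirichletSpec([1.0, 1.0]), 1)
        rep = tail_probability(model, (0, 1, 0), n_outer=200, rng=6)
        assert rep.tail_probability == 1.0
        assert not rep.conflict

    def test_sample_size_mismatch_rejected(self, ccr5):
        model = HWEPriorPredictive(DirichletSpec([1.0, 1.0]), 100)
        with pytest.raises(ValueError, match="n ="):
            tail_probability(model, ccr5.counts)

    def test_permutation_invariance_by_enumeration(self):
        # relabeling the cells (and the prior alpha consistently) leaves the
        # tail unchanged; enumerate the predictive exactly for small n
        n = 6
        alpha = np.array([2.0, 1.0, 3.5])
        obs = (3, 1, 2)
        perm = [2, 0, 1]

        def exact_tail(alpha, obs):
            prior = DirichletSpec(alpha)
            vals = {t: math.exp(dirichlet_log_mT(t, prior))
                    for t in _genotype_vectors(n)}
            m_obs = vals[tuple(obs)]
            return sum(v for v in vals.values() if v <= m_obs + 1e-15)

        base = exact_tail(alpha, obs)
        permuted = exact_tail(alpha[perm], tuple(np.asarray(obs)[perm]))
        assert base == pytest.approx(permuted, abs=1e-12)

    def test_tail_under_own_predictive_is_roughly_uniform(self):
        # P(tail <= q) ~ q for draws from the model's own predictive
        # (up to discreteness of m_T)
        model = HWEPriorPredictive(DirichletSpec([11.35, 25.15]), 212)
        gen = np.random.default_rng(7)
        thetas = model.sample_theta(400, gen)
        ts = gen.multinomial(212, thetas)
        log_m = model.log_mT_many(ts)
        tails = np.array([(log_m <= v + 1e-12).mean() for v in log_m])
        for q in (0.1, 0.5):
            assert abs((tails <= q).mean() - q) < 0.08

    def test_seed_reproducibility(self, ccr5):
        model = HWEPriorPredictive(DirichletSpec([11.35, 25.15]), 212)
        a = tail_probability(model, ccr5.counts, n_outer=500, rng=8)
        b = tail_probability(model, ccr5.counts, n_outer=500, rng=8)
        assert a.tail_probability == b.tail_probability
        assert a.log_mT_observed == b.log_mT_observed


class TestOrderedPredictive:
    def test_closed_form_agreement_at_uniform_prior(self):
        # with a flat Dirichlet on omega, theta = A omega has a known
        # pushforward; compare the IS estimate against brute-force averaging
        spec = DirichletSpec([1.0, 1.0, 1.0])
        model = OrderedPriorPredictive(spec, 12, n_inner=40_000,
                                       tau_proposal=10.0)
        t = CellCounts([7, 3, 2])
        est = model.log_mT(t, rng=9)
        gen = np.random.default_rng(10)
        thetas = model.sample_theta(400_000, gen)
        ll = _log_likelihood(thetas, np.asarray(t, float))
        brute = float(_log_multinomial_coef(np.asarray(t, float)[None, :])[0]
                      + logsumexp(ll) - math.log(len(thetas)))
        assert est == pytest.approx(brute, abs=0.05)

    def test_empty_sample(self):
        model = OrderedPriorPredictive(DirichletSpec([1.0, 1.0]), 0)
        assert model.log_mT(CellCounts([0, 0])) == 0.0

    def test_grouped_check_reproduces_fly_study(self, fly):
        rep = grouped_conflict_check(fly.counts, l=1 / 450, u=0.5,
                                     epsilon=0.0, m=9, tau=2.85,
                                     n_outer=400, n_inner=5_000, rng=11)
        assert rep.tail_probability == pytest.approx(0.41, abs=0.1)
        assert rep.settings["p_in_cone"] == pytest.approx(0.04, abs=0.03)
        assert not rep.conflict

    def test_grouped_check_detects_order_violation(self, fly):
        shuffled = CellCounts([35, 29, 20, 145, 96, 11, 4, 4, 4, 3, 3, 2, 2,
                               1, 1, 1, 1, 1])
        rep = grouped_conflict_check(shuffled, l=1 / 450, u=0.5,
                                     epsilon=0.0, m=9, tau=2.85,
                                     n_outer=300, n_inner=5_000, rng=12)
        assert rep.tail_probability <= 0.02
        assert rep.conflict


class TestConvergenceExperiment:
    def test_limits_at_mode_and_tail(self):
        from multinomcheck import conflict_convergence_experiment
        prior = DirichletSpec([2.0, 2.0])
        # theta_true at the prior mode: the limit target is ~1
        res = conflict_convergence_experiment(
            prior, [0.5, 0.5], n_grid=[200], reps=3, n_outer=300,
            n_limit_draws=20_000, rng=13)
        assert res["limit_target"] > 0.95
        # theta_true in the extreme tail: the limit target is ~0
        res2 = conflict_convergence_experiment(
            prior, [0.995, 0.005], n_grid=[200], reps=3, n_outer=300,
            n_limit_draws=20_000, rng=14)
        assert res2["limit_target"] < 0.05
        assert np.mean(res2["mean_tail"]) < 0.1
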