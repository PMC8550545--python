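"""Constraint regions: membership, KL distance and prior content."""

import math

import numpy as np
import pytest

from multinomcheck import (hwe_region, kl_divergence, ordered_region,
                           quantum_region, region_from_config, trine_region,
                           zm_region)
from multinomcheck.ordered import theta_from_omega_many, zm_pmf
from multinomcheck.regions import hwe_allele_frequencies, hwe_theta_from_omega


class TestTrine:
    def test_symmetric_geometry_and_mass(self):
        reg = trine_region(math.pi / 6)
        assert reg.geometry.a == pytest.approx(1 / 3, abs=1e-12)
        assert reg.analytic_prior_mass == pytest.approx(0.6046, abs=5e-5)

    def test_asymmetric_geometry_and_mass(self):
        reg = trine_region(2 * math.pi / 9)
        assert reg.geometry.a == pytest.approx(0.48445, abs=5e-6)
        assert reg.analytic_prior_mass == pytest.approx(0.2684, abs=5e-5)

    def test_center_is_member(self):
        # the ellipse center c maps to theta = (1/3, 1/3, 1/3) when a = 1/3
        reg = trine_region(math.pi / 6)
        assert reg.contains([1 / 3, 1 / 3, 1 / 3])
        assert reg.distance([1 / 3, 1 / 3, 1 / 3]) == 0.0

    @pytest.mark.parametrize("phi0,mass", [(math.pi / 6, 0.6046),
                                           (2 * math.pi / 9, 0.2684)])
    def test_analytic_mass_matches_monte_carlo(self, phi0, mass, rng):
        reg = trine_region(phi0)
        n = 400_000
        draws = rng.dirichlet([1, 1, 1], n)
        p = reg.contains_many(draws).mean()
        se = math.sqrt(mass * (1 - mass) / n)
        assert abs(p - mass) < 3.5 * se

    def test_distance_positive_outside(self):
        reg = trine_region(math.pi / 6)
        theta = [0.9, 0.05, 0.05]
        assert not reg.contains(theta)
        assert reg.distance(theta) > 0.01

    def test_inadmissible_angle_rejected(self):
        with pytest.raises(ValueError):
            trine_region(0.05)  # cot(2 phi0) > 1


class TestQuantumRegions:
    def test_uniform_point_memberships(self):
        quarter = [0.25] * 4
        assert quantum_region("tetrahedron").contains(quarter)
        cross = quantum_region("cross_hairs")
        assert cross.contains(quarter)
        assert cross.distance(quarter) == 0.0
        assert quantum_region("pauli").contains([1 / 6] * 6)

    def test_vertex_outside_tetrahedron(self):
        tet = quantum_region("tetrahedron")
        vertex = [1.0, 0.0, 0.0, 0.0]
        assert not tet.contains(vertex)
        assert tet.distance(vertex) > 0.0

    def test_cross_hairs_equality_violated(self):
        cross = quantum_region("cross_hairs")
        assert not cross.contains([0.4, 0.2, 0.2, 0.2])  # pair sums not 1/2

    def test_cross_hairs_distance_respects_slice(self):
        # the projection of a point onto the slice stays on the slice, so the
        # distance is at least the KL to the best *unconstrained* pair-split
        cross = quantum_region("cross_hairs")
        theta = [0.55, 0.15, 0.15, 0.15]
        d = cross.distance(theta)
        assert d > 0.0
        # distance to the member (0.35, 0.15, 0.15, 0.35) bounds it above
        ref = kl_divergence(theta, [0.35, 0.15, 0.15, 0.35])
        assert d <= ref + 1e-8

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown"):
            quantum_region("octahedron")


class TestHWE:
    def test_on_curve_distance_zero(self):
        reg = hwe_region(2)
        for w in (0.5, 0.1, 0.73):
            theta = [w**2, 2 * w * (1 - w), (1 - w) ** 2]
            assert reg.distance(theta) <= 1e-12
            assert reg.contains(theta)

    def test_no_heterozygotes_worked_example(self):
        # theta = (1/2, 0, 1/2): minimizer omega = 1/2, distance = ln 2
        reg = hwe_region(2)
        assert reg.distance([0.5, 0.0, 0.5]) == pytest.approx(math.log(2))

    def test_plugin_matches_grid_minimizer(self, rng):
        # closed-form minimizer vs brute-force 1-D grid over omega
        reg = hwe_region(2)
        grid = np.linspace(1e-6, 1 - 1e-6, 20_001)
        hwe_grid = np.stack([grid**2, 2 * grid * (1 - grid), (1 - grid) ** 2], 1)
        for theta in rng.dirichlet([1, 1, 1], 100):
            with np.errstate(divide="ignore", invalid="ignore"):
                kl = np.where(theta[None, :] > 0,
                              theta[None, :] * np.log(theta[None, :] / hwe_grid),
                              0.0).sum(1)
            assert reg.distance(theta) <= kl.min() + 1e-6

    def test_plugin_matches_numeric_minimizer_three_alleles(self, rng):
        reg = hwe_region(3)
        for theta in rng.dirichlet([1] * 6, 10):
            assert reg.distance(theta) <= reg.distance_numeric(theta) + 1e-8

    def test_three_allele_surface(self):
        w = np.array([0.5, 0.3, 0.2])
        theta = hwe_theta_from_omega(w)
        assert theta.sum() == pytest.approx(1.0)
        reg = hwe_region(3)
        assert reg.distance(theta) <= 1e-12
        assert np.allclose(hwe_allele_frequencies(theta[None, :], 3)[0], w)

    def test_dimension_check(self):
        with pytest.raises(ValueError):
            hwe_region(2).distance([0.2, 0.3, 0.3, 0.2])


class TestOrdered:
    @pytest.mark.parametrize("k,mass", [(17, 1.5619e-16), (8, 2.7557e-6)])
    def test_analytic_mass(self, k, mass):
        assert ordered_region(k).analytic_prior_mass == pytest.approx(
            mass, rel=1e-4)

    def test_uniform_theta_is_member(self):
        reg = ordered_region(3)
        assert reg.contains([0.25] * 4)  # ties allowed
        assert reg.distance([0.25] * 4) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_mass_matches_monte_carlo_small_k(self, k, rng):
        reg = ordered_region(k)
        n = 100_000
        p = reg.contains_many(rng.dirichlet([1.0] * (k + 1), n)).mean()
        se = math.sqrt(reg.analytic_prior_mass * (1 - reg.analytic_prior_mass) / n)
        assert abs(p - reg.analytic_prior_mass) < 4 * se

    def test_pava_projection_matches_slsqp(self, rng):
        from scipy.optimize import minimize
        reg = ordered_region(3)
        for theta in rng.dirichlet([1, 1, 1, 1], 5):
            if reg.contains(theta):
                continue
            d_pava = reg.distance(theta)

            def objective(q):
                if np.any(q <= 0):
                    return np.inf
                return float(np.sum(theta * np.log(theta / q)))

            cons = [{"type": "eq", "fun": lambda q: q.sum() - 1.0}] + [
                {"type": "ineq", "fun": lambda q, i=i: q[i] - q[i + 1]}
                for i in range(3)]
            res = minimize(objective, np.full(4, 0.25), method="SLSQP",
                           constraints=cons, bounds=[(1e-9, 1)] * 4,
                           options={"maxiter": 500, "ftol": 1e-14})
            assert d_pava == pytest.approx(res.fun, abs=1e-7)

    def test_membership_implies_zero_distance(self, rng):
        reg = ordered_region(4)
        draws = np.sort(rng.dirichlet([1] * 5, 50), axis=1)[:, ::-1]
        for theta in draws:
            assert reg.distance(theta) <= 1e-10


@pytest.fixture(scope="module")
def reg():
    return zm_region(5, beta_max=3.0, beta_step=0.05, n_alpha=20)


class TestZipfMandelbrotRegion:

    def test_table_member_has_zero_distance(self, reg):
        beta = reg.betas[len(reg.betas) // 2]
        alpha = reg.alphas[len(reg.alphas) // 2]
        theta = np.asarray(zm_pmf(5, alpha=alpha, beta=beta))
        assert reg.distance(theta) <= 1e-12

    def test_uniform_has_zero_distance(self, reg):
        # beta = 0 is the uniform member
        assert reg.distance([1 / 6] * 6) <= 1e-12

    def test_dominates_ordered_cone_distance(self, reg, rng):
        # ZM family is a subset of the cone, so its distance is never smaller
        cone = ordered_region(5)
        for theta in rng.dirichlet([1] * 6, 25):
            assert reg.distance(theta) >= cone.distance(theta) - 1e-9

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            zm_region(3, beta_max=-1.0)


def test_region_from_config_dispatch():
    assert region_from_config({"region": "trine", "phi0": 0.5235987756}).k == 2
    assert region_from_config({"region": "hwe", "l": 3}).k == 5
    assert region_from_config({"region": "ordered", "k": 4}).k == 4
    assert region_from_config({"region": "pauli"}).k == 5
    with pytest.raises(ValueError):
        region_from_config({"region": "bogus"})
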