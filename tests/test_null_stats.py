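"""Tests for the analytic null distributions of z and s, against MC oracles."""

import math

import numpy as np
import pytest
from scipy import integrate

from netsym.null_stats import (
    M2_Z_UNIFORM,
    MU_Z_UNIFORM,
    ConfigurationError,
    NullModelSpec,
    correlation_uv,
    mc_null_statistics,
    moments_s,
    moments_z,
    null_densities,
    sample_weights,
)

P_GRID = [0.0, 0.1, 0.3, 0.5, 0.7, 0.9]


class TestSpecValidation:
    def test_rejects_full_pruning(self):
        with pytest.raises(ConfigurationError):
            NullModelSpec(prune_p=1.0)

    def test_rejects_wide_gaussian(self):
        # sigma = 0.2 leaves ~1.2% of the mass outside [0, 1]
        with pytest.raises(ConfigurationError, match="narrow"):
            NullModelSpec(family="gaussian", sigma=0.2)

    def test_rejects_off_centre_gaussian(self):
        with pytest.raises(ConfigurationError, match="centre"):
            NullModelSpec(family="gaussian", mu=0.3)


class TestDensities:
    @pytest.mark.parametrize("family", ["uniform", "gaussian"])
    @pytest.mark.parametrize("p", [0.0, 0.3, 0.7])
    def test_marginals_integrate_to_mixture_weights(self, family, p):
        spec = NullModelSpec(family=family, prune_p=p)
        b = null_densities(spec)
        lo, hi = b.u_support
        mass_u, _ = integrate.quad(b.pdf_u, lo - 0.5, hi + 0.5, limit=200)
        mass_v, _ = integrate.quad(
            b.pdf_v, 0.0, b.v_support[1] + 0.5, limit=200
        )
        # continuous u/v parts include the one-alive component, so each
        # marginal integrates to 1 (the (0,0) atom is excluded by design)
        assert mass_u == pytest.approx(1.0, abs=1e-6)
        assert mass_v == pytest.approx(1.0, abs=1e-6)
        w_cont, _ = integrate.quad(b.pdf_w, lo / 2 - 0.5, hi / 2 + 0.5, limit=200)
        assert w_cont + b.w_atom == pytest.approx(1.0, abs=1e-6)
        assert b.weight_continuous + b.weight_line == pytest.approx(1.0)

    def test_uniform_unpruned_v_density_is_2_1mv(self):
        b = null_densities(NullModelSpec())
        v = np.linspace(0.01, 0.99, 7)
        assert b.pdf_v(v) == pytest.approx(2 * (1 - v))

    def test_uniform_unpruned_u_density_is_triangular(self):
        b = null_densities(NullModelSpec())
        assert b.pdf_u(np.array([0.5, 1.0, 1.5])) == pytest.approx([0.5, 1.0, 0.5])

    def test_uniform_joint_integrates_to_continuous_weight(self):
        # midpoint grid sum (the density is piecewise constant with a
        # triangular support edge, which defeats adaptive quadrature)
        spec = NullModelSpec(prune_p=0.4)
        b = null_densities(spec)
        h = 1 / 1000
        u = np.arange(h / 2, 2, h)
        v = np.arange(h / 2, 1, h)
        U, V = np.meshgrid(u, v)
        mass = float(np.sum(b.pdf_joint(U, V))) * h * h
        assert mass == pytest.approx(b.weight_continuous, abs=5e-3)

    def test_v_histogram_matches_density(self):
        # MC oracle: 1e6 uniform pairs vs the closed-form 2(1-v)
        rng = np.random.default_rng(42)
        a, bb = rng.uniform(0, 1, (2, 10**6))
        v = np.abs(a - bb)
        hist, edges = np.histogram(v, bins=20, range=(0, 1), density=True)
        mid = (edges[:-1] + edges[1:]) / 2
        assert hist == pytest.approx(2 * (1 - mid), abs=0.02)

    def test_pruning_weight_vanishes_as_p_to_zero(self):
        b = null_densities(NullModelSpec(prune_p=1e-9))
        assert b.weight_line == pytest.approx(0.0, abs=1e-8)


class TestMomentsZ:
    def test_uniform_closed_forms(self):
        mu, var = moments_z(NullModelSpec())
        assert mu == pytest.approx(2 * math.log(2) - 1, abs=1e-15)
        assert var == pytest.approx(
            (3 - 4 * math.log(2)) - (2 * math.log(2) - 1) ** 2, abs=1e-15
        )

    def test_uniform_closed_form_vs_mc_oracle(self):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(0, 1, (2, 10**6))
        z = np.abs(a - b) / (a + b)
        se = z.std() / 1000
        assert abs(z.mean() - MU_Z_UNIFORM) < 3 * se
        se2 = (z**2).std() / 1000
        assert abs((z**2).mean() - M2_Z_UNIFORM) < 3 * se2

    def test_mixture_identity_at_half_pruning(self):
        mu, _ = moments_z(NullModelSpec(prune_p=0.5))
        expected = (MU_Z_UNIFORM / 3) + 2 / 3
        assert mu == pytest.approx(expected, abs=1e-15)
        assert mu == pytest.approx(0.795431, abs=1e-6)

    def test_mixture_identity_vs_mc(self):
        # sample pruned pairs directly, conditioned on at least one alive
        rng = np.random.default_rng(3)
        p = 0.4
        n = 10**6
        a, b = rng.uniform(0, 1, (2, n))
        alive_a = rng.random(n) >= p
        alive_b = rng.random(n) >= p
        a = np.where(alive_a, a, 0.0)
        b = np.where(alive_b, b, 0.0)
        keep = (a + b) > 0
        z = np.abs(a - b)[keep] / (a + b)[keep]
        mu, _ = moments_z(NullModelSpec(prune_p=p))
        se = z.std() / math.sqrt(z.size)
        assert abs(z.mean() - mu) < 3 * se

    def test_gaussian_quadrature_vs_mc_oracle(self, gaussian_spec):
        mu, var = moments_z(gaussian_spec)
        # regression pin from the 1e6-pair MC oracle (mean 0.11521, se ~9e-5)
        assert mu == pytest.approx(0.11521, abs=4e-4)
        rng = np.random.default_rng(12)
        a = sample_weights(gaussian_spec, 10**6, rng)
        b = sample_weights(gaussian_spec, 10**6, rng)
        z = np.abs(a - b) / (a + b)
        assert abs(z.mean() - mu) < 3 * z.std() / 1000
        assert var == pytest.approx(z.var(), rel=0.01)

    def test_gaussian_half_normal_approximation(self, gaussian_spec):
        # cross-check: E[z] ~ E[v] E[1/u] with v half-normal, u ~ N(1, 2s^2)
        mu, _ = moments_z(gaussian_spec)
        sigma = gaussian_spec.sigma
        approx = 2 * sigma / math.sqrt(math.pi) * (1 + 2 * sigma**2)
        assert mu == pytest.approx(approx, rel=0.02)


class TestMomentsS:
    def test_uniform_n30_reference_values(self, uniform_spec):
        ns = moments_s(uniform_spec, 30)
        assert ns.mu_s == pytest.approx(2 - 2 * math.log(2), abs=1e-15)
        assert ns.expected_counted_pairs == 435
        assert ns.sigma_s == pytest.approx(0.013407, abs=1e-6)

    def test_var_s_is_var_z_over_expected_pairs(self):
        for p in (0.0, 0.5):
            spec = NullModelSpec(prune_p=p)
            ns = moments_s(spec, 30)
            assert ns.var_s == pytest.approx(
                ns.var_z / ns.expected_counted_pairs, abs=1e-12
            )
            assert ns.mu_s == pytest.approx(1 - ns.mu_z, abs=1e-15)

    def test_pruned_expected_pairs(self):
        ns = moments_s(NullModelSpec(prune_p=0.5), 30)
        assert ns.expected_counted_pairs == pytest.approx(0.75 * 435)
        assert ns.mu_s == pytest.approx(0.204569, abs=1e-6)

    def test_var_s_decreases_with_n(self, uniform_spec):
        variances = [moments_s(uniform_spec, n).var_s for n in (5, 10, 30, 100)]
        assert all(a > b for a, b in zip(variances, variances[1:]))

    @pytest.mark.parametrize("family", ["uniform", "gaussian"])
    def test_analytic_vs_mc_across_pruning_grid(self, family):
        seeds = np.random.SeedSequence(2024).generate_state(len(P_GRID))
        for p, seed in zip(P_GRID, seeds):
            spec = NullModelSpec(family=family, prune_p=p)
            ana = moments_s(spec, 30)
            mc = mc_null_statistics(spec, 30, 2000, seed=int(seed % 2**31))
            se = math.sqrt(mc.var_s / mc.n_networks)
            assert abs(ana.mu_s - mc.mu_s) < 3 * se, (family, p)

    def test_pruning_biases_towards_asymmetry(self):
        # mu_s(p) strictly decreasing for both families
        for family in ("uniform", "gaussian"):
            mus = [
                moments_s(NullModelSpec(family=family, prune_p=p), 30).mu_s
                for p in P_GRID
            ]
            assert all(a > b for a, b in zip(mus, mus[1:])), family

    def test_gaussian_biases_towards_symmetry(self):
        # gaussian mu_s above uniform mu_s at every pruning level
        for p in P_GRID:
            g = moments_s(NullModelSpec(family="gaussian", prune_p=p), 30).mu_s
            u = moments_s(NullModelSpec(family="uniform", prune_p=p), 30).mu_s
            assert g > u, p


class TestMonteCarlo:
    def test_same_seed_is_bitwise_identical(self, uniform_spec):
        a = mc_null_statistics(uniform_spec, 10, 50, seed=5)
        b = mc_null_statistics(uniform_spec, 10, 50, seed=5)
        assert a == b

    def test_rejects_tiny_sample(self, uniform_spec):
        with pytest.raises(ConfigurationError):
            mc_null_statistics(uniform_spec, 10, 1, seed=0)

    def test_truncated_gaussian_sampler_respects_bounds(self, gaussian_spec):
        rng = np.random.default_rng(0)
        w = sample_weights(gaussian_spec, 10**5, rng)
        assert w.min() >= 0.0 and w.max() <= 1.0
        assert w.mean() == pytest.approx(0.5, abs=0.002)
        assert w.std() == pytest.approx(0.1, abs=0.002)


class TestCorrelationUV:
    def test_gaussian_u_v_uncorrelated(self, gaussian_spec):
        assert abs(correlation_uv(gaussian_spec, 10**6, seed=7)) < 0.01

    def test_uniform_u_v_uncorrelated(self, uniform_spec):
        # cov(u, v) = E|a^2-b^2| - E[u]E[v] = 1/3 - 1/3 = 0 exactly
        assert abs(correlation_uv(uniform_spec, 10**6, seed=7)) < 0.01

    def test_requires_unpruned_spec(self):
        with pytest.raises(ConfigurationError):
            correlation_uv(NullModelSpec(prune_p=0.2), 1000, seed=0)

    def test_rejects_single_sample(self, uniform_spec):
        with pytest.raises(ConfigurationError):
            correlation_uv(uniform_spec, 1, seed=0)
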