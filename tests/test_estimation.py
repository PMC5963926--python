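import math

import numpy as np
import pytest
from scipy.stats import norm

from scobserver import (
    Category,
    Grid,
    ObserverModel,
    ObserverParams,
    bias_curve,
    conditional_measurement_density,
    conditioned_posterior,
    estimate,
    estimate_distribution,
    estimate_distribution_boundary_variants,
    motor_convolve,
)
from scobserver.estimation import EstimateDensity


class TestConditionalMeasurementDensity:
    def test_partition_identity(self, params, grid):
        # mass-weighted sum over choices reconstructs the full Gaussian
        for theta in (0.0, 2.0, 6.0, -9.0):
            for lvl in range(3):
                qcw, _ = conditional_measurement_density(theta, "cw", params, lvl, grid)
                qccw, _ = conditional_measurement_density(theta, "ccw", params, lvl, grid)
                st = params.sigma_total(lvl)
                full = norm.pdf(grid.values, theta, st)
                assert np.max(np.abs(qcw + qccw - full)) < 1e-3

    def test_zero_memory_noise_is_truncated_gaussian(self, params, grid):
        p = params.replace(sigma_m=0.0)
        q, _ = conditional_measurement_density(4.0, "cw", p, 1, grid)
        expected = norm.pdf(grid.values, 4.0, p.sigma_s[1]) * (grid.values >= 0)
        assert np.max(np.abs(q - expected)) < 1e-12

    def test_mirror_symmetry_at_zero(self, params, grid):
        qcw, wcw = conditional_measurement_density(0.0, "cw", params, 1, grid)
        qccw, wccw = conditional_measurement_density(0.0, "ccw", params, 1, grid)
        assert np.allclose(qcw, qccw[::-1])
        assert wcw == pytest.approx(wccw, rel=1e-9)

    def test_mass_equals_choice_probability(self, params, grid, model):
        for theta in (3.0, -6.0):
            _, mass = conditional_measurement_density(theta, "cw", params, 2, grid)
            assert mass == pytest.approx(model.choice_probability(theta, 2), abs=1e-6)

    def test_closed_form_matches_quadrature_oracle(self, params, grid):
        q1, m1 = conditional_measurement_density(6.0, "cw", params, 1, grid, method="closed")
        q2, m2 = conditional_measurement_density(6.0, "cw", params, 1, grid, method="quadrature")
        assert np.max(np.abs(q1 - q2)) < 1e-4
        assert m1 == pytest.approx(m2, abs=1e-4)


class TestConditionedPosterior:
    def test_zero_mass_on_inconsistent_side(self, params, grid):
        post = conditioned_posterior(3.0, "cw", params, 1, grid)
        assert np.all(post[grid.values < 0] == 0.0)
        assert abs(grid.integrate(post) - 1.0) < 1e-9

    def test_reduces_to_truncated_gaussian(self, grid):
        # sigma_m = 0, flat wide prior: the theta-likelihood at fixed mm = m
        # keeps its Gaussian shape; only the prior support truncates it
        p = ObserverParams(sigma_s=(5.0,), sigma_m=0.0, alpha=70.0, beta=0.0)
        mm = 4.0
        post = conditioned_posterior(mm, "cw", p, 0, grid)
        ref = norm.pdf(grid.values, mm, 5.0) * ((grid.values > 0) & (grid.values <= 70.0))
        ref /= ref.sum() * grid.step
        assert np.max(np.abs(post - ref)) < 1e-6

    def test_grid_misconfiguration_raises(self, grid):
        p = ObserverParams(sigma_s=(0.5,), sigma_m=0.0, alpha=5.0, beta=0.0)
        with pytest.raises(ValueError):
            conditioned_posterior(-70.0, "cw", p, 0, grid)


class TestEstimate:
    def test_noiseless_limit_returns_stimulus(self, grid):
        p = ObserverParams(sigma_s=(0.05,), sigma_m=0.0, alpha=25.0, beta=6.0)
        assert estimate(8.0, "cw", p, 0, grid) == pytest.approx(8.0, abs=0.1)

    def test_half_normal_mean_closed_form(self, grid):
        # sigma_m=0, wide uniform prior, mm=0, cw: mean of half-normal
        p = ObserverParams(sigma_s=(5.0,), sigma_m=0.0, alpha=100.0, beta=0.0)
        got = estimate(0.0, "cw", p, 0, grid)
        assert got == pytest.approx(5.0 * math.sqrt(2 / math.pi), abs=0.05)

    def test_general_case_against_fine_grid_oracle(self):
        # independent quadrature at 10x resolution
        p = ObserverParams(sigma_s=(5.0,), sigma_m=3.0, alpha=25.0, beta=6.0)
        coarse = estimate(4.0, "cw", p, 0, Grid(80.0, 0.2))
        fine = estimate(4.0, "cw", p, 0, Grid(80.0, 0.02))
        assert coarse == pytest.approx(fine, abs=0.05)

    def test_sign_consistent_and_monotone_in_mm(self, model):
        mapping = model.estimate_mapping(1, "cw", "self_consistent")
        assert np.all(np.diff(mapping) >= 0)
        assert np.all(mapping > 0)

    def test_mapping_cache_hits_are_identical(self, params, grid):
        m1 = ObserverModel(params, grid)
        a = m1.estimate_mapping(0, "cw", "self_consistent")
        b = m1.estimate_mapping(0, "cw", "self_consistent")
        assert a is b
        fresh = ObserverModel(params, grid).estimate_mapping(0, "cw", "self_consistent")
        assert np.array_equal(a, fresh)


class TestEstimateDistribution:
    def test_self_consistent_bimodal_with_gap(self, model, grid):
        dens = model.distribution(0.0, 1, "self_consistent")
        mix = dens.mixture
        assert np.all(mix[np.abs(grid.values) < 1.0] == 0.0)
        assert mix.max() > 0
        # conditional supports are disjoint half-lines
        assert np.all(dens.p_cw[grid.values < 0] == 0.0)
        assert np.all(dens.p_ccw[grid.values > 0] == 0.0)

    def test_independent_unimodal_symmetric(self, model, grid):
        mix = model.distribution(0.0, 1, "independent").mixture
        assert np.allclose(mix, mix[::-1], atol=1e-9)
        peaks = np.flatnonzero((mix[1:-1] > mix[:-2]) & (mix[1:-1] >= mix[2:])) + 1
        inner = peaks[(grid.values[peaks] > -30) & (grid.values[peaks] < 30)]
        assert len(inner) <= 2  # one plateau around zero, no gap

    def test_conditionals_normalized(self, model, grid):
        dens = model.distribution(6.0, 1, "self_consistent")
        assert grid.integrate(dens.p_cw) == pytest.approx(1.0, abs=1e-6)
        assert grid.integrate(dens.p_ccw) == pytest.approx(1.0, abs=1e-6)
        assert dens.weight_cw + dens.weight_ccw == pytest.approx(1.0, abs=1e-9)

    def test_matches_monte_carlo_chain(self, params, model, grid, rng):
        # total variation against simulating the full generative chain
        theta, lvl, n = 6.0, 1, 200_000
        m = theta + params.sigma_s[lvl] * rng.standard_normal(n)
        mm = m + params.sigma_m * rng.standard_normal(n)
        cw = m >= 0
        est = np.where(
            cw,
            np.interp(mm, grid.values, model.estimate_mapping(lvl, "cw", "self_consistent")),
            np.interp(mm, grid.values, model.estimate_mapping(lvl, "ccw", "self_consistent")),
        )
        emp, _ = np.histogram(est, bins=grid.edges)
        emp = emp / n / grid.step
        mix = model.distribution(theta, lvl, "self_consistent").mixture
        tv = 0.5 * np.sum(np.abs(emp - mix)) * grid.step
        assert tv < 0.02

    def test_known_category_conditions_on_truth(self, model, grid):
        dens = model.distribution(6.0, 1, "known_category")
        assert dens.weight_cw == 1.0 and dens.weight_ccw == 0.0
        assert np.all(dens.p_cw[grid.values < 0] == 0.0)
        # wrong-cue conditional exists and concentrates on the other side
        assert grid.integrate(dens.p_ccw) == pytest.approx(1.0, abs=1e-6)
        assert np.all(dens.p_ccw[grid.values > 0] == 0.0)

    def test_unknown_variant_rejected(self, model):
        with pytest.raises(ValueError):
            model.distribution(0.0, 0, "telepathic")


class TestBoundaryVariants:
    def test_degenerate_equals_self_consistent(self, model):
        base = model.distribution(3.0, 1, "self_consistent")
        var = model.boundary_variant_distribution(3.0, 1, sigma_b=0.0, shift=0.0)
        assert np.array_equal(base.mixture, var.mixture)

    def test_boundary_noise_fills_the_gap(self, model, grid):
        base = model.distribution(0.0, 1, "self_consistent").mixture
        noisy = model.boundary_variant_distribution(0.0, 1, sigma_b=10.0).mixture
        centre = np.abs(grid.values) < 1.0
        assert base[centre].max() == 0.0
        assert noisy[centre].max() > 0.0
        assert abs(grid.integrate(noisy) - 1.0) < 1e-6

    def test_shift_translates_gap_to_shift(self, params, model, grid):
        # shifting the boundary while the stimulus stays put is a frame
        # translation: density(theta=0 | shift=6) = density(theta=-6) moved
        # +6 degrees, so the estimate gap sits at the shifted boundary
        shifted = model.boundary_variant_distribution(0.0, 1, shift=6.0).mixture
        base = model.distribution(-6.0, 1, "self_consistent").mixture
        k = int(round(6.0 / grid.step))
        translated = np.concatenate([np.zeros(k), base[:-k]])
        assert np.max(np.abs(shifted - translated)) < 1e-6
        # density vanishes in a neighborhood of the shifted boundary
        assert shifted[np.abs(grid.values - 6.0) < 0.5].max() == pytest.approx(0.0, abs=1e-12)

    def test_invalid_sigma_b(self, model):
        with pytest.raises(ValueError):
            model.boundary_variant_distribution(0.0, 0, sigma_b=-1.0)


class TestMotorConvolve:
    def test_zero_noise_is_identity_with_flag(self, model):
        dens = model.distribution(3.0, 0, "self_consistent")
        out = motor_convolve(dens, 0.0)
        assert np.array_equal(out.p_cw, dens.p_cw)
        assert out.motor_convolved

    def test_delta_becomes_gaussian(self, grid):
        delta = np.zeros(grid.n)
        centre = grid.values[np.argmin(np.abs(grid.values - 3.0))]
        delta[np.argmin(np.abs(grid.values - 3.0))] = 1.0 / grid.step
        ed = EstimateDensity(3.0, 0, grid, delta, np.zeros(grid.n), 1.0, 0.0, "self_consistent")
        out = motor_convolve(ed, 4.3)
        target = norm.pdf(grid.values, centre, 4.3)
        assert np.max(np.abs(out.p_cw - target)) < 1e-4

    def test_crossing_mass_tail_identity(self, model, grid):
        # mass below 0 after convolution equals the Gaussian-tail integral
        dens = model.distribution(3.0, 1, "self_consistent")
        sigma_0 = 4.3
        out = motor_convolve(dens, sigma_0)
        got = out.p_cw[grid.values < 0].sum() * grid.step
        expected = np.sum(dens.p_cw * norm.cdf(-grid.values / sigma_0)) * grid.step
        assert got == pytest.approx(expected, abs=1e-3)

    def test_double_convolution_refused(self, model):
        dens = motor_convolve(model.distribution(3.0, 0, "self_consistent"), 2.0)
        with pytest.raises(ValueError):
            motor_convolve(dens, 2.0)


class TestBiasCurve:
    def test_repulsive_near_boundary_all_levels(self, params, model):
        for lvl in range(3):
            th, b = bias_curve(params, lvl, "self_consistent", model=model)
            near = b[th <= 6.0]
            assert np.all(near > 0)

    def test_magnitude_nondecreasing_in_sensory_noise(self, params, model):
        vals = []
        for lvl in range(3):
            th, b = bias_curve(params, lvl, "self_consistent", model=model)
            vals.append(b[th == 3.0][0])
        assert vals[0] <= vals[1] <= vals[2]

    def test_independent_unbiased_inside_core(self, params, model):
        th, b = bias_curve(
            params, 0, "independent", correct_only=False, theta_values=[0.0, 3.0, 6.0], model=model
        )
        assert np.max(np.abs(b)) < 0.05

    def test_known_category_bias_not_larger_near_boundary(self, params, model):
        th, bk = bias_curve(params, 1, "known_category", theta_values=[0.0, 3.0, 6.0], model=model)
        _, bs = bias_curve(params, 1, "self_consistent", theta_values=[0.0, 3.0, 6.0], model=model)
        assert np.all(bk <= bs + 1e-9)

    def test_crossover_moves_boundaryward_with_narrower_prior(self, params):
        thetas = np.arange(0.0, 45.1, 1.5)

        def crossover(p):
            _, b = bias_curve(p, 1, "self_consistent", theta_values=thetas)
            neg = np.flatnonzero(b < 0)
            return thetas[neg[0]] if len(neg) else np.inf

        wide = crossover(params)  # wp = 33
        narrow = crossover(params.replace(alpha=15.0, beta=6.0))  # wp = 19
        assert narrow < wide
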