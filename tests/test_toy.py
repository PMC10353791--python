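"""Toy model: samplers, analytic oracle, copula, nonlinear orders."""

import numpy as np
import pytest
from scipy import stats

from condpop import toy


class TestIndependentSampler:
    def test_support_and_mean(self):
        m = toy.sample_independent(toy.ToyConfig(n_vars=4, n_samples=100_000, rng_seed=1))
        assert m.shape == (100_000, 4)
        assert m.min() >= 0.0 and m.max() <= 2.0
        se = 2 / np.sqrt(12) / np.sqrt(100_000)
        assert np.all(np.abs(m.mean(axis=0) - 1.0) < 3 * se)

    def test_seeded_determinism(self):
        cfg = toy.ToyConfig(n_vars=3, n_samples=100, rng_seed=9)
        assert np.array_equal(toy.sample_independent(cfg), toy.sample_independent(cfg))


class TestValidFraction:
    def test_vacuous_tolerance(self):
        m = np.random.default_rng(0).uniform(0, 2, (100, 3))
        assert toy.valid_fraction(m, tol=np.inf) == 1.0

    @pytest.mark.parametrize("n_vars, expected", [(1, 0.015), (2, 0.029775)])
    def test_closed_form_anchors(self, n_vars, expected):
        assert toy.analytic_valid_fraction(n_vars) == pytest.approx(expected, abs=1e-12)
        m = toy.sample_independent(toy.ToyConfig(n_vars=n_vars, n_samples=10**6, rng_seed=5))
        se = np.sqrt(expected * (1 - expected) / 10**6)
        assert abs(toy.valid_fraction(m) - expected) < 3 * se

    def test_monte_carlo_matches_irwin_hall(self):
        """Law-of-large-numbers curve: MC within 3 SE of the exact oracle."""
        for n in (1, 2, 5, 8, 20):
            m = toy.sample_independent(toy.ToyConfig(n_vars=n, n_samples=10**6, rng_seed=n))
            expected = toy.analytic_valid_fraction(n)
            se = np.sqrt(expected * (1 - expected) / 10**6)
            assert abs(toy.valid_fraction(m) - expected) < 3 * se

    def test_analytic_fraction_increases_with_n(self):
        fr = [toy.analytic_valid_fraction(n) for n in range(1, 41)]
        assert all(b > a for a, b in zip(fr, fr[1:]))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            toy.valid_fraction(np.empty((0, 2)))


class TestCopula:
    def test_independent_case_uncorrelated(self):
        m = toy.sample_copula(4, 0.0, 200_000, seed=3)
        C = np.corrcoef(m, rowvar=False)
        iu = np.triu_indices(4, 1)
        assert np.max(np.abs(C[iu])) < 0.01

    def test_output_correlation_closed_form(self):
        """Gaussian-copula uniforms have Pearson r = (6/π)·arcsin(ρ/2)."""
        m = toy.sample_copula(5, 0.5, 10**6, seed=4)
        C = np.corrcoef(m, rowvar=False)
        iu = np.triu_indices(5, 1)
        expected = 6 / np.pi * np.arcsin(0.25)
        assert C[iu].mean() == pytest.approx(expected, abs=0.005)

    def test_marginals_uniform(self):
        m = toy.sample_copula(3, 0.6, 50_000, seed=7)
        for j in range(3):
            stat = stats.kstest(m[:, j] / 2.0, "uniform")
            assert stat.pvalue > 0.01

    def test_invalid_negative_rho_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            toy.copula_correlation_matrix(5, -0.5)  # bound is -1/4

    def test_boundary_rho_accepted(self):
        m = toy.sample_copula(3, -0.5 + 1e-9, 1000, seed=0)
        assert m.shape == (1000, 3)


class TestDistributedSampler:
    def test_first_draw_uniform(self):
        m = toy.sample_distributed(1, 50_000, seed=1)
        assert stats.kstest(m[:, 0] / 2.0, "uniform").pvalue > 0.01

    def test_second_draw_obeys_largest_gap_rule(self):
        """x₂ falls below x₁ iff x₁ ≥ 2 − x₁ (the bigger boundary gap)."""
        m = toy.sample_distributed(2, 20_000, seed=2)
        x1, x2 = m[:, 0], m[:, 1]
        below = x1 >= 1.0
        assert np.all(x2[below] < x1[below])
        assert np.all(x2[~below] > x1[~below])

    def test_row_mean_variance_below_independent(self):
        d = toy.sample_distributed(5, 100_000, seed=3)
        var_d = d.mean(axis=1).var()
        assert var_d < 1.0 / 15.0  # independent-sampler variance of the mean

    def test_more_valid_than_independent(self):
        for n in (2, 5, 8):
            d = toy.sample_distributed(n, 100_000, seed=n)
            i = toy.sample_independent(toy.ToyConfig(n_vars=n, n_samples=100_000, rng_seed=n + 50))
            assert toy.valid_fraction(d) > toy.valid_fraction(i)


class TestNonlinear:
    def test_sigmoid_midpoint_and_identity(self):
        assert toy.sigmoid(0.0) == pytest.approx(0.0)
        for x in (-3.0, -1.0, 0.0, 1.0, 3.0):
            assert toy.sigmoid(x) == pytest.approx(np.tanh(x / 2.0), abs=1e-12)

    def test_interaction_matrix_left_stochastic(self, rng):
        M = toy.random_interaction_matrix(6, rng)
        assert np.allclose(M.sum(axis=0), 1.0)
        assert np.all(np.isfinite(M))

    def test_order_zero_elementwise(self):
        cfg = toy.make_nonlinear_config(4, 0, seed=1)
        row = np.full((1, 4), 0.7)
        out = toy.nonlinear_transform(row, cfg)
        assert np.allclose(out, toy.sigmoid(0.7))

    def test_outputs_in_open_interval(self, rng):
        cfg = toy.make_nonlinear_config(5, 2, seed=3)
        u = rng.uniform(0, 2, (200, 5))
        v = toy.nonlinear_transform(u, cfg)
        assert np.all(v > -1.0) and np.all(v < 1.0)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            toy.NonlinearConfig(order=3)

    def test_orders_raise_valid_fraction_on_default_seeds(self):
        """Interaction orders 0 → 1 → 2 increase the valid fraction (mean over
        20 seeded matrix draws)."""
        fracs = [
            np.mean([toy.nonlinear_valid_fraction(5, order, 20_000, seed=s) for s in range(20)])
            for order in (0, 1, 2)
        ]
        assert fracs[0] < fracs[1] < fracs[2]


class TestOutputCorrelations:
    def test_valid_rows_anticorrelated(self):
        m = toy.sample_independent(toy.ToyConfig(n_vars=2, n_samples=300_000, rng_seed=4))
        r = toy.output_correlation_summary(m[toy.valid_mask(m)])
        assert r < -0.5  # sum constraint forces strong anticorrelation at n=2

    def test_magnitude_decreases_with_n(self):
        rs = {}
        for n in (3, 8):
            m = toy.sample_independent(toy.ToyConfig(n_vars=n, n_samples=300_000, rng_seed=n))
            rs[n] = toy.output_correlation_summary(m[toy.valid_mask(m)])
        assert rs[3] < 0 and rs[8] < 0
        assert abs(rs[8]) < abs(rs[3])

    def test_unfiltered_rows_uncorrelated(self):
        m = toy.sample_independent(toy.ToyConfig(n_vars=4, n_samples=200_000, rng_seed=6))
        assert abs(toy.output_correlation_summary(m)) < 0.01

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            toy.output_correlation_summary(np.ones((2, 3)))


class TestRangeShrink:
    def test_range_inside_window_fully_valid(self):
        df = toy.range_shrink_experiment([3], half_widths=[0.007], n_samples=1000, seed=0)
        assert df["fraction"].iloc[0] == 1.0

    def test_one_var_closed_form(self):
        df = toy.range_shrink_experiment([1], half_widths=[0.1], n_samples=200_000, seed=1)
        se = np.sqrt(0.15 * 0.85 / 200_000)
        assert abs(df["fraction"].iloc[0] - 0.15) < 3 * se

    def test_fraction_nondecreasing_as_width_shrinks(self):
        df = toy.range_shrink_experiment([4], n_samples=50_000, seed=2)
        f = df["fraction"].to_numpy()  # widths decrease 1.0 → 0.1 down the frame
        assert np.all(np.diff(f) >= -2e-3)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            toy.range_shrink_experiment([2], half_widths=[1.2], n_samples=10)

    def test_prefix_fractions_match_analytic(self):
        fr = toy.prefix_valid_fractions(10, 200_000, seed=3)
        for n in (1, 5, 10):
            expected = toy.analytic_valid_fraction(n)
            se = np.sqrt(expected * (1 - expected) / 200_000)
            assert abs(fr[n - 1] - expected) < 4 * se
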