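"""Population protocols validated against analytic evaluators.

Most tests drive the machinery with the toy-model validity rule (valid iff
the row mean is within tolerance of 1), whose valid fraction has an exact
Irwin–Hall expression — an oracle entirely independent of the simulator.
"""

import numpy as np
import pytest

from condpop import toy
from condpop.population import (
    PAIR_WEIGHTS,
    TRIPLET_AXIS,
    PopulationConfig,
    classify_population,
    hyperplane_pair,
    hyperplane_triplet,
    pairwise_correlations,
    random_walk,
    range_sweep,
    sample_population,
    walk_ensemble,
)


def toy_rule(tol=0.015):
    """P surrogate for the toy validity rule: P < 2 iff |mean − 1| < tol."""

    def evaluate(row):
        return 0.0 if abs(float(np.mean(row)) - 1.0) < tol else 6.0

    return evaluate


def toy_rule_rows(tol=0.015):
    def evaluate(rows):
        return np.where(np.abs(rows.mean(axis=1) - 1.0) < tol, 0.0, 6.0)

    return evaluate


class TestSamplePopulation:
    def test_fold_range_bounds_and_frozen(self, baselines):
        cfg = PopulationConfig(baseline=baselines["gc5"], n_samples=500, rng_seed=3)
        S = sample_population(cfg)
        base = baselines["gc5"].free_array()
        assert S.shape == (500, len(base))
        assert np.all(S >= 0.0)
        assert np.all(S <= 2.0 * base + 1e-12)
        # frozen pas/Kir21 never appear among the sampled columns
        assert all(k[0] not in ("pas", "Kir21") for k in baselines["gc5"].free_keys)

    def test_seeded_determinism(self, baselines):
        cfg = PopulationConfig(baseline=baselines["gc5"], n_samples=50, rng_seed=11)
        assert np.array_equal(sample_population(cfg), sample_population(cfg))

    def test_zero_baseline_density_rejected(self, baselines):
        broken = baselines["gc5"].with_free_array(
            np.where(np.arange(7) == 2, 0.0, baselines["gc5"].free_array())
        )
        with pytest.raises(ValueError, match="degenerate"):
            sample_population(PopulationConfig(baseline=broken, n_samples=10))


class TestClassifyPopulation:
    def test_degenerate_evaluators(self):
        S = np.ones((40, 3))
        assert classify_population(S, lambda r: 0.0).fraction == 1.0
        assert classify_population(S, lambda r: 6.0).fraction == 0.0

    def test_irwin_hall_oracle(self):
        """Uniform sampling + toy rule reproduces the analytic valid fraction."""
        rng = np.random.default_rng(0)
        S = rng.uniform(0.0, 2.0, size=(10**6, 5))
        res = classify_population(S, toy_rule_rows(), vectorized=True)
        expected = toy.analytic_valid_fraction(5)
        se = np.sqrt(expected * (1 - expected) / 10**6)
        assert abs(res.fraction - expected) < 3 * se
        assert res.ci[0] < res.fraction < res.ci[1]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            classify_population(np.empty((0, 3)), lambda r: 0.0)


class TestRangeSweep:
    def test_zero_width_keeps_baseline(self):
        df = range_sweep(np.ones(4), [0.0], toy_rule(), n_per=50)
        assert df["fraction"].iloc[0] == 1.0

    def test_one_dim_closed_form(self):
        """w = 0.1, tol 0.015: valid window 0.03 over range width 0.2 → 0.15."""
        df = range_sweep(np.ones(1), [0.1], toy_rule_rows(), n_per=100_000, seed=2, vectorized=True)
        se = np.sqrt(0.15 * 0.85 / 100_000)
        assert abs(df["fraction"].iloc[0] - 0.15) < 3 * se

    def test_fraction_nonincreasing_in_width(self):
        df = range_sweep(np.ones(3), [0.05, 0.1, 0.2, 0.5], toy_rule_rows(),
                         n_per=50_000, seed=4, vectorized=True)
        f = df["fraction"].to_numpy()
        assert np.all(np.diff(f) <= 1e-3)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            range_sweep(np.ones(2), [1.5], toy_rule(), n_per=10)


class TestPairwiseCorrelations:
    def test_duplicated_column_flagged(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, x, rng.normal(size=100)])
        out = pairwise_correlations(X)
        assert out["r"].iloc[0, 1] == pytest.approx(1.0)
        assert out["significant"].iloc[0, 1]

    def test_constant_column_missing_and_unflagged(self, rng):
        X = np.column_stack([np.full(50, 2.0), rng.normal(size=50)])
        out = pairwise_correlations(X)
        assert np.isnan(out["r"].iloc[0, 1])
        assert not out["significant"].iloc[0, 1]

    def test_null_distribution_false_positive_rate(self):
        """Independent columns: tiny correlations, ~1% of pairs flagged."""
        rng = np.random.default_rng(12)
        n_flagged, n_pairs = 0, 0
        for _ in range(30):
            X = rng.uniform(size=(10_000, 5))
            out = pairwise_correlations(X)
            r = out["r"].to_numpy()
            iu = np.triu_indices(5, 1)
            assert np.max(np.abs(r[iu])) < 0.05
            n_flagged += out["significant"].to_numpy()[iu].sum()
            n_pairs += len(iu[0])
        assert n_flagged / n_pairs <= 0.10

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pairwise_correlations(np.ones((2, 3)))


class TestRandomWalk:
    def test_always_valid_reaches_cap(self):
        assert random_walk(np.ones(3), lambda r: 0.0, max_steps=37, seed=0) == 37

    def test_valid_only_at_start_dies_immediately(self):
        start = np.ones(3)

        def only_start(row):
            return 0.0 if np.array_equal(row, start) else 6.0

        assert random_walk(start, only_start, max_steps=10, seed=0) == 0

    def test_step_factors_within_five_percent(self):
        seen = []

        def spy(row):
            seen.append(np.array(row))
            return 0.0

        random_walk(np.ones(4), spy, max_steps=20, seed=8)
        for a, b in zip(seen, seen[1:]):
            f = b / a
            assert np.all(f >= 0.95) and np.all(f <= 1.05)

    def test_invalid_start_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            random_walk(np.ones(3), lambda r: 6.0, max_steps=5)

    def test_ensemble_accounting_and_determinism(self):
        rule = toy_rule(tol=0.2)
        a = walk_ensemble(np.ones(4), rule, reps=60, max_steps=50, seed=2)
        b = walk_ensemble(np.ones(4), rule, reps=60, max_steps=50, seed=2)
        assert np.array_equal(a.steps, b.steps)
        counts, edges = a.histogram()
        assert counts.sum() == 60
        assert np.all(edges % 4 == 0)
        assert a.mean_steps == pytest.approx(float(np.mean(a.steps)))

    def test_survival_monotone_in_threshold(self):
        """Loosening the validity threshold never shortens walks (same seeds)."""

        def p_rule(row):
            return abs(float(np.mean(row)) - 1.0) * 20.0

        tight = walk_ensemble(np.ones(5), p_rule, reps=40, max_steps=80, seed=3, threshold=2.0)
        loose = walk_ensemble(np.ones(5), p_rule, reps=40, max_steps=80, seed=3, threshold=3.0)
        assert np.all(loose.steps >= tight.steps)


class TestHyperplanes:
    def test_pair_degenerate_connected_iff_valid(self):
        v = np.ones(3)
        res = hyperplane_pair(v, v, toy_rule())
        assert res.connected
        res2 = hyperplane_pair(v * 3, v * 3, toy_rule())
        assert not res2.connected

    def test_pair_uses_exactly_nine_interpolants(self):
        calls = []

        def spy(row):
            calls.append(np.array(row))
            return 0.0

        hyperplane_pair(np.ones(2), np.full(2, 1.02), spy)
        assert len(calls) == 9
        assert np.allclose(PAIR_WEIGHTS, np.arange(0.1, 0.95, 0.1))

    def test_pair_interpolants_are_convex(self):
        A, B = np.array([1.0, 2.0]), np.array([2.0, 0.5])
        seen = []
        hyperplane_pair(A, B, lambda r: (seen.append(np.array(r)), 0.0)[1])
        for p in seen:
            assert np.all(p >= np.minimum(A, B) - 1e-12)
            assert np.all(p <= np.maximum(A, B) + 1e-12)

    def test_triplet_grid_geometry(self):
        assert len(TRIPLET_AXIS) == 101
        A, B, C = np.array([1.0, 1.0]), np.array([1.1, 0.9]), np.array([0.9, 1.1])
        res = hyperplane_triplet(A, B, C, toy_rule(tol=0.5))
        # weights sum to 1 at every point
        w1, w2 = res.weights[:, 0], res.weights[:, 1]
        assert np.allclose(w1 + w2 + (1 - w1 - w2), 1.0)
        # vertex (1, 0) reproduces A exactly
        idx = np.flatnonzero((w1 == 1.0) & (w2 == 0.0))[0]
        assert not res.masked[idx]

    def test_triplet_masking_of_negative_points(self):
        A, B, C = np.array([1.0, 0.1]), np.array([0.1, 1.0]), np.array([0.5, 0.5])
        res = hyperplane_triplet(A, B, C, toy_rule(tol=10.0))
        w1, w2 = res.weights[:, 0], res.weights[:, 1]
        w3 = 1.0 - w1 - w2
        pts = w1[:, None] * A + w2[:, None] * B + w3[:, None] * C
        assert np.array_equal(res.masked, np.any(pts < 0.0, axis=1))
        assert np.all(np.isnan(res.P[res.masked]))
        assert np.all(np.isfinite(res.P[~res.masked]))

    def test_triplet_vertices_recover_input_P(self):
        rng = np.random.default_rng(0)
        A, B, C = (rng.uniform(0.5, 1.5, 3) for _ in range(3))

        def p_rule(row):
            return float(np.sum(row))

        res = hyperplane_triplet(A, B, C, p_rule)
        w1, w2 = res.weights[:, 0], res.weights[:, 1]
        for vec, (a, b) in ((A, (1.0, 0.0)), (B, (0.0, 1.0)), (C, (0.0, 0.0))):
            idx = np.flatnonzero((w1 == a) & (w2 == b))[0]
            assert res.P[idx] == pytest.approx(p_rule(vec))

    def test_layout_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hyperplane_pair(np.ones(3), np.ones(4), toy_rule())
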