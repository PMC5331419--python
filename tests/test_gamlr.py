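"""OLS fitting, Friedman lack-of-fit, and the genetic subset search."""

import itertools

import numpy as np
import pytest

from arqsar import DescriptorTable, GAConfig, fit_ols, friedman_lof, run_ga
from arqsar.errors import ConfigError, DegeneratePenaltyError, SingularFitError
from conftest import make_xy


class TestFitOLS:
    def test_exact_linear_data_gives_zero_sse(self):
        x = np.linspace(0, 1, 8)
        table = DescriptorTable(tuple(f"c{i}" for i in range(8)), ("x",), x[:, None])
        fit = fit_ols(table, 2.0 + 3.0 * x)
        assert fit.sse == pytest.approx(0.0, abs=1e-20)
        assert fit.model.intercept == pytest.approx(2.0)
        assert fit.model.coefficients[0] == pytest.approx(3.0)

    def test_duplicated_column_is_singular(self, rng):
        x = rng.standard_normal(10)
        table = DescriptorTable(
            tuple(f"c{i}" for i in range(10)), ("a", "b"), np.column_stack([x, x])
        )
        with pytest.raises(SingularFitError):
            fit_ols(table, rng.standard_normal(10))

    def test_matches_normal_equations_oracle(self):
        table, y = make_xy(20, 3, seed=5)
        fit = fit_ols(table, y)
        design = np.column_stack([np.ones(20), table.values])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit.model.intercept == pytest.approx(oracle[0], abs=1e-10)
        np.testing.assert_allclose(fit.model.coefficients, oracle[1:], atol=1e-10)

    def test_matches_sklearn(self):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        table, y = make_xy(25, 4, seed=11)
        fit = fit_ols(table, y)
        ref = sklearn_lm.LinearRegression().fit(table.values, y)
        assert fit.model.intercept == pytest.approx(ref.intercept_, abs=1e-10)
        np.testing.assert_allclose(fit.model.coefficients, ref.coef_, atol=1e-10)

    def test_sse_equals_sum_of_squared_residuals(self):
        table, y = make_xy(15, 2, seed=3, noise=0.5)
        fit = fit_ols(table, y)
        assert fit.sse == pytest.approx(float(fit.residuals @ fit.residuals))

    def test_too_few_samples_rejected(self):
        table, y = make_xy(4, 3, seed=0)
        with pytest.raises(ConfigError):
            fit_ols(table, y)


class TestFriedmanLOF:
    def test_zero_sse_gives_zero(self):
        assert friedman_lof(0.0, 5, 0.5, 4, 29) == 0.0

    @pytest.mark.parametrize(
        "sse,c,d,p,n,expected",
        [
            (2.0, 5, 0.5, 4, 29, 2.0 / (22.0 / 29.0) ** 2),  # ~3.4752
            (1.0, 2, 0.5, 1, 10, 1.0 / 0.75**2),              # ~1.7778
        ],
    )
    def test_hand_computed_values(self, sse, c, d, p, n, expected):
        assert friedman_lof(sse, c, d, p, n) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_sse_and_p(self):
        base = friedman_lof(1.0, 3, 0.5, 2, 20)
        assert friedman_lof(2.0, 3, 0.5, 2, 20) > base
        assert friedman_lof(1.0, 4, 0.5, 3, 20) > base

    def test_degenerate_penalty_raises(self):
        with pytest.raises(DegeneratePenaltyError):
            friedman_lof(1.0, 20, 0.5, 4, 20)


class TestRunGA:
    def test_recovers_planted_subset_among_decoys(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((30, 50))
        true = (4, 17, 29, 41)
        y = 1.0 + X[:, true] @ np.array([1.0, -1.2, 0.8, 1.5]) + 0.1 * rng.standard_normal(30)
        table = DescriptorTable(
            tuple(f"c{i}" for i in range(30)), tuple(f"x{j}" for j in range(50)), X
        )
        ranked = run_ga(table, y, GAConfig(seed=1, model_size=4, population_size=100,
                                           max_generations=300, stagnation_patience=100))
        assert ranked[0][0].descriptor_indices == true

    def test_matches_exhaustive_enumeration(self):
        """On a small space the GA best equals the brute-force LOF optimum."""
        table, y = make_xy(18, 10, seed=9, noise=0.3)
        ranked = run_ga(table, y, GAConfig(seed=0, model_size=3, population_size=60,
                                           max_generations=200, stagnation_patience=50))
        best_lof = np.inf
        best_subset = None
        for subset in itertools.combinations(range(10), 3):
            names = [table.descriptor_names[i] for i in subset]
            fit = fit_ols(table.select_descriptors(names), y)
            lof = friedman_lof(fit.sse, 4, 0.5, 3, 18)
            if lof < best_lof:
                best_lof, best_subset = lof, subset
        assert ranked[0][0].descriptor_indices == best_subset
        assert ranked[0][0].fitness == pytest.approx(best_lof, rel=1e-8)

    def test_zero_generations_ranks_initial_population(self):
        table, y = make_xy(15, 8, seed=2)
        cfg = GAConfig(seed=3, model_size=2, population_size=20, max_generations=0)
        first = run_ga(table, y, cfg)
        second = run_ga(table, y, cfg)
        assert [c.descriptor_indices for c, _ in first] == [
            c.descriptor_indices for c, _ in second
        ]
        fits = [c.fitness for c, _ in first]
        assert fits == sorted(fits)

    def test_single_descriptor_space(self):
        table, y = make_xy(10, 1, seed=4)
        ranked = run_ga(table, y, GAConfig(seed=0, model_size=1, population_size=5,
                                           max_generations=5))
        chrom, fit = ranked[0]
        assert chrom.descriptor_indices == (0,)
        assert chrom.fitness == pytest.approx(
            friedman_lof(fit.sse, 2, 0.5, 1, 10), rel=1e-8
        )

    def test_seed_determinism(self):
        table, y = make_xy(25, 30, seed=6, noise=0.5)
        cfg = GAConfig(seed=11, model_size=3, population_size=40,
                       max_generations=100, stagnation_patience=30)
        a = run_ga(table, y, cfg)
        b = run_ga(table, y, cfg)
        assert [(c.descriptor_indices, c.fitness) for c, _ in a] == [
            (c.descriptor_indices, c.fitness) for c, _ in b
        ]

    def test_model_size_exceeding_columns_rejected(self):
        table, y = make_xy(10, 2, seed=0)
        with pytest.raises(ConfigError):
            run_ga(table, y, GAConfig(model_size=3))

    def test_gram_fitness_agrees_with_fit_ols(self):
        """The GA's Gram-matrix shortcut and the public OLS path agree."""
        table, y = make_xy(20, 6, seed=8, noise=0.4)
        ranked = run_ga(table, y, GAConfig(seed=5, model_size=2, population_size=15,
                                           max_generations=10, stagnation_patience=5))
        for chrom, fit in ranked:
            assert chrom.fitness == pytest.approx(
                friedman_lof(fit.sse, fit.c, 0.5, fit.p_terms, fit.n), rel=1e-8
            )
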