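"""Leverage applicability domain, Williams and Insubria point tables."""

import numpy as np
import pytest

from arqsar import (
    DescriptorTable,
    fit_ols,
    insubria_points,
    leverage_cutoff,
    leverages,
    standardized_residuals,
    williams_points,
)
from arqsar.errors import ConfigError, DomainError
from conftest import make_xy


class TestLeverageCutoff:
    @pytest.mark.parametrize(
        "p,n,expected",
        [(4, 29, 15.0 / 29.0), (2, 12, 0.75), (1, 6, 1.0)],
    )
    def test_values(self, p, n, expected):
        assert leverage_cutoff(p, n) == pytest.approx(expected, rel=1e-12)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigError):
            leverage_cutoff(0, 10)
        with pytest.raises(ConfigError):
            leverage_cutoff(4, 5)


class TestLeverages:
    def test_training_hats_sum_to_p_plus_one(self):
        table, _ = make_xy(20, 3, seed=0)
        h = leverages(table, table)
        assert h.sum() == pytest.approx(4.0, abs=1e-8)
        assert np.all(h >= 1.0 / 20 - 1e-12)
        assert np.all(h <= 1.0 + 1e-12)

    def test_two_points_one_descriptor_both_have_leverage_one(self):
        t = DescriptorTable(("a", "b"), ("x",), np.array([[0.0], [1.0]]))
        np.testing.assert_allclose(leverages(t, t), [1.0, 1.0], atol=1e-12)

    def test_far_query_exceeds_cutoff(self):
        table, _ = make_xy(20, 3, seed=1)
        h_star = leverage_cutoff(3, 20)
        far = DescriptorTable(("q",), table.descriptor_names,
                              np.full((1, 3), 50.0))
        assert leverages(table, far)[0] > h_star

    def test_affine_recoding_invariance(self):
        """Scaling/translating descriptor columns must not change leverage."""
        table, _ = make_xy(15, 3, seed=2)
        query = DescriptorTable(("q1", "q2"), table.descriptor_names,
                                np.array([[0.5, -1.0, 2.0], [3.0, 0.0, -2.0]]))
        h = leverages(table, query)
        scale = np.array([2.0, -0.5, 10.0])
        shift = np.array([1.0, -3.0, 0.25])
        recoded = DescriptorTable(table.compound_ids, table.descriptor_names,
                                  table.values * scale + shift)
        recoded_q = DescriptorTable(query.compound_ids, query.descriptor_names,
                                    query.values * scale + shift)
        np.testing.assert_allclose(leverages(recoded, recoded_q), h, atol=1e-9)

    def test_leverage_monotone_in_centroid_distance(self):
        table, _ = make_xy(20, 2, seed=3)
        centroid = table.values.mean(axis=0)
        direction = np.array([1.0, -0.5])
        hs = []
        for scale in (0.5, 1.0, 2.0, 4.0, 8.0):
            q = DescriptorTable(("q",), table.descriptor_names,
                                (centroid + scale * direction)[None, :])
            hs.append(leverages(table, q)[0])
        assert all(a < b for a, b in zip(hs, hs[1:]))

    def test_column_mismatch_rejected(self):
        table, _ = make_xy(10, 2, seed=4)
        other = DescriptorTable(("q",), ("other", "names"), np.zeros((1, 2)))
        with pytest.raises(DomainError):
            leverages(table, other)


class TestStandardizedResiduals:
    def test_alternating_equal_residuals(self):
        # residuals +-r have sample SD r*sqrt(n/(n-1)); standardized values
        # are -+sqrt((n-1)/n) under the ddof=1 convention
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = y + np.array([0.5, -0.5, 0.5, -0.5])
        std, flags = standardized_residuals(y, yhat)
        expected = np.sqrt(3.0 / 4.0)
        np.testing.assert_allclose(np.abs(std), expected, atol=1e-12)
        assert not flags.any()

    def test_zero_residual_maps_to_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.0, 2.5, 2.5])
        std, _ = standardized_residuals(y, yhat)
        assert std[0] == 0.0

    def test_large_residual_flagged(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        yhat = y + 0.1 * rng.standard_normal(30)
        yhat[5] = y[5] + 3.0  # gross response outlier
        std, flags = standardized_residuals(y, yhat)
        assert flags[5]
        assert abs(std[5]) > 2.5


class TestWilliamsAndInsubria:
    def _fitted(self, n=25, p=3, seed=5, noise=0.15):
        table, y = make_xy(n, p, seed=seed, noise=noise)
        fit = fit_ols(table, y)
        return fit.model, table, y

    def test_benign_data_all_inside(self):
        model, table, y = self._fitted()
        report = williams_points(model, table, y)
        assert all(r.inside_ad for r in report.records)
        assert all(not r.residual_flag for r in report.records)
        assert report.h_star == pytest.approx(leverage_cutoff(3, 25))

    def test_descriptor_outlier_flags_leverage_only(self):
        model, table, y = self._fitted()
        far_x = table.values.mean(axis=0) + 40.0
        x_ext = DescriptorTable(("out",), table.descriptor_names, far_x[None, :])
        y_ext = np.array([float(model.intercept + far_x @ np.array(model.coefficients))])
        report = williams_points(model, table, y, x_ext, y_ext)
        rec = report.records[-1]
        assert rec.compound_id == "out"
        assert not rec.inside_ad
        assert not rec.residual_flag  # response was on-model

    def test_activity_outlier_flags_residual_only(self):
        model, table, y = self._fitted()
        central = table.values.mean(axis=0)
        x_ext = DescriptorTable(("out",), table.descriptor_names, central[None, :])
        y_ext = np.array([model.intercept + central @ np.array(model.coefficients) + 5.0])
        report = williams_points(model, table, y, x_ext, y_ext)
        rec = report.records[-1]
        assert rec.inside_ad
        assert rec.residual_flag

    def test_insubria_screen_identical_to_training_row(self):
        model, table, y = self._fitted()
        h_train = leverages(table, table)
        clone = DescriptorTable(("clone",), table.descriptor_names,
                                table.values[[3], :])
        report = insubria_points(model, table, clone)
        rec = report.records[0]
        assert rec.h == pytest.approx(h_train[3], abs=1e-12)
        assert rec.inside_ad
        assert rec.predicted == pytest.approx(
            model.intercept + float(table.values[3] @ np.array(model.coefficients))
        )

    def test_insubria_extrapolated_row_is_outside(self):
        model, table, _ = self._fitted()
        far = DescriptorTable(("far",), table.descriptor_names,
                              np.full((1, 3), 30.0))
        report = insubria_points(model, table, far)
        assert not report.records[0].inside_ad

    def test_empty_screen_set_gives_empty_report(self):
        model, table, _ = self._fitted()
        report = insubria_points(model, table, None)
        assert report.records == ()
        assert report.h_star > 0
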