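"""Closed-form and oracle checks for the psychometric primitives."""

import numpy as np
import pandas as pd
import pytest

from pbmcscore import (
    CorrelationMatrix,
    bartlett_sphericity,
    correlation_matrix,
    cronbach_alpha,
    extract_factors,
    kmo,
    retain_dimensions,
    rotate_loadings,
)
from pbmcscore.psychometrics import PsychometricsError, varimax_criterion

from conftest import exchangeable_items


class TestCorrelationMatrix:
    def test_identical_columns_give_unit_correlation(self):
        x = pd.Series([0, 1, 2, 1, 0, 2, 1])
        items = pd.DataFrame({"a": x, "b": x, "c": 2 - x})
        corr = correlation_matrix(items)
        assert corr.values[0, 1] == pytest.approx(1.0)
        assert corr.values[0, 2] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(7)
        items = pd.DataFrame(rng.integers(0, 3, size=(10_000, 3)), columns=list("abc"))
        corr = correlation_matrix(items)
        off = corr.values[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_matches_hand_computed_pearson(self):
        # 3 items, 4 rows; r(a,b) computed by the product-moment formula by hand
        items = pd.DataFrame({"a": [0, 1, 2, 1], "b": [0, 2, 2, 0], "c": [2, 1, 0, 1]})
        corr = correlation_matrix(items)
        a = np.array([0, 1, 2, 1], dtype=float)
        b = np.array([0, 2, 2, 0], dtype=float)
        r_ab = np.sum((a - 1.0) * (b - 1.0)) / np.sqrt(np.sum((a - 1) ** 2) * np.sum((b - 1) ** 2))
        assert corr.values[0, 1] == pytest.approx(r_ab, abs=1e-12)
        assert corr.values[0, 2] == pytest.approx(-1.0)  # c = 2 - a
        assert corr.n_obs == 4

    def test_zero_variance_item_named_in_error(self):
        items = pd.DataFrame({"a": [0, 1, 2, 1], "flat": [1, 1, 1, 1]})
        with pytest.raises(PsychometricsError, match="flat"):
            correlation_matrix(items)

    def test_listwise_deletion(self):
        items = pd.DataFrame(
            {"a": [0, 1, 2, 1, np.nan], "b": [0, 2, 2, 0, 1], "c": [2, 1, 0, 1, 0]}
        )
        assert correlation_matrix(items).n_obs == 4

    def test_polychoric_recovers_latent_correlation(self):
        rng = np.random.default_rng(11)
        n = 4000
        rho = 0.5
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        items = pd.DataFrame(
            {
                "a": np.digitize(z[:, 0], [-0.5, 0.8]),
                "b": np.digitize(z[:, 1], [-0.2, 1.0]),
            }
        )
        poly = correlation_matrix(items, method="polychoric")
        pear = correlation_matrix(items, method="pearson")
        assert poly.values[0, 1] == pytest.approx(rho, abs=0.06)
        assert pear.values[0, 1] < poly.values[0, 1]  # Pearson attenuates


class TestKMO:
    def test_two_items_force_half(self):
        corr = CorrelationMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]), ["a", "b"], 100)
        overall, per_item = kmo(corr)
        assert overall == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(per_item, 0.5)

    def test_equicorrelated_matches_closed_form(self):
        # exchangeable r: partial correlation given the other p-2 items is
        # r / (1 + (p-2) r), hence KMO = r^2 / (r^2 + (r/(1+(p-2)r))^2)
        r, p = 0.5, 4
        values = np.full((p, p), r)
        np.fill_diagonal(values, 1.0)
        corr = CorrelationMatrix(values, list("abcd"), 500)
        overall, per_item = kmo(corr)
        partial = r / (1 + (p - 2) * r)
        expected = r**2 / (r**2 + partial**2)
        assert overall == pytest.approx(expected, abs=1e-10)
        assert np.allclose(per_item, expected, atol=1e-10)

    def test_permutation_invariance(self, calibrated_dataset):
        items = calibrated_dataset.items
        corr = correlation_matrix(items)
        overall, per_item = kmo(corr)
        shuffled = items[list(items.columns[::-1])]
        overall2, per_item2 = kmo(correlation_matrix(shuffled))
        assert overall2 == pytest.approx(overall, abs=1e-12)
        assert np.allclose(per_item2[items.columns].to_numpy(), per_item.to_numpy())
        assert 0 <= overall <= 1
        assert ((per_item >= 0) & (per_item <= 1)).all()

    def test_singular_matrix_raises(self):
        values = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        corr = CorrelationMatrix(values, list("abc"), 50)
        with pytest.raises((PsychometricsError, np.linalg.LinAlgError)):
            kmo(corr)


class TestBartlett:
    def test_identity_matrix_statistic_zero(self):
        corr = CorrelationMatrix(np.eye(4), list("abcd"), 200)
        stat, df, p = bartlett_sphericity(corr)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_df_for_six_items(self):
        corr = CorrelationMatrix(np.eye(6), [f"i{k}" for k in range(6)], 100)
        _, df, _ = bartlett_sphericity(corr)
        assert df == 15

    def test_matches_hand_computed_determinant(self):
        values = np.array([[1.0, 0.3, 0.2], [0.3, 1.0, 0.4], [0.2, 0.4, 1.0]])
        # det by cofactor expansion: 1*(1-.16) - .3*(.3-.08) + .2*(.12-.2)
        det = 0.84 - 0.3 * 0.22 + 0.2 * (-0.08)
        n = 50
        expected = -(n - 1 - (2 * 3 + 5) / 6) * np.log(det)
        corr = CorrelationMatrix(values, list("abc"), n)
        stat, df, _ = bartlett_sphericity(corr)
        assert stat == pytest.approx(expected, abs=1e-8)
        assert df == 3

    def test_statistic_scales_with_n(self):
        values = np.array([[1.0, 0.3], [0.3, 1.0]])
        s1, _, _ = bartlett_sphericity(CorrelationMatrix(values, ["a", "b"], 100))
        s2, _, _ = bartlett_sphericity(CorrelationMatrix(values, ["a", "b"], 1000))
        factor = (1000 - 1 - 9 / 6) / (100 - 1 - 9 / 6)
        assert s2 / s1 == pytest.approx(factor, rel=1e-12)
        assert s1 > 0


class TestCronbachAlpha:
    def test_parallel_items_match_spearman_brown(self):
        k, r = 4, 0.368
        items = exchangeable_items(k, r, n=200, seed=5)
        result = cronbach_alpha(items)
        expected = k * r / (1 + (k - 1) * r)  # = 0.6996...
        assert result.alpha == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.6996, abs=5e-5)

    def test_duplicated_column_gives_one(self):
        x = pd.Series([0.0, 1, 2, 1, 0, 2])
        result = cronbach_alpha(pd.DataFrame({"a": x, "b": x}))
        assert result.alpha == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        items = exchangeable_items(4, 0.0, n=5000, seed=9)
        assert abs(cronbach_alpha(items).alpha) < 1e-10  # exactly uncorrelated sample

    def test_subset_selection(self, calibrated_dataset):
        items = calibrated_dataset.items
        sub = ["having_money", "distance_to_facility"]
        result = cronbach_alpha(items, subset=sub)
        assert result.k_items == 2
        assert list(result.item_total.index) == sub


class TestExtractFactors:
    def test_exact_one_factor_recovery_iterated(self):
        lam = 0.7
        values = np.full((6, 6), lam * lam)
        np.fill_diagonal(values, 1.0)
        corr = CorrelationMatrix(values, [f"i{k}" for k in range(6)], 1000)
        result = extract_factors(corr, 1, extraction="pf", iterate=True)
        assert np.allclose(result.loadings[:, 0], lam, atol=1e-3)
        assert np.allclose(result.communalities, lam * lam, atol=2e-3)

    def test_identity_matrix_degenerate(self):
        corr = CorrelationMatrix(np.eye(5), [f"i{k}" for k in range(5)], 100)
        result = extract_factors(corr, 1, extraction="pf")
        # no common variance: communalities stay at (zero) SMC level
        assert np.all(result.communalities < 1e-8)

    def test_calibrated_data_one_strong_factor(self, calibrated_dataset):
        reduced = calibrated_dataset.items[
            ["having_money", "distance_to_facility", "finding_transport", "going_alone"]
        ]
        corr = correlation_matrix(reduced)
        result = extract_factors(corr, 1)
        assert result.eigenvalues[0] > 1.1
        assert np.sum(np.abs(result.loadings[:, 0]) > 0.4) == 4

    def test_eigenvalues_descending_and_variance_share(self, calibrated_dataset):
        corr = correlation_matrix(calibrated_dataset.items)
        result = extract_factors(corr, 2)
        assert np.all(np.diff(result.eigenvalues) <= 1e-10)
        assert result.proportion_variance[0] == pytest.approx(
            result.eigenvalues[0] / corr.p
        )


class TestRotation:
    def test_single_factor_unchanged_up_to_sign(self):
        corr = CorrelationMatrix(
            np.array([[1, 0.5, 0.4], [0.5, 1, 0.45], [0.4, 0.45, 1.0]]), list("abc"), 300
        )
        result = extract_factors(corr, 1)
        rotated = rotate_loadings(result, "varimax")
        assert np.allclose(np.abs(rotated.rotated_loadings), np.abs(result.loadings))

    def test_varimax_matches_angle_grid_oracle(self):
        # 2-factor toy: brute-force search over the single rotation angle
        L = np.array([[0.8, 0.1], [0.75, 0.2], [0.15, 0.7], [0.1, 0.8], [0.45, 0.5]])
        values = L @ L.T
        np.fill_diagonal(values, 1.0)
        corr = CorrelationMatrix(values, [f"i{k}" for k in range(5)], 500)
        result = extract_factors(corr, 2)
        rotated = rotate_loadings(result, "varimax", kaiser_normalize=False)
        best = -np.inf
        for theta in np.linspace(0, np.pi / 2, 20001):
            c, s = np.cos(theta), np.sin(theta)
            for rot in (np.array([[c, -s], [s, c]]), np.array([[c, s], [s, -c]])):
                best = max(best, varimax_criterion(result.loadings @ rot))
        assert varimax_criterion(rotated.rotated_loadings) == pytest.approx(best, abs=1e-6)

    def test_communalities_invariant_under_rotation(self, calibrated_dataset):
        corr = correlation_matrix(calibrated_dataset.items)
        result = extract_factors(corr, 2)
        rotated = rotate_loadings(result, "varimax")
        assert np.allclose(
            np.sum(rotated.rotated_loadings**2, axis=1), result.communalities, atol=1e-8
        )

    def test_unknown_method_rejected(self):
        corr = CorrelationMatrix(np.eye(3), list("abc"), 50)
        result = extract_factors(corr, 1)
        with pytest.raises(PsychometricsError):
            rotate_loadings(result, "promax")


class TestRetainDimensions:
    @pytest.mark.parametrize(
        "eigenvalues, threshold, expected",
        [
            ((2.13, 0.9, 0.4, 0.2, 0.1), 1.1, 1),
            ((3.0, 2.0, 1.2, 0.5), 1.1, 3),
            ((0.9, 0.8), 1.1, 1),  # none exceed: floor at one with a warning
        ],
    )
    def test_counts(self, eigenvalues, threshold, expected):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert retain_dimensions(np.array(eigenvalues), threshold) == expected

    def test_boundary_is_strict(self):
        with pytest.warns(UserWarning):
            assert retain_dimensions(np.array([1.1, 1.1]), 1.1) == 1
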