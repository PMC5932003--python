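import numpy as np
import pandas as pd
import pytest

from peatflux.omquality import (
    build_om_matrix,
    correct_dph,
    detrend_on_component,
    ftir_indices,
    pca_correlation,
    pearson,
)


class TestCorrectDph:
    def test_linear_trend_becomes_constant_mean(self):
        age = np.linspace(0, 8000, 50)
        absorbance = 0.2 + 3e-5 * age
        corrected = correct_dph(absorbance, age)
        assert np.allclose(corrected, absorbance.mean(), atol=1e-12)

    def test_zero_slope_input_is_unchanged(self):
        rng = np.random.default_rng(0)
        age = np.linspace(0, 8000, 50)
        absorbance = 0.3 + 0.0 * age + 0.0 * rng.standard_normal(50)
        assert np.allclose(correct_dph(absorbance, age), absorbance)

    def test_embedded_step_survives_detrending(self):
        age = np.linspace(0, 8000, 200)
        step = np.where((age > 3000) & (age < 4000), 0.1, 0.0)
        absorbance = 0.2 + 2e-5 * age + step
        corrected = correct_dph(absorbance, age)
        inside = corrected[(age > 3000) & (age < 4000)].mean()
        outside = corrected[(age < 2500) | (age > 4500)].mean()
        assert inside - outside == pytest.approx(0.1, rel=0.05)

    def test_corrected_series_is_uncorrelated_with_age(self):
        rng = np.random.default_rng(1)
        age = np.linspace(0, 8000, 100)
        absorbance = 0.2 + 4e-5 * age + 0.01 * rng.standard_normal(100)
        r, _ = pearson(correct_dph(absorbance, age), age)
        assert abs(r) < 1e-9

    def test_constant_age_vector_raises(self):
        with pytest.raises(ValueError):
            correct_dph(np.ones(5), np.full(5, 100.0))


def test_ftir_indices_elementwise():
    cl, ca = ftir_indices(np.array([2.0, 1.0]), np.array([1.0, 1.0]), np.array([1.0, 1.0]))
    assert np.allclose(cl, [2.0, 1.0])
    assert np.allclose(ca, [2.0, 1.0])
    with pytest.raises(ValueError):
        ftir_indices(np.array([1.0]), np.array([0.0]), np.array([1.0]))


class TestPca:
    def test_two_perfectly_correlated_variables(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        m = pd.DataFrame({"a": x, "b": 3.0 * x + 1.0})
        res = pca_correlation(m)
        assert res.explained_variance[0] == pytest.approx(1.0)
        assert np.allclose(np.abs(res.loadings["Cp1"]), 1.0, atol=1e-9)

    def test_independent_columns_have_unit_eigenvalues(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.standard_normal((10_000, 8)), columns=list("abcdefgh"))
        res = pca_correlation(m)
        assert np.all(res.eigenvalues > 0.9)
        assert np.all(res.eigenvalues < 1.1)

    def test_structural_invariants(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((300, 3))
        m = pd.DataFrame(
            np.column_stack([base, base @ rng.standard_normal((3, 3)) + 0.3 * rng.standard_normal((300, 3))]),
            columns=list("abcdef"),
        )
        res = pca_correlation(m)
        p = m.shape[1]
        assert res.eigenvalues.sum() == pytest.approx(p, abs=1e-9)
        # loadings reproduce the correlation matrix at full rank
        L = res.loadings.to_numpy()
        corr = np.corrcoef(m.to_numpy(), rowvar=False)
        assert np.allclose(L @ L.T, corr, atol=1e-9)
        # column sum-of-squares of loadings equals the eigenvalue
        assert np.allclose((L**2).sum(axis=0), res.eigenvalues, atol=1e-9)
        # scores are standardised
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(res.scores.std(axis=0, ddof=1), 1.0, atol=1e-6)
        # orientation: largest-|loading| variable positive per component
        for j in range(p):
            col = L[:, j]
            assert col[np.argmax(np.abs(col))] >= 0

    def test_invariant_to_row_order_and_affine_rescaling(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.standard_normal((100, 4)), columns=list("abcd"))
        res1 = pca_correlation(m)
        shuffled = m.sample(frac=1.0, random_state=0)
        res2 = pca_correlation(shuffled)
        assert np.allclose(
            res1.loadings.to_numpy(), res2.loadings.to_numpy(), atol=1e-9
        )
        rescaled = m.copy()
        rescaled["b"] = 100.0 * rescaled["b"] - 7.0
        res3 = pca_correlation(rescaled)
        assert np.allclose(
            res1.loadings.to_numpy(), res3.loadings.to_numpy(), atol=1e-9
        )

    def test_constant_column_is_named_in_error(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            pca_correlation(m)


class TestDetrend:
    def test_exact_multiple_gives_zero_residuals(self):
        rng = np.random.default_rng(6)
        scores = rng.standard_normal(100)
        resid = detrend_on_component(2.0 * scores, scores)
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_orthogonal_series_is_centred_but_unchanged(self):
        scores = np.tile([1.0, -1.0], 50)
        series = np.tile([1.0, 1.0, -1.0, -1.0], 25) + 5.0  # orthogonal to scores
        resid = detrend_on_component(series, scores)
        assert np.allclose(resid, series - series.mean(), atol=1e-12)

    def test_recovers_secondary_component(self):
        rng = np.random.default_rng(7)
        cp1 = rng.standard_normal(500)
        cp2 = rng.standard_normal(500)
        series = 3.0 * cp1 + 2.0 * cp2 + 0.05 * rng.standard_normal(500)
        resid = detrend_on_component(series, cp1)
        r, _ = pearson(resid, cp2)
        assert r >= 0.9


class TestPearson:
    def test_perfect_correlations(self):
        x = np.linspace(0, 1, 50)
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_bivariate_normal_rho_08(self):
        rng = np.random.default_rng(8)
        cov = [[1.0, 0.8], [0.8, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=105)
        r, p = pearson(xy[:, 0], xy[:, 1])
        assert 0.70 <= r <= 0.88
        assert p < 0.001

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pearson(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            pearson(np.array([1.0, np.nan, 2.0]), np.array([1.0, 2.0, 3.0]))


def test_build_om_matrix_layout():
    n = 30
    rng = np.random.default_rng(9)
    age = np.linspace(100, 8000, n)
    m = build_om_matrix(
        age=age,
        c_pct=49 + rng.standard_normal(n),
        n_pct=1.0 + 0.05 * rng.standard_normal(n),
        d13c=-26 + 0.2 * rng.standard_normal(n),
        d15n=1.0 + 0.3 * rng.standard_normal(n),
        dph=0.3 + 2e-5 * age + 0.01 * rng.standard_normal(n),
        ftir_1040=1.0 + 0.05 * rng.standard_normal(n),
        ftir_1650=0.5 + 0.02 * rng.standard_normal(n),
        ftir_2920=0.45 + 0.02 * rng.standard_normal(n),
    )
    assert list(m.columns) == [
        "C", "N", "C/N", "d13C", "d15N", "DPH",
        "carbohydrate/lignin", "carbohydrate/aliphatic",
    ]
    # DPH detrended on age by default
    r, _ = pearson(m["DPH"].to_numpy(), age)
    assert abs(r) < 0.3
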