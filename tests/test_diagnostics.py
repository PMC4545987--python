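"""Residual fit statistics, reliability, dimensionality, local independence."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import raschkit as rk
from raschkit.config import AnalysisConfig
from raschkit.diagnostics import (classify_fit, infit_outfit_from_moments,
                                  kr20, local_independence, pca_residuals,
                                  residuals_from_moments,
                                  separation_from_reliability,
                                  separation_reliability)


class TestStandardizedResiduals:
    def test_definition_cases(self):
        X = np.array([[0.5, 1.0, 0.0]])
        E = np.array([[0.5, 0.5, 0.5]])
        V = np.array([[0.25, 0.25, 0.0]])
        z = residuals_from_moments(X, E, V)
        assert z[0, 0] == 0.0
        assert z[0, 1] == pytest.approx(1.0)   # (1-0.5)/sqrt(0.25)
        assert np.isnan(z[0, 2])               # degenerate cell

    def test_model_true_data_mean_zero_unit_variance(self):
        cfg = rk.dichotomous_bank_config(n_persons=500)
        matrix, _ = rk.generate(cfg, seed=3)
        result = rk.RaschModel(matrix, cfg.spec).fit()
        z = result.standardized_residuals()
        assert z.mean().abs().max() < 0.15          # per-item mean ~ 0
        assert abs(z.to_numpy().mean()) < 0.05      # overall mean ~ 0
        # overall variance ~ 1 (per-item variance is noisy for the most
        # off-target items, whose squared residuals are heavy-tailed)
        assert abs(np.nanvar(z.to_numpy()) - 1.0) < 0.15
        centred = z.var(ddof=0).between(0.7, 1.3)
        assert centred[5:15].all()                  # well-targeted items

    def test_score_equations_hold_at_solution(self, small_dich_matrix):
        # at the JMLE optimum sum(x - E) vanishes per person and per item
        matrix, spec = small_dich_matrix
        res = rk.RaschModel(matrix, spec).fit(tol=1e-6)
        E, _ = res.expected_and_variance()
        resid = res.responses() - E
        assert resid.sum(axis=0).abs().max() < 1e-3
        assert resid.sum(axis=1).abs().max() < 1e-3


class TestInfitOutfit:
    def test_classification_bands(self):
        cfg = AnalysisConfig()
        assert classify_fit(1.46, cfg) == "misfit"
        assert classify_fit(1.00, cfg) == "fit"
        assert classify_fit(0.59, cfg) == "overfit"

    def test_outfit_equals_infit_under_equal_variances(self):
        rng = np.random.default_rng(2)
        E = np.full((30, 4), 0.5)
        V = np.full((30, 4), 0.25)
        X = rng.integers(0, 2, size=(30, 4)).astype(float)
        infit, outfit, _ = infit_outfit_from_moments(X, E, V)
        np.testing.assert_allclose(infit, outfit, atol=1e-12)

    def test_item_with_one_observation_missing_stats(self):
        X = np.array([[1.0, 1.0], [0.0, np.nan], [1.0, np.nan]])
        E = np.where(np.isnan(X), np.nan, 0.5)
        V = np.where(np.isnan(X), np.nan, 0.25)
        infit, outfit, n = infit_outfit_from_moments(X, E, V)
        assert np.isnan(infit[1]) and np.isnan(outfit[1])
        assert np.isfinite(infit[0])

    def test_null_mean_infit_near_one(self, bank300):
        cfg, matrix, truth, result = bank300
        fit = result.infit_outfit()
        assert 0.9 <= fit["infit"].mean() <= 1.1
        outside = ((fit["infit"] < 0.6) | (fit["infit"] > 1.4)).mean()
        assert outside <= 0.10


class TestSeparationReliability:
    def test_closed_forms(self):
        assert separation_from_reliability(0.8) == pytest.approx(2.0)
        assert separation_from_reliability(0.5) == pytest.approx(1.0)

    def test_published_pairs_mutually_consistent(self):
        # printed reliability/separation pairs agree through G = sqrt(R/(1-R))
        for R, G in [(0.86, 2.50), (0.81, 2.08), (0.59, 1.21)]:
            assert separation_from_reliability(R) == pytest.approx(G, abs=0.05)

    def test_adjusted_variance_path(self):
        rng = np.random.default_rng(0)
        measures = rng.normal(0, 2.0, 500)
        ses = np.full(500, 1.0)
        R, G = separation_reliability(measures, ses)
        obs = np.var(measures, ddof=1)
        assert R == pytest.approx((obs - 1.0) / obs)
        assert G == pytest.approx(np.sqrt(R / (1 - R)))

    def test_degenerate_zero_variance(self):
        R, G = separation_reliability(np.zeros(5), np.ones(5))
        assert (R, G) == (0.0, 0.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=40)
        s = np.abs(rng.normal(size=40)) * 0.3 + 0.1
        assert separation_reliability(m, s) == separation_reliability(m + 5.0, s)


class TestResidualPCA:
    def test_duplicated_residual_structure_raises_first_eigenvalue(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(200, 5))
        z[:, 4] = z[:, 3]  # perfectly correlated residual pair among 5
        res = pca_residuals(pd.DataFrame(z, columns=list("abcde")))
        assert res.first_contrast >= 2.0

    def test_unidimensional_null_below_cut(self, bank300):
        cfg, matrix, truth, result = bank300
        res = pca_residuals(result.standardized_residuals())
        assert res.first_contrast < 2.5
        assert res.eigenvalues[0] == pytest.approx(res.first_contrast)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        # item units: eigenvalues sum to the number of items
        assert res.eigenvalues.sum() == pytest.approx(res.n_items)

    def test_two_dimensions_beat_null(self):
        cfg = rk.dichotomous_bank_config(n_persons=400)
        m0, _ = rk.generate(cfg, seed=4)
        e0 = pca_residuals(
            rk.RaschModel(m0, cfg.spec).fit().standardized_residuals()
        ).first_contrast
        cfg2 = rk.inject_second_dimension(
            cfg, [f"Q{i:02d}" for i in range(11, 21)], 0.0)
        m1, _ = rk.generate(cfg2, seed=4)
        e1 = pca_residuals(
            rk.RaschModel(m1, cfg2.spec).fit().standardized_residuals()
        ).first_contrast
        assert e1 > e0

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        z = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        z["e"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = pca_residuals(z)
        assert res.dropped_items == ["e"]
        assert res.n_items == 4


class TestLocalIndependence:
    def test_duplicate_item_pair_flagged(self, small_dich_matrix):
        matrix, spec = small_dich_matrix
        import raschkit
        from raschkit.instrument import InstrumentSpec, ItemSpec, ResponseMatrix
        dup_vals = np.column_stack([matrix.values, matrix.values[:, 0]])
        spec2 = InstrumentSpec(spec.items + [ItemSpec("i0copy", "D", 2, "g")])
        m2 = ResponseMatrix(matrix.persons, spec.item_ids + ["i0copy"], dup_vals)
        res = raschkit.RaschModel(m2, spec2).fit()
        pairs = local_independence(res.standardized_residuals(), 0.3)
        flagged = {frozenset((r.item_a, r.item_b)) for r in pairs.itertuples()}
        assert frozenset(("i0", "i0copy")) in flagged
        top = pairs.iloc[0]
        assert {top["item_a"], top["item_b"]} == {"i0", "i0copy"}
        assert top["r"] > 0.3

    def test_null_flag_rate_low(self, bank300):
        cfg, matrix, truth, result = bank300
        pairs = local_independence(result.standardized_residuals(), 0.3)
        n_pairs = 20 * 19 / 2
        assert len(pairs) / n_pairs <= 0.05

    def test_threshold_one_flags_nothing(self, bank300):
        cfg, matrix, truth, result = bank300
        assert len(local_independence(result.standardized_residuals(), 1.0)) == 0


class TestKR20:
    def test_identical_columns_give_one(self):
        col = np.array([1, 0, 1, 1, 0, 1, 0, 0, 1, 1], dtype=float)
        df = pd.DataFrame({"a": col, "b": col, "c": col})
        assert kr20(df) == pytest.approx(1.0)

    def test_independent_fair_coins_near_zero(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.integers(0, 2, size=(1000, 8)).astype(float))
        assert abs(kr20(df)) < 0.1

    def test_single_item_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            kr20(pd.DataFrame({"a": [0.0, 1.0, 1.0]}))

    def test_equals_generic_cronbach_alpha(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        base = rng.normal(size=200)
        df = pd.DataFrame({
            f"i{j}": (base + rng.normal(size=200) > j * 0.3 - 0.5).astype(float)
            for j in range(6)
        })
        alpha = pingouin.cronbach_alpha(data=df)[0]
        assert kr20(df) == pytest.approx(alpha, abs=1e-10)

    def test_dispatch_from_response_matrix_selects_dichotomous(self):
        m, _ = rk.generate(seed=2)
        spec = rk.sgrq_like_spec()
        a = kr20(m, spec)
        assert 0.0 < a < 1.0
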