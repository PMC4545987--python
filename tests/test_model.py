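"""Estimation engine: probabilities, expectations, PROX, JMLE, extremes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import raschkit as rk
from raschkit.instrument import InstrumentSpec, ItemSpec, ResponseMatrix
from raschkit.model import (RaschModel, category_probabilities, expected_score,
                            measure_extreme, prox_initialize)

from _oracles import grid_jmle_dichotomous, pcm_category_probs

DICH = ItemSpec("d", "D", 2, "g")
TRI = ItemSpec("t", "D", 3, "g3")


class TestCategoryProbabilities:
    def test_dichotomous_symmetry_at_item_location(self):
        p = category_probabilities(0.7, DICH, 0.7, [0.0])
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-12)

    def test_dichotomous_logistic_closed_form(self):
        p = category_probabilities(np.log(3), DICH, 0.0, [0.0])
        np.testing.assert_allclose(p[1], 0.75, atol=1e-12)

    def test_three_category_hand_evaluation(self):
        # numerators 1, e, 1 at theta=0, delta=0, tau=(-1, +1)
        p = category_probabilities(0.0, TRI, 0.0, [-1.0, 1.0])
        np.testing.assert_allclose(p, [0.21194156, 0.57611688, 0.21194156],
                                   atol=5e-9)

    def test_matches_independent_pcm_formula(self):
        item = ItemSpec("q", "D", 4, "g4")
        for theta in (-2.3, 0.4, 1.9):
            mine = category_probabilities(theta, item, 0.5, [-0.8, 0.1, 0.7])
            ref = pcm_category_probs(theta, [0.5 - 0.8, 0.5 + 0.1, 0.5 + 0.7])
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    @given(st.floats(-10, 10), st.floats(-3, 3))
    def test_probabilities_sum_to_one(self, theta, delta):
        item = ItemSpec("q", "D", 5, "g5")
        p = category_probabilities(theta, item, delta, [-1.5, -0.5, 0.5, 1.5])
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()


class TestExpectedScore:
    def test_limits_and_bernoulli(self):
        E, V = expected_score(30.0, DICH, 0.0, [0.0])
        assert E == pytest.approx(1.0, abs=1e-9)
        E, V = expected_score(0.0, DICH, 0.0, [0.0])
        assert (E, V) == (pytest.approx(0.5), pytest.approx(0.25))

    def test_symmetric_three_category_expectation(self):
        E, _ = expected_score(0.0, TRI, 0.0, [-1.0, 1.0])
        assert E == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(-4, 4), st.floats(-4, 4))
    def test_strictly_increasing_in_theta(self, a, b):
        item = ItemSpec("q", "D", 4, "g4")
        lo, hi = sorted((a, b))
        if hi - lo < 1e-6:
            return
        e_lo, _ = expected_score(lo, item, 0.3, [-1.0, 0.0, 1.0])
        e_hi, _ = expected_score(hi, item, 0.3, [-1.0, 0.0, 1.0])
        assert e_hi > e_lo


class TestProx:
    def test_half_score_item_starts_near_zero(self):
        spec = InstrumentSpec([ItemSpec(f"i{j}", "D", 2, "g") for j in range(4)])
        vals = np.array([[1, 1, 0, 1], [0, 1, 1, 0],
                         [1, 0, 1, 1], [0, 0, 0, 0],
                         [1, 1, 0, 1], [0, 1, 1, 0]])
        m = ResponseMatrix([f"p{i}" for i in range(6)],
                           [f"i{j}" for j in range(4)], vals)
        theta0, delta0 = prox_initialize(m, spec)
        # item i1 has 4/6 -> below-average difficulty; i0 at 3/6 is middling
        assert delta0["i1"] < delta0["i0"]

    def test_harder_item_gets_larger_initial_difficulty(self):
        spec = InstrumentSpec([ItemSpec("easy", "D", 2, "g"),
                               ItemSpec("hard", "D", 2, "g")])
        vals = np.array([[1, 0], [1, 0], [1, 1], [0, 0], [1, 0]])
        m = ResponseMatrix([f"p{i}" for i in range(5)], ["easy", "hard"], vals)
        _, delta0 = prox_initialize(m, spec)
        assert delta0["hard"] > delta0["easy"]

    def test_equal_raw_scores_equal_starts(self):
        spec = InstrumentSpec([ItemSpec(f"i{j}", "D", 2, "g") for j in range(3)])
        vals = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        m = ResponseMatrix(["a", "b", "c"], [f"i{j}" for j in range(3)], vals)
        theta0, _ = prox_initialize(m, spec)
        assert theta0.nunique() == 1


class TestJMLE:
    def test_duplicated_items_get_equal_difficulty(self, small_dich_matrix):
        matrix, spec = small_dich_matrix
        dup_vals = np.column_stack([matrix.values, matrix.values[:, 0]])
        spec2 = InstrumentSpec(spec.items + [ItemSpec("i0copy", "D", 2, "g")])
        m2 = ResponseMatrix(matrix.persons, spec.item_ids + ["i0copy"], dup_vals)
        res = RaschModel(m2, spec2).fit(tol=1e-4)
        assert abs(res.delta["i0"] - res.delta["i0copy"]) < 1e-3

    def test_matches_grid_oracle(self, small_dich_matrix):
        matrix, spec = small_dich_matrix
        res = RaschModel(matrix, spec).fit()
        theta_o, delta_o = grid_jmle_dichotomous(matrix.values)
        assert np.abs(res.delta.to_numpy() - delta_o).max() < 0.02
        assert np.abs(res.theta.to_numpy() - theta_o).max() < 0.02

    def test_raw_score_sufficiency(self, bank300):
        cfg, matrix, truth, result = bank300
        rows = [matrix.persons.index(p) for p in result.persons]
        raw = matrix.values[rows].sum(axis=1)
        theta = result.theta.to_numpy()
        order = np.argsort(raw)
        # equal raw -> equal theta; higher raw -> strictly higher theta
        for a, b in zip(order, order[1:]):
            if raw[a] == raw[b]:
                assert abs(theta[a] - theta[b]) < 1e-6
            else:
                assert theta[b] > theta[a]

    def test_translation_invariance_of_solution(self):
        import dataclasses
        cfg = rk.dichotomous_bank_config(n_persons=120, n_items=10)
        shifted = dataclasses.replace(
            cfg, theta_mean=1.0,
            delta={k: v + 1.0 for k, v in cfg.delta.items()})
        m1, _ = rk.generate(cfg, seed=5)
        m2, _ = rk.generate(shifted, seed=5)
        # same seed + shifted parameters give identical responses ...
        np.testing.assert_array_equal(m1.values, m2.values)
        # ... hence identical centred calibrations
        r1 = RaschModel(m1, cfg.spec).fit()
        r2 = RaschModel(m2, shifted.spec).fit()
        np.testing.assert_allclose(r1.delta, r2.delta, atol=1e-9)

    def test_divergence_guard(self, small_dich_matrix):
        matrix, spec = small_dich_matrix
        with pytest.raises(rk.model.DivergenceError):
            RaschModel(matrix, spec).fit(divergence_limit=0.3)

    def test_nonconvergence_flagged_not_raised(self, small_dich_matrix):
        matrix, spec = small_dich_matrix
        res = RaschModel(matrix, spec).fit(max_iter=1)
        assert not res.converged
        assert res.n_iter == 1 and len(res.trace) == 1

    def test_loglik_nondecreasing_over_trace(self, small_dich_matrix):
        matrix, spec = small_dich_matrix
        res = RaschModel(matrix, spec).fit(tol=1e-5)
        lls = [e["loglik"] for e in res.trace]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_polytomous_recovery_modest_n(self):
        # 3 rating-scale items sharing thresholds + known tau signs recovered
        items = [ItemSpec(f"s{j}", "S", 4, "quad") for j in range(6)]
        spec = InstrumentSpec(items)
        cfg = rk.GenerationConfig(
            spec=spec, n_persons=400,
            delta={f"s{j}": d for j, d in enumerate(np.linspace(-1, 1, 6))},
            taus={"quad": [-1.0, 0.0, 1.0]}, severity_theta_shift=0.0)
        m, truth = rk.generate(cfg, seed=11)
        res = RaschModel(m, spec).fit()
        tau_hat = res.taus["quad"]
        np.testing.assert_allclose(tau_hat, [-1.0, 0.0, 1.0], atol=0.35)
        true_d = truth.delta_series().loc[res.delta.index]
        r = np.corrcoef(res.delta, true_d - true_d.mean())[0, 1]
        assert r > 0.95


class TestExtremes:
    def make_result(self):
        spec = InstrumentSpec([ItemSpec(f"i{j}", "D", 2, "g") for j in range(5)])
        vals = np.array([
            [1, 1, 1, 1, 1],   # perfect
            [0, 0, 0, 0, 0],   # zero
            [1, 0, 1, 0, 1],
            [0, 1, 0, 1, 0],
            [1, 1, 0, 0, 1],
            [0, 0, 1, 1, 0],
            [1, 1, 1, 0, 0],
            [0, 0, 0, 1, 1],
        ])
        m = ResponseMatrix([f"p{i}" for i in range(8)],
                           [f"i{j}" for j in range(5)], vals)
        return RaschModel(m, spec).fit()

    def test_extremes_removed_and_extrapolated(self):
        res = self.make_result()
        assert set(res.extreme_persons) == {"p0", "p1"}
        assert np.isfinite(res.extreme_theta).all()
        assert res.extreme_theta["p0"] > res.theta.max()
        assert res.extreme_theta["p1"] < res.theta.min()

    def test_smaller_adjustment_more_extreme_measure(self):
        res = self.make_result()
        items = [f"i{j}" for j in range(5)]
        t25 = measure_extreme(5, items, res, adjustment=0.25)
        t30 = measure_extreme(5, items, res, adjustment=0.3)
        assert abs(t25) >= abs(t30)
        z25 = measure_extreme(0, items, res, adjustment=0.25)
        z30 = measure_extreme(0, items, res, adjustment=0.3)
        assert abs(z25) >= abs(z30)

    def test_non_extreme_score_rejected(self):
        res = self.make_result()
        with pytest.raises(ValueError, match="not extreme"):
            measure_extreme(3, [f"i{j}" for j in range(5)], res)
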