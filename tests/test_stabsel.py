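"""Stability selection: q bound, path oracle, PFER control, AIC ladder."""

import numpy as np
import pandas as pd
import pytest

from mscmorph.stabsel import (StabilityConfig, aic_gaussian, aic_ladder,
                              lasso_first_q, q_from_pfer, stability_selection)


class TestQFromPfer:
    def test_published_bound_examples(self):
        assert q_from_pfer(2, 0.75, 50) == 7   # floor(sqrt(2*0.5*50))
        assert q_from_pfer(2, 0.75, 2) == 1
        assert q_from_pfer(2, 0.75, 40) == 6

    def test_limiting_case_selects_everything(self):
        p = 13
        assert q_from_pfer(pfer=p, theta=1.0, p=p) == p

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            q_from_pfer(2, 0.75, 0)
        with pytest.raises(ValueError):
            q_from_pfer(2, 0.4, 10)
        with pytest.raises(ValueError):
            q_from_pfer(0, 0.75, 10)


def _coordinate_descent_entry_set(X, y, q, n_lambda=300):
    """Independent oracle: Lasso by coordinate descent on a decreasing
    lambda grid; returns the first q variables to become active."""
    n, p = X.shape
    lam_max = np.max(np.abs(X.T @ y)) / n
    lams = lam_max * np.logspace(0, -4, n_lambda)
    beta = np.zeros(p)
    seen: list[int] = []
    for lam in lams:
        for _ in range(200):
            beta_old = beta.copy()
            for j in range(p):
                r = y - X @ beta + X[:, j] * beta[j]
                rho = X[:, j] @ r / n
                z = (X[:, j] ** 2).sum() / n
                beta[j] = np.sign(rho) * max(abs(rho) - lam, 0) / z
            if np.max(np.abs(beta - beta_old)) < 1e-10:
                break
        for j in np.nonzero(np.abs(beta) > 1e-8)[0]:
            if j not in seen:
                seen.append(int(j))
        if len(seen) >= q:
            break
    return set(seen[:q])


class TestLassoFirstQ:
    def test_perfect_predictor_enters_first(self, rng):
        X = rng.standard_normal((30, 8))
        y = X[:, 3].copy()
        assert 3 in lasso_first_q(X, y, 1)

    def test_q_equals_p_selects_all(self, rng):
        X = rng.standard_normal((40, 5))
        y = X @ rng.standard_normal(5) + 0.1 * rng.standard_normal(40)
        assert lasso_first_q(X, y, 5) == {0, 1, 2, 3, 4}

    def test_matches_coordinate_descent_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            X = rng.standard_normal((20, 6))
            X = (X - X.mean(0)) / X.std(0)
            y = X @ np.array([1.5, 0.0, -0.8, 0.0, 0.4, 0.0])
            y = y + 0.3 * rng.standard_normal(20)
            y = y - y.mean()
            assert lasso_first_q(X, y, 3) == _coordinate_descent_entry_set(
                X, y, 3)

    def test_zero_variance_column_excluded_with_warning(self, rng):
        X = rng.standard_normal((25, 4))
        X[:, 2] = 1.0
        y = X[:, 0] + 0.1 * rng.standard_normal(25)
        with pytest.warns(UserWarning, match="zero-variance"):
            selected = lasso_first_q(X, y, 3)
        assert 2 not in selected


class TestStabilitySelection:
    def test_deterministic_in_seed(self, rng):
        X = rng.standard_normal((40, 12))
        y = rng.standard_normal(40)
        cfg = StabilityConfig(seed=5)
        a = stability_selection(X, y, cfg)
        b = stability_selection(X, y, cfg)
        assert np.array_equal(a.selection_probability,
                              b.selection_probability)
        assert a.q_used == q_from_pfer(2, 0.75, 12)

    def test_probabilities_are_exact_frequencies(self, rng):
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)
        res = stability_selection(X, y, StabilityConfig(seed=1))
        counts = np.zeros(6)
        for s in res.subsample_sets:
            for j in s:
                counts[j] += 1
        assert np.array_equal(res.selection_probability,
                              counts / res.n_subsamples)

    def test_permuting_columns_permutes_probabilities(self, rng):
        X = rng.standard_normal((36, 7))
        y = X[:, 2] + 0.5 * rng.standard_normal(36)
        perm = np.array([3, 0, 6, 1, 5, 2, 4])
        res1 = stability_selection(X, y, StabilityConfig(seed=9))
        res2 = stability_selection(X[:, perm], y, StabilityConfig(seed=9))
        assert np.array_equal(res2.selection_probability,
                              res1.selection_probability[perm])

    def test_strong_predictor_is_stably_selected(self):
        rng = np.random.default_rng(4)
        hits = 0
        for s in range(15):
            X = rng.standard_normal((56, 20))
            y = X[:, 7] + 0.8 * rng.standard_normal(56)  # ~60% variance
            res = stability_selection(X, y, StabilityConfig(seed=s))
            hits += res.selection_probability[7] >= 0.75
        assert hits >= 13

    def test_null_design_respects_pfer_budget(self):
        rng = np.random.default_rng(11)
        sizes = []
        for s in range(25):
            X = rng.standard_normal((56, 40))
            y = rng.standard_normal(56)
            res = stability_selection(X, y, StabilityConfig(seed=s))
            sizes.append(len(res.stable_set))
        assert np.mean(sizes) <= 2.0

    def test_too_small_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            stability_selection(rng.standard_normal((8, 4)),
                                rng.standard_normal(8), StabilityConfig())


class TestAicLadder:
    def test_perfect_covariate_beats_intercept(self, rng):
        x = rng.standard_normal(30)
        table = pd.DataFrame({"x": x, "y": 2 * x + 1})
        ladder = aic_ladder(table, "y", ["x"], m2_size=1)
        assert ladder.aic["m1"] < ladder.aic["m0"]
        assert np.isfinite(ladder.aic["m1"])

    def test_null_covariates_leave_intercept_best_mostly(self):
        rng = np.random.default_rng(2)
        wins = 0
        for _ in range(25):
            table = pd.DataFrame(rng.standard_normal((40, 5)),
                                 columns=list("abcde"))
            table["y"] = rng.standard_normal(40)
            ladder = aic_ladder(table, "y", list("abcd"))
            wins += ladder.best() == "m0"
        assert wins >= 15

    def test_single_planted_predictor_prefers_m1_over_m2(self):
        """Extra covariates beyond the real one do not improve AIC in the
        majority of replicates."""
        rng = np.random.default_rng(6)
        m1_wins = 0
        for _ in range(25):
            table = pd.DataFrame(rng.standard_normal((56, 4)),
                                 columns=list("abcd"))
            table["y"] = table["a"] + 0.8 * rng.standard_normal(56)
            ladder = aic_ladder(table, "y", list("abcd"))
            m1_wins += ladder.aic["m1"] <= ladder.aic["m2"]
        assert m1_wins >= 13

    def test_log_transform_requires_positive_outcome(self):
        table = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 2, -3, 4]})
        with pytest.raises(ValueError):
            aic_ladder(table, "y", ["x"], log_outcome=True)

    def test_collinear_covariates_warn_but_fit(self, rng):
        x = rng.standard_normal(30)
        table = pd.DataFrame({"x1": x, "x2": 2 * x, "y": x})
        with pytest.warns(UserWarning, match="collinear"):
            ladder = aic_ladder(table, "y", ["x1", "x2"], m2_size=2)
        assert np.isfinite(ladder.aic["m2"])

    def test_aic_formula(self):
        assert aic_gaussian(rss=10.0, n=20, k=3) == pytest.approx(
            20 * np.log(0.5) + 6)
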