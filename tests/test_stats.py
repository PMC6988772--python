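"""Screening statistics: permutation oracles, ROUT behavior, ROC properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscmorph.stats import (ConstantInputError, correlate_screen, roc_auc,
                            rout_outliers, spearman, ttest_unpaired)


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self):
        x = np.array([0.3, 1.2, -0.5, 2.0, 0.9, -1.4])
        rs, _ = spearman(x, x**3)
        assert rs == pytest.approx(1.0)
        rs, _ = spearman(x, -x)
        assert rs == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_p_matches_full_permutation_oracle(self):
        """n=8: p agrees with brute-force enumeration over all 8! orderings
        using the sum-of-squared-rank-differences route."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.9])
        y = np.array([2.7, 1.8, 2.8, 1.2, 8.2, 8.4, 5.9, 0.4])
        rs_obs, p_obs = spearman(x, y)
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        n = len(x)
        d2_obs = np.sum((rx - ry) ** 2)
        rs_check = 1 - 6 * d2_obs / (n * (n**2 - 1))
        assert rs_obs == pytest.approx(rs_check)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            d2 = np.sum((rx - np.array(perm)) ** 2)
            rs_perm = 1 - 6 * d2 / (n * (n**2 - 1))
            count += abs(rs_perm) >= abs(rs_obs) - 1e-12
            total += 1
        assert p_obs == pytest.approx(count / total)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        rs, p = spearman(x, y)
        rs2, p2 = spearman(np.exp(x), y)
        rs3, p3 = spearman(x, 3 * y - 7)
        assert rs2 == pytest.approx(rs) and p2 == pytest.approx(p)
        assert rs3 == pytest.approx(rs) and p3 == pytest.approx(p)


class TestRout:
    def test_q_zero_removes_nothing(self, rng):
        x = rng.uniform(0, 10, 30)
        y = x + rng.standard_normal(30)
        y[0] += 50
        assert rout_outliers(x, y, q_pct=0.0).all()

    def test_gross_outliers_removed_clean_points_kept(self, rng):
        x = rng.uniform(0, 10, 50)
        y = 2 * x + 1 + rng.standard_normal(50)
        y[:5] += 10 * np.sign(rng.standard_normal(5))
        mask = rout_outliers(x, y, q_pct=1.0)
        assert not mask[:5].any()
        assert mask[5:].sum() >= 43

    def test_clean_data_rarely_loses_points(self):
        rng = np.random.default_rng(7)
        removed = []
        for _ in range(100):
            x = rng.uniform(0, 10, 50)
            y = -x + 3 + rng.standard_normal(50)
            removed.append(50 - rout_outliers(x, y).sum())
        assert np.mean(np.array(removed) <= 1) >= 0.95

    def test_small_sample_warns(self, rng):
        with pytest.warns(UserWarning, match="unreliable"):
            rout_outliers(np.arange(6.0), rng.standard_normal(6))

    def test_degenerate_size_rejected(self):
        with pytest.raises(ValueError):
            rout_outliers([1.0, 2.0], [1.0, 2.0])


class TestScreen:
    def test_no_outliers_keeps_all_donors(self, rng):
        table = pd.DataFrame({
            "donor_id": [f"D{i}" for i in range(20)],
            "x": np.linspace(0, 1, 20),
            "y": np.linspace(0, 1, 20) + 0.01 * rng.standard_normal(20),
        })
        res = correlate_screen(table, [("x", "y")])[0]
        assert res.n_used == 20 and not res.outlier_ids
        assert res.n_used + len(res.outlier_ids) == len(table)

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            correlate_screen(pd.DataFrame({"a": [1.0] * 12}), [("a", "b")])

    def test_planted_outlier_attributed_to_donor(self, rng):
        x = np.linspace(0, 10, 30)
        y = 2 * x + 0.3 * rng.standard_normal(30)
        y[4] += 40
        table = pd.DataFrame({"donor_id": [f"D{i}" for i in range(30)],
                              "x": x, "y": y})
        res = correlate_screen(table, [("x", "y")])[0]
        assert res.outlier_ids == ["D4"]


class TestTTest:
    def test_identical_groups_give_t_zero(self):
        t, p = ttest_unpaired([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_shifted_groups_strongly_significant(self):
        _, p = ttest_unpaired([1, 2, 3], [11, 12, 13])
        assert p < 0.001

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ConstantInputError):
            ttest_unpaired([2.0, 2.0], [2.0, 2.0])

    def test_p_tracks_exact_permutation_distribution(self):
        """Small fixed groups: Student p close to the enumerated
        permutation p of the t statistic."""
        a = np.array([0.2, 1.1, -0.4, 0.9])
        b = np.array([1.8, 2.4, 1.2, 3.1])
        t_obs, p_obs = ttest_unpaired(a, b)
        pooled = np.concatenate([a, b])
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(8) if i not in idx]]
            t_perm, _ = ttest_unpaired(ga, gb)
            count += abs(t_perm) >= abs(t_obs) - 1e-12
            total += 1
        assert abs(p_obs - count / total) < 0.15


class TestRoc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12.0], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0 and r.ci_low <= r.auc <= r.ci_high
        assert r.n_pos == 3 and r.n_neg == 3

    def test_matches_pair_counting_brute_force(self):
        """AUC equals P(random positive outranks random negative), ties
        counted half, on random small instances."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = rng.integers(6, 20)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(2, n - 1)] = 1
            rng.shuffle(labels)
            scores = rng.integers(0, 6, n).astype(float)  # forces ties
            if labels.min() == labels.max():
                continue
            r = roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert r.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_orientation_metadata(self):
        r = roc_auc([3, 2, 1, 0.0], [1, 1, 0, 0])
        assert r.auc == 1.0 and r.direction == 1
        r = roc_auc([0, 1, 2, 3.0], [1, 1, 0, 0])
        assert r.auc == 0.0 and r.direction == -1 and r.auc_oriented == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_ci_brackets_auc(self, rng):
        scores = rng.standard_normal(40)
        labels = (rng.random(40) > 0.5).astype(int)
        r = roc_auc(scores, labels)
        assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0
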