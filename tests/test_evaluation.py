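"""Metrics, ensembling, stochastic evaluation, statistical comparisons."""

import numpy as np
import pytest
from scipy.stats import friedmanchisquare

import spottune3d as st
from spottune3d.evaluation import (compare_networks, compute_metrics,
                                   ensemble_mean, friedman_test,
                                   stochastic_eval, true_class_probability)


def _brute_force_auc(p, y):
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return wins / (len(pos) * len(neg))


def _brute_force_ap(p, y):
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    tp, ap = 0, 0.0
    n_pos = int(y.sum())
    for i, yi in enumerate(y_sorted, start=1):
        if yi == 1:
            tp += 1
            ap += tp / i
    return ap / n_pos


class TestMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        res = compute_metrics(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert res.auc == 1.0 and res.ap == 1.0
        assert res.sen == 1.0 and res.spe == 1.0 and res.m == 1.0

    def test_all_ties_give_half_auc(self):
        y = np.array([0, 1, 0, 1])
        res = compute_metrics(np.full(4, 0.5), y)
        assert res.auc == 0.5

    def test_hand_case_matches_pair_counting(self):
        p = np.array([0.9, 0.4, 0.65, 0.65, 0.2, 0.7])
        y = np.array([1, 0, 1, 0, 0, 1])
        res = compute_metrics(p, y)
        assert res.auc == pytest.approx(_brute_force_auc(p, y), abs=1e-12)

    def test_random_problems_match_oracles(self):
        # 200 random 20-sample problems against brute-force AUC/AP oracles
        r = np.random.default_rng(2024)
        for _ in range(200):
            y = np.zeros(20, dtype=int)
            y[r.choice(20, size=r.integers(1, 20), replace=False)] = 1
            p = np.round(r.random(20), 2)     # induce occasional ties
            res = compute_metrics(p, y)
            assert res.auc == pytest.approx(_brute_force_auc(p, y),
                                            abs=1e-12)
            if len(np.unique(p)) == len(p):    # sequential oracle needs no ties
                assert res.ap == pytest.approx(_brute_force_ap(p, y),
                                               abs=1e-12)

    def test_single_class_flagged_undefined(self):
        res = compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]))
        assert res.undefined and np.isnan(res.auc)

    def test_monotone_transform_invariance(self):
        r = np.random.default_rng(5)
        p = r.random(30)
        y = (r.random(30) < 0.4).astype(int)
        a = compute_metrics(p, y).auc
        b = compute_metrics(1 / (1 + np.exp(-5 * p)), y).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestEnsemble:
    def test_idempotent_on_identical_inputs(self):
        v = np.array([0.1, 0.9, 0.5])
        assert np.allclose(ensemble_mean([v, v, v]), v)

    def test_pairwise_mean(self):
        out = ensemble_mean([np.array([0.2]), np.array([0.8])])
        assert out[0] == pytest.approx(0.5)

    def test_mean_of_means_equals_flat_mean_for_equal_folds(self):
        r = np.random.default_rng(0)
        mods = [[r.random(6) for _ in range(3)] for _ in range(3)]
        per_mod = [ensemble_mean(folds) for folds in mods]
        nested = ensemble_mean(per_mod)
        flat = ensemble_mean([f for folds in mods for f in folds])
        assert np.allclose(nested, flat, atol=1e-12)

    def test_misaligned_patients_listed(self):
        with pytest.raises(ValueError, match="P9"):
            ensemble_mean([np.array([0.1, 0.2]), np.array([0.3, 0.4])],
                          patient_ids=[["P1", "P2"], ["P1", "P9"]])

    def test_output_stays_in_unit_interval(self):
        r = np.random.default_rng(1)
        vecs = [r.random(10) for _ in range(4)]
        out = ensemble_mean(vecs)
        assert np.all((out >= 0) & (out <= 1))

    def test_roc_pr_points_exportable(self):
        from spottune3d.evaluation import roc_pr_points
        y = np.array([0, 0, 1, 1])
        df = roc_pr_points(np.array([0.1, 0.6, 0.4, 0.9]), y)
        assert set(df.curve) == {"roc", "pr"}
        assert df.x.between(0, 1).all() and df.y.between(0, 1).all()


class TestStochasticEval:
    def test_deterministic_given_seed(self):
        r = np.random.default_rng(0)
        base = r.random(12)
        y = (r.random(12) < 0.5).astype(int)

        def predict(s_idx, seed):
            rr = np.random.default_rng([seed, s_idx])
            return np.clip(base + 0.05 * rr.normal(size=12), 0, 1)

        a = stochastic_eval(predict, y, n_samples=100, seed=42)
        b = stochastic_eval(predict, y, n_samples=100, seed=42)
        assert np.array_equal(a.probabilities, b.probabilities)
        assert a.auc == b.auc and a.ap == b.ap

    def test_degenerate_single_pass(self):
        y = np.array([0, 1, 0, 1])
        p = np.array([0.2, 0.7, 0.4, 0.9])
        res = stochastic_eval(lambda i, s: p, y, n_samples=100, seed=42,
                              stochastic=False)
        assert np.array_equal(res.probabilities, p)

    def test_sample_standard_error_bound(self):
        # binomial extreme: per-patient SE of the 100-sample mean <= 0.05
        r = np.random.default_rng(3)

        def predict(s_idx, seed):
            rr = np.random.default_rng([seed, s_idx])
            return (rr.random(10) < 0.5).astype(float)

        draws = np.stack([predict(i, 42) for i in range(100)])
        se = draws.std(axis=0) / np.sqrt(100)   # empirical sd is at most 0.5
        assert np.all(se <= 0.5 / np.sqrt(100) + 1e-9)

    def test_invalid_sample_count(self):
        with pytest.raises(ValueError):
            stochastic_eval(lambda i, s: np.zeros(2), np.array([0, 1]), 0)


class TestComparison:
    def test_identical_vectors_statistic_zero_p_one(self):
        v = np.array([0.2, 0.5, 0.7, 0.9])
        stat, p = friedman_test(np.column_stack([v, v, v]))
        assert stat == 0.0 and p == 1.0

    def test_hand_case_matches_rank_formula(self):
        # 4 subjects × 3 models, no ties: classic Friedman formula
        x = np.array([[0.1, 0.2, 0.3],
                      [0.6, 0.4, 0.5],
                      [0.7, 0.9, 0.8],
                      [0.2, 0.3, 0.1]])
        n, k = x.shape
        ranks = np.argsort(np.argsort(x, axis=1), axis=1) + 1
        rj = ranks.sum(axis=0)
        expected = 12.0 / (n * k * (k + 1)) * np.sum(rj ** 2) - 3 * n * (k + 1)
        stat, _ = friedman_test(x)
        assert stat == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_without_ties(self):
        r = np.random.default_rng(7)
        x = r.random((12, 4))
        stat, p = friedman_test(x)
        ref_stat, ref_p = friedmanchisquare(*(x[:, j] for j in range(4)))
        assert stat == pytest.approx(ref_stat, rel=1e-10)
        assert p == pytest.approx(ref_p, rel=1e-10)

    def test_permutation_of_patients_invariant(self):
        r = np.random.default_rng(9)
        scores = {c: r.random(15) for c in ("spottune", "random", "transfer")}
        out1 = compare_networks(scores, alpha=0.5)
        perm = r.permutation(15)
        out2 = compare_networks({c: v[perm] for c, v in scores.items()},
                                alpha=0.5)
        assert out1["friedman_p"] == pytest.approx(out2["friedman_p"])
        if out1["nemenyi_p"]:
            for pair, val in out1["nemenyi_p"].items():
                assert out2["nemenyi_p"][pair] == pytest.approx(val)

    def test_nemenyi_reported_only_when_significant(self):
        v = np.array([0.2, 0.5, 0.7, 0.9])
        out = compare_networks({"a": v, "b": v, "c": v})
        assert out["nemenyi_p"] is None

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            compare_networks({"a": np.zeros(3), "b": np.zeros(4),
                              "c": np.zeros(3)})

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            compare_networks({"a": np.zeros(3), "b": np.zeros(3)})

    def test_true_class_probability(self):
        p = np.array([0.8, 0.3])
        y = np.array([1, 0])
        assert np.allclose(true_class_probability(p, y), [0.8, 0.7])
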