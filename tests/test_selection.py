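import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phenoface.selection import (
    SelectionConfig,
    balanced_class_weights,
    default_k_grid,
    feature_screening,
    fisher_compare,
    loocv_curve,
    mann_whitney,
    optimal_k,
    overall_from_group_accuracies,
    relative_improvement,
    stratified_evaluation,
    svm_rfe_ranking,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def mann_whitney_enumeration_oracle(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        ranks = {}
        s = sorted(pooled)
        # midranks
        i = 0
        rank_of = []
        while i < len(s):
            j = i
            while j < len(s) and s[j] == s[i]:
                j += 1
            rank_of.append((s[i], (i + j + 1) / 2.0))
            i = j
        lookup = dict(rank_of)
        r1 = sum(lookup[v] for v in group_a)
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_stat(a, b)
    total = 0
    n_le = n_ge = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        total += 1
        n_le += u <= u_obs + 1e-12
        n_ge += u >= u_obs - 1e-12
    return u_obs, min(1.0, 2.0 * min(n_le, n_ge) / total)


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

class TestBalancedWeights:
    def test_imbalanced_cohort(self):
        labels = ["WBS"] * 286 + ["NS"] * 161
        w = balanced_class_weights(labels)
        assert w[0] == pytest.approx(447 / 572)
        assert w[-1] == pytest.approx(447 / 322)
        assert w[:286].sum() == pytest.approx(223.5)
        assert w[286:].sum() == pytest.approx(223.5)

    def test_balanced_cohort_unit_weights(self):
        assert balanced_class_weights(["A", "B"] * 5) == pytest.approx(np.ones(10))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            balanced_class_weights(["A"] * 5)


class TestRFE:
    @pytest.mark.parametrize("seed", range(20))
    def test_separating_feature_ranked_first(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        y = np.array(["A"] * 20 + ["B"] * 20)
        X = pd.DataFrame(
            rng.normal(size=(n, 10)), columns=[f"f{i:02d}" for i in range(10)]
        )
        X["f03"] = np.where(y == "A", 1.0, -1.0) + 0.05 * rng.normal(size=n)
        ranking = svm_rfe_ranking(X, y, balanced_class_weights(y))
        assert ranking[0] == "f03"

    def test_duplicated_feature_adjacent_ranks(self):
        rng = np.random.default_rng(3)
        n = 30
        y = np.array(["A"] * 15 + ["B"] * 15)
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=list("abcdef"))
        X["a"] = np.where(y == "A", 1.0, -1.0) + 0.3 * rng.normal(size=n)
        X["b"] = X["a"]  # exact duplicate: identical |coefficient| every round
        ranking = svm_rfe_ranking(X, y, balanced_class_weights(y))
        assert abs(ranking.index("a") - ranking.index("b")) == 1

    def test_single_round_equals_coefficient_order(self):
        from sklearn.svm import LinearSVC

        rng = np.random.default_rng(5)
        n, p = 50, 8
        y = np.array(["A"] * 25 + ["B"] * 25)
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
        X["f0"] += np.where(y == "A", 1.5, -1.5)
        X["f5"] += np.where(y == "A", 0.7, -0.7)
        ranking = svm_rfe_ranking(
            X, y, balanced_class_weights(y), coarse_step=1.0, fine_threshold=0
        )
        Z = (X - X.mean()) / X.std(ddof=0)
        clf = LinearSVC(C=1.0, dual=False, tol=1e-5, max_iter=5000)
        clf.fit(Z, y, sample_weight=balanced_class_weights(y))
        coef_order = list(X.columns[np.argsort(-np.abs(clf.coef_[0]))])
        assert ranking == coef_order

    def test_planted_recovery_among_noise(self):
        """>= 80% of independent planted features reach the top-2p ranking."""
        recoveries = []
        planted = [f"sig{i}" for i in range(5)]
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, p_noise = 200, 500
            y = np.array(["A"] * 100 + ["B"] * 100)
            X = pd.DataFrame(
                rng.normal(size=(n, p_noise)),
                columns=[f"n{i:03d}" for i in range(p_noise)],
            )
            for f in planted:
                X[f] = rng.normal(size=n) + np.where(y == "A", 0.75, -0.75)  # d = 1.5
            ranking = svm_rfe_ranking(X, y, balanced_class_weights(y))
            top = set(ranking[: 2 * len(planted)])
            recoveries.append(len(top & set(planted)) / len(planted))
        assert np.mean(recoveries) >= 0.8


class TestOptimalK:
    def test_convergence_rule(self):
        aucs = {1: 0.70, 2: 0.80, 5: 0.90, 10: 0.905, 20: 0.906}
        assert optimal_k(aucs, epsilon=0.01) == 5

    def test_flat_curve_returns_smallest(self):
        assert optimal_k({3: 0.9, 7: 0.9, 12: 0.9}, epsilon=0.005) == 3

    def test_large_epsilon_returns_smallest(self):
        assert optimal_k({2: 0.6, 4: 0.95}, epsilon=0.5) == 2


class TestMannWhitney:
    def test_complete_separation_small(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize("n1,n2,seed", [(2, 3, 0), (3, 3, 1), (4, 4, 2), (4, 5, 3), (5, 5, 4), (3, 6, 5)])
    def test_agrees_with_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        pool = rng.permutation(np.arange(1.0, n1 + n2 + 1.0))  # distinct, tie-free
        a, b = pool[:n1], pool[n1:]
        u_impl, p_impl = mann_whitney(a, b)
        u_oracle, p_oracle = mann_whitney_enumeration_oracle(a, b)
        assert u_impl == pytest.approx(u_oracle)
        assert p_impl == pytest.approx(p_oracle, abs=1e-12)

    def test_large_sample_against_permutation_oracle(self):
        rng = np.random.default_rng(7)
        a = np.round(rng.normal(0.0, 1.0, 25), 1)   # rounding induces ties
        b = np.round(rng.normal(0.6, 1.0, 25), 1)
        _, p_impl = mann_whitney(a, b)

        pooled = np.concatenate([a, b])
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        u_obs = ranks[:25].sum() - 25 * 26 / 2.0
        n_perm = 100_000
        perms = np.argsort(rng.random((n_perm, 50)), axis=1)[:, :25]
        u_perm = ranks[perms].sum(axis=1) - 25 * 26 / 2.0
        center = 25 * 25 / 2.0
        p_perm = np.mean(np.abs(u_perm - center) >= abs(u_obs - center) - 1e-9)
        se = math.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert p_impl == pytest.approx(p_perm, abs=max(5 * se, 5e-4))


class TestFisher:
    def test_small_table(self):
        cmp = fisher_compare(3, 4, 1, 4)
        assert cmp.p_value == pytest.approx(0.4857, abs=5e-5)

    def test_identical_rows(self):
        assert fisher_compare(7, 10, 7, 10).p_value == 1.0

    def test_complete_separation(self):
        cmp = fisher_compare(10, 10, 0, 10)
        assert cmp.p_value == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)

    def test_agrees_with_enumeration_oracle(self):
        for ta in range(1, 9):
            for tb in range(1, 9):
                for ca in range(ta + 1):
                    for cb in range(tb + 1):
                        p_impl = fisher_compare(ca, ta, cb, tb).p_value
                        p_oracle = fisher_enumeration_oracle(
                            [[ca, ta - ca], [cb, tb - cb]]
                        )
                        assert p_impl == pytest.approx(min(1.0, p_oracle), abs=1e-9), (
                            ca, ta, cb, tb,
                        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fisher_compare(1, 0, 1, 2)
        with pytest.raises(ValueError):
            fisher_compare(5, 4, 1, 4)


class TestImprovementAndAccounting:
    @pytest.mark.parametrize(
        "acc_g,acc_s,expected",
        [(87.30, 93.65, 7.27), (83.23, 91.30, 9.70), (84.85, 87.88, 3.57),
         (85.68, 90.38, 5.49), (50.0, 50.0, 0.0)],
    )
    def test_relative_improvement(self, acc_g, acc_s, expected):
        assert relative_improvement(acc_g, acc_s) == pytest.approx(expected, abs=5e-3)

    def test_group_accuracy_recombination(self):
        correct, total, acc = overall_from_group_accuracies([87.58, 84.62], [161, 286])
        assert (correct, total) == (383, 447)
        assert acc == pytest.approx(85.68, abs=5e-3)


# ---------------------------------------------------------------------------
# LOOCV protocol
# ---------------------------------------------------------------------------

def _toy_table(seed=0, n=24, p=6, effect=2.0):
    rng = np.random.default_rng(seed)
    y = pd.Series(["A"] * (n // 2) + ["B"] * (n // 2))
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    X["f0"] += np.where(y == "A", effect / 2, -effect / 2)
    return X, y


class TestLOOCV:
    def test_full_model_point_matches_manual_loocv(self):
        from sklearn.svm import LinearSVC

        X, y = _toy_table(seed=2)
        res = loocv_curve(X, y, SelectionConfig(protocol="flat", k_grid=(X.shape[1],)))
        manual = []
        for i in range(len(X)):
            mask = np.ones(len(X), bool)
            mask[i] = False
            Xtr = X[mask]
            mu, sd = Xtr.mean(), Xtr.std(ddof=0).replace(0, 1.0)
            clf = LinearSVC(C=1.0, dual=False, tol=1e-5, max_iter=5000)
            clf.fit((Xtr - mu) / sd, y[mask],
                    sample_weight=balanced_class_weights(y[mask]))
            manual.append(clf.predict(((X.iloc[[i]] - mu) / sd))[0])
        assert res.accuracy == pytest.approx(np.mean(np.array(manual) == y.to_numpy()))

    def test_prediction_bookkeeping_identities(self):
        X, y = _toy_table(seed=3, n=30)
        res = loocv_curve(X, y, SelectionConfig(protocol="nested", k_grid=(1, 3, 6)))
        assert len(res.predictions) == len(X)
        assert set(res.predictions["subject_id"]) == set(X.index)
        per_class = res.per_class_accuracy()
        n_by_class = y.value_counts()
        recombined = sum(per_class[c] * n_by_class[c] for c in per_class) / len(y)
        assert res.accuracy == pytest.approx(recombined)
        assert len(res.selected_features) == res.k_star

    def test_planted_separation_reaches_high_accuracy(self):
        X, y = _toy_table(seed=4, n=40, effect=4.0)
        res = loocv_curve(X, y, SelectionConfig(protocol="nested"))
        assert res.accuracy >= 0.95

    def test_small_cohort_rejected(self):
        X, y = _toy_table(n=8)
        with pytest.raises(ValueError, match="at least 10"):
            loocv_curve(X, y)

    def test_class_with_single_member_rejected(self):
        X, _ = _toy_table(n=12)
        y = pd.Series(["A"] * 11 + ["B"])
        with pytest.raises(ValueError):
            loocv_curve(X, y)


class TestStratifiedEvaluation:
    def test_single_stratum_reports_coincide(self):
        X, y = _toy_table(seed=5, n=30)
        strata = ["only"] * len(X)
        report = stratified_evaluation(X, y, strata, SelectionConfig(protocol="flat", k_grid=(1, 2, 6)))
        c = report["comparison"]["only"]
        assert c["global_accuracy_pct"] == pytest.approx(
            100 * pd.DataFrame(report["global"]["predictions"]).pipe(
                lambda t: (t["true"] == t["predicted"]).mean()
            )
        )
        assert report["comparison"]["overall"]["global_accuracy_pct"] == pytest.approx(
            c["global_accuracy_pct"]
        )
        # identical cohort, identical protocol: specific model == global model
        assert report["strata"]["only"]["k_star"] == report["global"]["k_star"]
        assert c["specific_accuracy_pct"] == pytest.approx(c["global_accuracy_pct"])

    def test_stratum_missing_class_is_skipped(self, caplog):
        X, y = _toy_table(seed=6, n=30)
        strata = ["big"] * 26 + ["tiny"] * 4
        y[-4:] = "A"  # "tiny" has no class B
        report = stratified_evaluation(X, y, strata, SelectionConfig(protocol="flat", k_grid=(1, 6)))
        assert "tiny" not in report["strata"]
        assert "big" in report["strata"]


def test_feature_screening_flags_planted_feature():
    X, y = _toy_table(seed=8, n=40, effect=3.0)
    screen = feature_screening(X, y)
    assert screen["p"].idxmin() == "f0"
    assert screen.loc["f0", "p"] < 0.001
    assert (screen["q"] >= screen["p"]).all()


def test_default_k_grid_structure():
    grid = default_k_grid(800)
    assert grid[0] == 1 and grid[-1] == 800
    assert 40 in grid and 64 in grid and 512 in grid
    assert default_k_grid(5) == (1, 2, 3, 4, 5)
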