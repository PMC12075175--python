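"""Cross-validation protocol and the nonparametric statistics vs oracles."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

import emgband as eb
from emgband.evaluation import (
    compare_conditions, confusion, cross_validate, friedman_test, nemenyi_test,
    wilcoxon_exact,
)
from emgband.features import WindowedFeatures
from emgband.recording import ConfigError


def _toy_feats(n_trials_per_class=6, samples_per_trial=4, n_classes=3, T=6, C=4, F=3,
               seed=0, margin=2.5):
    """Separable-by-construction feature set with trial groups."""
    rng = np.random.default_rng(seed)
    X, y, g = [], [], []
    trial = 0
    for c in range(n_classes):
        for _ in range(n_trials_per_class):
            x = rng.standard_normal((samples_per_trial, T, C, F))
            x[:, :, c % C, :] += margin
            X.append(x)
            y.extend([c] * samples_per_trial)
            g.extend([trial] * samples_per_trial)
            trial += 1
    return WindowedFeatures(tensor=np.concatenate(X), labels=np.array(y),
                            groups=np.array(g))


class TestCrossValidate:
    def test_separable_data_scores_high(self):
        feats = _toy_feats()
        acc = cross_validate(feats, "lda", n_splits=3, seed=0)
        assert acc >= 0.95

    def test_uninformative_features_score_at_chance(self):
        # margin 0: labels carry no signal, out-of-fold accuracy ~ 1/3
        feats = _toy_feats(n_trials_per_class=8, n_classes=3, margin=0.0, seed=1)
        acc = cross_validate(feats, "lda", n_splits=4, seed=0)
        assert abs(acc - 1 / 3) < 0.15

    def test_more_folds_than_trials_is_error(self):
        feats = _toy_feats(n_trials_per_class=3)
        with pytest.raises(ConfigError):
            cross_validate(feats, "lda", n_splits=5)

    def test_windows_of_one_trial_never_split(self):
        from sklearn.model_selection import StratifiedGroupKFold
        feats = _toy_feats(n_trials_per_class=4, seed=3)
        cv = StratifiedGroupKFold(n_splits=2, shuffle=True, random_state=0)
        for tr, te in cv.split(feats.tensor, feats.labels, feats.groups):
            assert not set(feats.groups[tr]) & set(feats.groups[te])


class TestConfusion:
    def test_perfect_predictions_identity(self):
        y = np.repeat(np.arange(4), 10)
        cm = confusion(y, y, np.arange(4))
        np.testing.assert_array_equal(cm["normalized"], np.eye(4))

    def test_uniform_random_off_diagonals(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(6), 1000)
        preds = rng.integers(0, 6, 6000)
        cm = confusion(preds, labels, np.arange(6))
        assert np.all(np.abs(cm["normalized"] - 1 / 6) < 0.04)
        np.testing.assert_allclose(cm["normalized"].sum(axis=1), 1.0, atol=1e-9)

    def test_single_prediction_one_hot_row(self):
        cm = confusion(np.array([2]), np.array([1]), np.arange(3))
        assert cm["counts"][1, 2] == 1
        assert cm["counts"].sum() == 1

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigError):
            confusion(np.array([9]), np.array([0]), np.arange(3))


def wilcoxon_enumeration(d, alternative="two-sided"):
    """Exact signed-rank p by full enumeration of the 2^n sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws, float)
    if alternative == "greater":
        return float(np.mean(ws >= w_obs))
    if alternative == "less":
        return float(np.mean(ws <= w_obs))
    return float(min(1.0, 2 * min(np.mean(ws >= w_obs), np.mean(ws <= w_obs))))


def friedman_rank_formula(table):
    """Literal chi-square-of-ranks formula (no ties expected in input)."""
    table = np.asarray(table, float)
    n, k = table.shape
    ranks = np.array([np.argsort(np.argsort(row)) + 1 for row in table], float)
    Rj = ranks.mean(axis=0)
    return 12.0 * n / (k * (k + 1)) * np.sum((Rj - (k + 1) / 2) ** 2)


class TestWilcoxon:
    def test_textbook_all_positive_five(self):
        w, p = wilcoxon_exact(np.array([1.0, 2, 3, 4, 5]), alternative="greater")
        assert p == pytest.approx(1 / 32)
        # all positive ranks: the negative-rank sum is 0
        assert 5 * 6 / 2 - w == 0

    def test_identical_pairs_give_p_one(self):
        x = np.array([0.5, 0.6, 0.7])
        w, p = wilcoxon_exact(x, x)
        assert p == 1.0

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(9)
        for n in range(3, 9):
            for _ in range(5):
                d = rng.standard_normal(n)
                d = np.where(np.abs(d) < 1e-3, 1e-3, d)  # no zeros, ties improbable
                for alt in ("two-sided", "greater", "less"):
                    _, p = wilcoxon_exact(d, alternative=alt)
                    assert p == pytest.approx(wilcoxon_enumeration(d, alt), abs=1e-12)


class TestFriedman:
    def test_identical_columns_p_one_df_two(self):
        table = np.tile([[0.8, 0.8, 0.8]], (6, 1))
        chi2, df, p = friedman_test(table)
        assert (chi2, df, p) == (0.0, 2, 1.0)

    def test_statistic_matches_rank_formula_on_all_small_tables(self):
        # every assignment of within-row orderings for 4 subjects x 3 conditions
        from itertools import permutations, product as iproduct
        perms = list(permutations([1.0, 2.0, 3.0]))
        for rows in iproduct(perms, repeat=4):
            table = np.array(rows)
            chi2, df, _ = friedman_test(table)
            assert df == 2
            assert chi2 == pytest.approx(friedman_rank_formula(table), abs=1e-10)

    def test_agrees_with_scipy_on_random_tables(self):
        from scipy import stats
        rng = np.random.default_rng(11)
        for _ in range(20):
            table = rng.standard_normal((7, 3))
            chi2, _, p = friedman_test(table)
            ref = stats.friedmanchisquare(*table.T)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)


class TestNemenyi:
    def test_critical_difference_anchor(self):
        # published Nemenyi critical value for k=3, alpha=0.05 is 2.343
        # (studentized range q_.05(3, inf)/sqrt(2)); a mean-rank difference
        # exactly at CD = 2.343*sqrt(k(k+1)/(6n)) must give p ~= 0.05
        n, k = 12, 3
        base = np.tile(np.array([[1.0, 2.0, 3.0]]), (n, 1))
        got = nemenyi_test(base)  # mean-rank diffs 1 and 2
        from scipy import stats
        q = 1.0 / np.sqrt(k * (k + 1) / (6.0 * n))
        expected = stats.studentized_range.sf(q * np.sqrt(2), k, np.inf)
        assert got[0, 1] == pytest.approx(expected, rel=1e-9)
        cd = 2.343 * np.sqrt(k * (k + 1) / (6 * n))
        q_cd = cd / np.sqrt(k * (k + 1) / (6.0 * n))
        p_cd = stats.studentized_range.sf(q_cd * np.sqrt(2), k, np.inf)
        assert p_cd == pytest.approx(0.05, abs=0.001)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(13)
        table = rng.random((8, 3))
        p = nemenyi_test(table)
        np.testing.assert_allclose(p, p.T)
        np.testing.assert_allclose(np.diag(p), 1.0)


class TestCompareConditions:
    def test_bundle_structure_and_gating(self):
        rng = np.random.default_rng(17)
        n = 10
        df = pd.DataFrame({
            "medium": 0.9 + 0.02 * rng.random(n),
            "low": 0.8 + 0.02 * rng.random(n),
            "lda": 0.85 + 0.01 * rng.random(n),
            "tcn": 0.85 + 0.01 * rng.random(n),
            "stcn": 0.95 + 0.01 * rng.random(n),
        })
        out = compare_conditions(df)
        assert out["wilcoxon"]["p"] < 0.01
        assert out["friedman"]["df"] == 2
        assert out["friedman"]["p"] < 0.05
        assert "nemenyi" in out
        pm = np.asarray(out["nemenyi"]["p_matrix"])
        assert pm.shape == (3, 3)

    def test_underpowered_flag(self):
        df = pd.DataFrame({"medium": [0.9, 0.8], "low": [0.7, 0.6]})
        out = compare_conditions(df)
        assert out["underpowered"]
        assert "wilcoxon" in out
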