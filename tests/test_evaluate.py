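import math

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from hybridgo.evaluate import (
    agreement,
    compute_metrics,
    confusion_at,
    evaluate_bootstraps,
    feature_importance,
    mean_tpr,
    tpr_curve,
)


def auroc_pair_oracle(probs, labels):
    """Fraction of concordant positive-negative pairs, ties counted 1/2."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    total = 0.0
    for pp in pos:
        for pn in neg:
            total += 1.0 if pp > pn else (0.5 if pp == pn else 0.0)
    return total / (len(pos) * len(neg))


def series(vals, prefix="g"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


class TestComputeMetrics:
    def test_perfect_ranking_saturates_everything(self):
        probs = series([0.9, 0.8, 0.7, 0.2, 0.1, 0.05])
        labels = series([1, 1, 1, 0, 0, 0])
        rep = compute_metrics(probs, labels, threshold=0.5)
        assert rep.auroc == 1.0 and rep.auprc == 1.0 and rep.mcc == 1.0
        assert rep.f1 == 1.0 and rep.accuracy == 1.0

    def test_mcc_direct_formula_value(self):
        # TP=50, FP=10, FN=10, TN=50 -> 2400/3600
        probs = series([0.9] * 50 + [0.9] * 10 + [0.1] * 10 + [0.1] * 50)
        labels = series([1] * 50 + [0] * 10 + [1] * 10 + [0] * 50)
        rep = compute_metrics(probs, labels, threshold=0.5)
        assert rep.confusion == (50, 10, 10, 50)
        assert rep.mcc == pytest.approx(2400 / 3600)
        assert rep.mcc == pytest.approx(0.6667, abs=5e-5)

    def test_auroc_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(0)
        probs_vals = np.round(rng.random(30), 1)  # coarse grid forces ties
        labels_vals = rng.integers(0, 2, 30)
        labels_vals[:2] = [0, 1]  # both classes present
        rep = compute_metrics(series(probs_vals), series(labels_vals))
        assert rep.auroc == pytest.approx(
            auroc_pair_oracle(probs_vals, labels_vals), abs=1e-10
        )

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        probs_vals = rng.random(40)
        labels_vals = rng.integers(0, 2, 40)
        labels_vals[:2] = [0, 1]
        a = compute_metrics(series(probs_vals), series(labels_vals)).auroc
        squashed = 1 / (1 + np.exp(-5 * (probs_vals - 0.5)))
        b = compute_metrics(series(squashed), series(labels_vals)).auroc
        assert a == pytest.approx(b, abs=1e-12)

    def test_constant_predictor_has_zero_mcc(self):
        probs = series([0.7] * 10)
        labels = series([1] * 5 + [0] * 5)
        rep = compute_metrics(probs, labels, threshold=0.5)
        assert rep.mcc == 0.0

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics(series([0.1, 0.9]), series([1, 1]))


class TestConfusion:
    def test_threshold_zero_predicts_all_positive(self):
        probs = series([0.2, 0.8, 0.5, 0.1])
        labels = series([1, 0, 1, 0])
        tp, fp, fn, tn = confusion_at(probs, labels, threshold=0.0)
        assert (fn, tn) == (0, 0) and tp + fp == 4

    def test_threshold_above_max_predicts_all_negative(self):
        probs = series([0.2, 0.8, 0.5, 0.1])
        labels = series([1, 0, 1, 0])
        tp, fp, fn, tn = confusion_at(probs, labels, threshold=0.81)
        assert (tp, fp) == (0, 0) and fn + tn == 4

    def test_ten_gene_fixture_hand_count_at_075(self):
        probs = series([0.9, 0.8, 0.76, 0.75, 0.74, 0.6, 0.5, 0.3, 0.2, 0.1])
        labels = series([1, 1, 0, 1, 1, 0, 0, 1, 0, 0])
        # >= 0.75 predicts the first four: TP {g0,g1,g3}, FP {g2}
        assert confusion_at(probs, labels, 0.75) == (3, 1, 2, 4)


class TestTprCurve:
    def test_saturated_and_zero_threshold_limits(self):
        probs = series([1.0, 1.0, 1.0])
        curve = tpr_curve(probs, list(probs.index), [0.0, 0.5, 1.0])
        assert (curve == 1.0).all()

    def test_fixture_values_and_interval_mean(self):
        probs = series([0.2, 0.4, 0.6, 0.8])
        pos = list(probs.index)
        curve = tpr_curve(probs, pos, [0.3, 0.5])
        assert curve.tolist() == [0.75, 0.5]
        assert mean_tpr(probs, pos, [0.3, 0.5], interval=(0.3, 0.5)) == pytest.approx(0.625)
        assert tpr_curve(probs, pos, [0.0]).iloc[0] == 1.0

    def test_curve_is_non_increasing(self):
        rng = np.random.default_rng(2)
        probs = series(rng.random(50))
        curve = tpr_curve(probs, list(probs.index), list(np.linspace(0, 1, 21)))
        assert (np.diff(curve.to_numpy()) <= 1e-12).all()

    def test_empty_positives_is_error(self):
        with pytest.raises(ValueError, match="nonempty"):
            tpr_curve(series([0.5]), [], [0.5])


class TestFeatureImportance:
    def test_planted_informative_feature_ranks_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 6))
            y = (X[:, 0] + 0.3 * rng.standard_normal(200) > 0).astype(int)
            rf = RandomForestClassifier(n_estimators=50, random_state=seed).fit(X, y)
            imp = feature_importance([rf], [f"f{j}" for j in range(6)])
            hits += imp.index[0] == "f0"
        assert hits >= 19  # >= 95% of seeded runs

    def test_importances_sum_to_one_even_for_duplicated_features(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((100, 1))
        X = np.hstack([x, x, x])  # identical copies share the credit
        y = (x[:, 0] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=30, random_state=0).fit(X, y)
        imp = feature_importance([rf], ["a", "b", "c"])
        assert imp["mean_importance"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp["mean_importance"] > 0).all()

    def test_non_rf_model_rejected(self):
        tree = DecisionTreeClassifier().fit([[0.0], [1.0]], [0, 1])
        with pytest.raises(TypeError, match="random-forest"):
            feature_importance([tree], ["f0"])


class TestAgreement:
    def test_identical_and_inverted_predictions(self):
        rng = np.random.default_rng(4)
        p = series(np.concatenate([rng.uniform(0.7, 1.0, 5), rng.uniform(0.0, 0.3, 5)]))
        r, n = agreement(p, p)
        assert r == pytest.approx(1.0)
        r2, _ = agreement(p, 1 - p)
        assert r2 == pytest.approx(-1.0)
        assert n == 10

    def test_band_genes_excluded_and_r_matches_direct_formula(self):
        a = series([0.9, 0.8, 0.7, 0.3, 0.2, 0.1, 0.5, 0.55])
        b = series([0.85, 0.9, 0.65, 0.2, 0.3, 0.15, 0.9, 0.1])
        r, n = agreement(a, b, upper=0.6, lower=0.4)
        assert n == 6  # g6, g7 fall inside a's (0.4, 0.6) band
        av, bv = a.iloc[:6].to_numpy(), b.iloc[:6].to_numpy()
        ac, bc = av - av.mean(), bv - bv.mean()
        direct = (ac @ bc) / math.sqrt((ac @ ac) * (bc @ bc))
        assert r == pytest.approx(direct, abs=1e-12)

    def test_confidence_required_in_both_tables(self):
        a = series([0.9, 0.8, 0.7, 0.5, 0.5])
        b = series([0.9, 0.8, 0.7, 0.9, 0.9])
        _, n = agreement(a, b)
        assert n == 3

    def test_too_few_confident_genes_is_error(self):
        a = series([0.5, 0.5, 0.5, 0.9])
        with pytest.raises(ValueError, match="fewer than 3"):
            agreement(a, a)


class TestBootstrapAggregation:
    def test_mean_of_iteration_metrics_not_pooled(self):
        probs = {
            0: series([0.9, 0.8, 0.2, 0.1]),
            1: series([0.6, 0.7, 0.4, 0.3]),
        }
        labels = {
            0: series([1, 1, 0, 0]),
            1: series([1, 0, 1, 0]),
        }
        ev = evaluate_bootstraps(probs, labels, threshold=0.5)
        per = [r.auroc for r in ev.per_iteration]
        assert ev.mean["auroc"] == pytest.approx(np.mean(per))
        # pooled is a different quantity, computed on the concatenated table
        pooled_oracle = auroc_pair_oracle(
            np.concatenate([probs[0], probs[1]]),
            np.concatenate([labels[0], labels[1]]),
        )
        assert ev.pooled.auroc == pytest.approx(pooled_oracle)
        assert ev.pooled.auroc != pytest.approx(ev.mean["auroc"])
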