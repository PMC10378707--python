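"""Metrics, cross-validation, the Bayesian network, and the region/band
harness."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import precision_score, recall_score

from mwl_eeg import (
    ClassifierSpec,
    compute_metrics,
    crossvalidate,
    make_estimator,
    region_band_harness,
)
from mwl_eeg.bnn import BNNConfig, MCDropoutBNN
from mwl_eeg.features import BAND_NAMES
from mwl_eeg.modeling import region_band_columns

from oracles import brute_metrics


# ---------------------------------------------------------------------------
# metrics


def test_perfect_predictions_score_one():
    y = np.array(["a", "b", "c"] * 10)
    rep = compute_metrics(y, y)
    assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0


def test_one_vs_rest_counts_hand_example():
    """TP=50, FP=10, FN=20, TN=120 for class 1 -> precision 50/60,
    recall 50/70, accuracy 170/200."""
    y_true = np.array([1] * 70 + [0] * 130)
    y_pred = np.array([1] * 50 + [0] * 20 + [1] * 10 + [0] * 120)
    rep = compute_metrics(y_true, y_pred)
    c1 = rep.per_class["1"]
    assert (c1["TP"], c1["FP"], c1["FN"], c1["TN"]) == (50, 10, 20, 120)
    assert np.isclose(c1["precision"], 50 / 60)
    assert np.isclose(c1["recall"], 50 / 70)
    assert np.isclose(rep.accuracy, 170 / 200)


def test_random_predictions_score_near_chance():
    rng = np.random.default_rng(1)
    n = 10_000
    y_true = np.repeat([0, 1, 2], n // 3)
    y_pred = rng.integers(0, 3, len(y_true))
    rep = compute_metrics(y_true, y_pred)
    assert abs(rep.accuracy - 1 / 3) < 0.02


def test_metrics_match_confusion_matrix_oracle_on_random_instances():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = rng.integers(10, 50)
        y_true = rng.integers(0, 3, n)
        y_pred = rng.integers(0, 3, n)
        rep = compute_metrics(y_true, y_pred)
        oracle = brute_metrics(y_true, y_pred)
        assert np.isclose(rep.accuracy, oracle["accuracy"])
        assert np.isclose(rep.precision, oracle["precision"])
        assert np.isclose(rep.recall, oracle["recall"])


def test_macro_averages_match_sklearn():
    rng = np.random.default_rng(3)
    y_true = rng.integers(0, 3, 200)
    y_pred = rng.integers(0, 3, 200)
    rep = compute_metrics(y_true, y_pred)
    assert np.isclose(rep.precision,
                      precision_score(y_true, y_pred, average="macro",
                                      zero_division=0))
    assert np.isclose(rep.recall,
                      recall_score(y_true, y_pred, average="macro",
                                   zero_division=0))


def test_f1_variants():
    y_true = np.array([0, 0, 1, 1, 2, 2, 0, 1])
    y_pred = np.array([0, 1, 1, 1, 2, 0, 0, 2])
    std = compute_metrics(y_true, y_pred)
    assert np.isclose(std.f1, 2 * std.precision * std.recall
                      / (std.precision + std.recall))
    lit = compute_metrics(y_true, y_pred, f1_variant="accuracy")
    assert np.isclose(lit.f1, 2 * lit.accuracy * lit.recall
                      / (lit.accuracy + lit.recall))


def test_empty_input_rejected():
    with pytest.raises(ValueError, match="empty"):
        compute_metrics([], [])


# ---------------------------------------------------------------------------
# cross-validation


def _gaussian_classes(n_per=100, sep=6.0, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for cls in range(3):
        X = rng.standard_normal((n_per, dim)) + cls * sep
        for x in X:
            rows.append({**{f"g{i}": v for i, v in enumerate(x)}, "mwl": str(cls)})
    return pd.DataFrame(rows)


def test_well_separated_classes_near_perfect_accuracy():
    df = _gaussian_classes()
    rep = crossvalidate(ClassifierSpec(kind="KNN", k=1, seed=0), df, folds=10)
    assert rep.mean("accuracy") >= 0.99


def test_permuted_labels_score_at_chance():
    df = _gaussian_classes(seed=4)
    rng = np.random.default_rng(5)
    df["mwl"] = rng.permutation(df["mwl"].to_numpy())
    rep = crossvalidate(ClassifierSpec(kind="KNN", k=1, seed=0), df, folds=10)
    assert abs(rep.mean("accuracy") - 1 / 3) <= 3 * max(rep.std("accuracy"), 0.02)


def test_crossvalidate_is_deterministic():
    df = _gaussian_classes(n_per=30, sep=1.0, seed=6)
    a = crossvalidate(ClassifierSpec(kind="RF", n_trees=20, seed=3), df, folds=5)
    b = crossvalidate(ClassifierSpec(kind="RF", n_trees=20, seed=3), df, folds=5)
    assert a.summary() == b.summary()


@pytest.mark.parametrize("kind", ["SVM-L", "SVM-R", "SVM-P", "KNN", "RF"])
def test_every_classifier_kind_runs_and_beats_chance_on_separable_data(kind):
    df = _gaussian_classes(n_per=40, sep=4.0, seed=7)
    spec = ClassifierSpec(kind=kind, n_trees=50, seed=0)
    rep = crossvalidate(spec, df, folds=5)
    assert rep.mean("accuracy") >= 0.9


def test_too_few_samples_per_class_rejected():
    df = _gaussian_classes(n_per=5, seed=8)
    with pytest.raises(ValueError, match="folds"):
        crossvalidate(ClassifierSpec(kind="KNN", seed=0), df, folds=10)


# ---------------------------------------------------------------------------
# Bayesian neural network


def _separable_xy(n_per=60, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n_per, 10)) + 4 * cls
                   for cls in range(3)])
    X = (X - X.mean(0)) / X.std(0)
    y = np.repeat([0, 1, 2], n_per)
    return X, y


def test_bnn_fits_linearly_separable_classes():
    X, y = _separable_xy()
    model = MCDropoutBNN(BNNConfig(hidden_sizes=(50, 50), epochs=500, seed=1))
    model.fit(X, y)
    assert model.score(X, y) >= 0.95
    assert model.loss_history_[-1] < model.loss_history_[0]


def test_bnn_without_kl_matches_plain_dropout_mlp():
    X, y = _separable_xy(seed=2)
    bnn = MCDropoutBNN(BNNConfig(hidden_sizes=(30,), epochs=300,
                                 kl_weight=0.0, seed=3)).fit(X, y)
    mlp = MCDropoutBNN(BNNConfig(hidden_sizes=(30,), epochs=300,
                                 kl_weight=0.05, seed=3)).fit(X, y)
    assert abs(bnn.score(X, y) - mlp.score(X, y)) <= 0.02


def test_mc_averaging_stabilizes_predictions():
    """Repeating prediction with many MC samples yields a less variable
    label than a single stochastic pass (lower empirical label entropy)."""
    X, y = _separable_xy(seed=4)
    # mildly uncertain model: few epochs
    model = MCDropoutBNN(BNNConfig(hidden_sizes=(30,), epochs=60,
                                   dropout=0.4, seed=5)).fit(X, y)
    test_x = X[:30]

    def label_entropy(mc):
        counts = np.zeros((len(test_x), 3))
        for rep in range(50):
            pred = model.predict(test_x, mc_samples=mc, seed=1000 + rep)
            counts[np.arange(len(test_x)), pred] += 1
        p = counts / counts.sum(1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
        return float(np.mean(h))

    assert label_entropy(100) <= label_entropy(1) + 1e-9


def test_bnn_inside_crossvalidate():
    df = _gaussian_classes(n_per=25, sep=5.0, seed=9)
    spec = ClassifierSpec(kind="BNN", seed=0)
    spec.bnn = BNNConfig(hidden_sizes=(30,), epochs=150, mc_samples=10, seed=0)
    rep = crossvalidate(spec, df, folds=3)
    assert rep.mean("accuracy") >= 0.9


# ---------------------------------------------------------------------------
# region / band harness


def test_occipital_mix_selects_six_columns():
    cols = region_band_columns("occipital", "mix", ["AF3", "AF4", "T7", "T8", "Pz"])
    assert cols == [f"Pz-{b}" for b in BAND_NAMES]


def test_frontal_delta_selects_two_columns():
    cols = region_band_columns("frontal", "δ", ["AF3", "AF4", "T7", "T8", "Pz"])
    assert cols == ["AF3-δ", "AF4-δ"]


def test_temporal_only_contrast_favors_temporal_region():
    """When only temporal-channel band powers carry class structure, the
    temporal x mix cell beats occipital x mix in most seeded runs."""
    wins = 0
    n_runs = 10
    for seed in range(n_runs):
        rng = np.random.default_rng(seed)
        n = 150
        labels = np.repeat(["low", "middle", "high"], n // 3)
        shift = {"low": 0.0, "middle": 1.2, "high": 2.4}
        planted = np.array([shift[l] for l in labels])
        data = {}
        for ch in ("AF3", "AF4", "T7", "T8", "Pz"):
            for b in BAND_NAMES:
                col = rng.standard_normal(n)
                if ch in ("T7", "T8"):
                    col = col + planted
                data[f"{ch}-{b}"] = col
        df = pd.DataFrame(data)
        df["mwl"] = labels
        res = region_band_harness(df, folds=5, seed=seed,
                                  regions=("temporal", "occipital"),
                                  bands=("mix",))
        acc = dict(zip(res["region"], res["accuracy_mean"]))
        wins += acc["temporal"] > acc["occipital"]
    assert wins >= 9


def test_harness_errors_on_missing_columns():
    df = pd.DataFrame({"AF3-δ": np.arange(30.0),
                       "mwl": np.repeat(["low", "middle", "high"], 10)})
    with pytest.raises(ValueError, match="no PSD columns"):
        region_band_harness(df, folds=3, regions=("occipital",), bands=("δ",))
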