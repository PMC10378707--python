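"""Normality screen, Kruskal-Wallis screen, z-scoring, and SFFS."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier

from mwl_eeg import kw_screen, normality_screen, sffs, zscore

from oracles import brute_kruskal_h


# ---------------------------------------------------------------------------
# normality screen


def test_normal_draws_rejected_at_nominal_rate():
    """Over 200 seeded repetitions of n = 500 standard-normal draws, the
    α = 0.05 rejection rate sits near 5 %."""
    rejections = 0
    n_rep = 200
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"f": rng.standard_normal(500)})
        rejections += normality_screen(df)["f"] < 0.05
    rate = rejections / n_rep
    assert 0.01 <= rate <= 0.10


def test_exponential_draws_nearly_always_rejected():
    rejections = 0
    n_rep = 200
    for seed in range(n_rep):
        rng = np.random.default_rng(1000 + seed)
        df = pd.DataFrame({"f": rng.exponential(size=500)})
        rejections += normality_screen(df)["f"] < 0.05
    assert rejections >= 0.99 * n_rep


def test_constant_column_flagged_degenerate():
    df = pd.DataFrame({"f": np.full(100, 3.0)})
    p = normality_screen(df)
    assert p["f"] == 0.0
    assert "f" in p.attrs["degenerate"]


# ---------------------------------------------------------------------------
# Kruskal-Wallis screen


def _kw_frame(groups):
    vals = np.concatenate(groups)
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    return pd.DataFrame({"f": vals}), labels


def test_kw_hand_example_h_is_7_2():
    groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
    df, labels = _kw_frame(groups)
    res = kw_screen(df, labels, columns=["f"])
    assert np.isclose(res.table.loc[0, "H"], 7.2)
    assert np.isclose(res.table.loc[0, "H"], brute_kruskal_h(groups))


def test_kw_matches_rank_formula_oracle_on_random_groups():
    rng = np.random.default_rng(5)
    for _ in range(10):
        groups = [rng.integers(0, 20, size=rng.integers(5, 15)).astype(float)
                  for _ in range(3)]
        df, labels = _kw_frame(groups)
        res = kw_screen(df, labels, columns=["f"])
        assert np.isclose(res.table.loc[0, "H"], brute_kruskal_h(groups))


def test_kw_identical_constant_groups_h_zero():
    groups = [np.full(5, 2.0)] * 3
    df, labels = _kw_frame(groups)
    res = kw_screen(df, labels, columns=["f"])
    assert res.table.loc[0, "H"] == 0.0
    assert res.table.loc[0, "p"] == 1.0


def test_kw_type_one_error_calibrated():
    """1000 null simulations: rejection rate at α = 0.05 within [0.03, 0.07]."""
    rng = np.random.default_rng(77)
    rejections = 0
    n_sim = 1000
    labels = np.repeat([0, 1, 2], 20)
    for _ in range(n_sim):
        df = pd.DataFrame({"f": rng.standard_normal(60)})
        res = kw_screen(df, labels, columns=["f"])
        rejections += res.table.loc[0, "p"] < 0.05
    assert 0.03 <= rejections / n_sim <= 0.07


def test_kw_invariant_under_monotone_transform():
    rng = np.random.default_rng(6)
    groups = [rng.normal(i, 1, 15) for i in range(3)]
    df, labels = _kw_frame(groups)
    h1 = kw_screen(df, labels, columns=["f"]).table.loc[0, "H"]
    df2 = pd.DataFrame({"f": np.exp(df["f"])})  # strictly monotone
    h2 = kw_screen(df2, labels, columns=["f"]).table.loc[0, "H"]
    assert np.isclose(h1, h2)


def test_kw_selected_sets_are_nested():
    rng = np.random.default_rng(9)
    labels = np.repeat([0, 1, 2], 30)
    df = pd.DataFrame({
        f"f{i}": rng.standard_normal(90) + (0.3 * i) * (labels == 2)
        for i in range(8)
    })
    res = kw_screen(df, labels)
    assert set(res.selected(0.01)) <= set(res.selected(0.05))


def test_kw_requires_three_classes():
    df = pd.DataFrame({"f": np.arange(10.0)})
    labels = np.repeat([0, 1], 5)
    with pytest.raises(ValueError, match="3 classes"):
        kw_screen(df, labels, columns=["f"])


# ---------------------------------------------------------------------------
# z-scoring


def test_zscore_full_fit_gives_zero_mean_unit_sd():
    rng = np.random.default_rng(11)
    df = pd.DataFrame({"a": rng.normal(5, 3, 200), "b": rng.exponential(2, 200)})
    z = zscore(df)
    for c in ("a", "b"):
        assert abs(z[c].mean()) < 1e-9
        assert abs(z[c].std(ddof=0) - 1) < 1e-9


def test_zscore_affine_invariance():
    rng = np.random.default_rng(12)
    x = rng.standard_normal(100)
    df = pd.DataFrame({"a": x, "b": 4.0 * x - 7.0})
    z = zscore(df)
    assert np.allclose(z["a"], z["b"])


def test_zscore_train_only_fit_leaves_test_rows_unstandardized():
    rng = np.random.default_rng(13)
    df = pd.DataFrame({"a": np.concatenate([rng.normal(0, 1, 50),
                                            rng.normal(5, 1, 50)])})
    z = zscore(df, fit_rows=np.arange(50))
    test_mean = z["a"].iloc[50:].mean()
    assert abs(test_mean) > 1.0  # shifted group is far from (0, 1)


def test_zscore_constant_feature_standardizes_to_zero():
    df = pd.DataFrame({"a": np.full(20, 9.0), "b": np.arange(20.0)})
    z = zscore(df)
    assert (z["a"] == 0.0).all()
    assert "a" in z.attrs["zscore_degenerate"]


# ---------------------------------------------------------------------------
# SFFS


def _sffs_dataset(seed=42, n=90):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1, 2], n // 3)
    f1 = np.array([0, 3.0, 6.0])[y] + rng.standard_normal(n)
    f2 = np.array([0, 4.0, 0.0])[y] + rng.standard_normal(n)
    X = np.column_stack([f1, f2] + [rng.standard_normal(n) for _ in range(4)])
    return X, y


def test_single_feature_is_forced_choice():
    X, y = _sffs_dataset()
    est = KNeighborsClassifier(n_neighbors=1)
    trace = sffs(X[:, :1], y, est, cv_folds=5, max_d=1, seed=0)
    feats, score = trace.best_at_size[1]
    assert feats == ("f0",)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
    expected = float(np.mean(cross_val_score(
        KNeighborsClassifier(n_neighbors=1), X[:, :1], y, cv=cv)))
    assert np.isclose(score, expected)


def test_sffs_matches_exhaustive_search_on_six_features():
    """Best subset at every size d equals exhaustive search over all C(6,d)
    subsets with the same estimator, folds, and seed."""
    X, y = _sffs_dataset()
    est = KNeighborsClassifier(n_neighbors=1)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)

    def score(cols):
        return float(np.mean(cross_val_score(est, X[:, list(cols)], y, cv=cv)))

    trace = sffs(X, y, est, cv_folds=5, max_d=6, seed=0)
    for d in range(1, 7):
        exhaustive_best = max(score(c) for c in combinations(range(6), d))
        assert np.isclose(trace.best_at_size[d][1], exhaustive_best), d


def test_sffs_inclusion_order_follows_nested_informative_structure():
    """f0 is the best singleton and {f0, f1} the best pair, so inclusion
    starts f0 then f1 (verified exhaustively in the companion test)."""
    X, y = _sffs_dataset()
    est = KNeighborsClassifier(n_neighbors=1)
    trace = sffs(X, y, est, cv_folds=5, max_d=3, seed=0)
    assert trace.best_at_size[1][0] == ("f0",)
    assert set(trace.best_at_size[2][0]) == {"f0", "f1"}
    assert trace.log[0].startswith("+f0")
    assert trace.log[1].startswith("+f1")


def test_sffs_never_worse_than_plain_forward_selection():
    """The floating variant's best criterion at its best subset is >= the
    plain forward (no-exclusion) criterion at the same size."""
    X, y = _sffs_dataset(seed=7)
    est = KNeighborsClassifier(n_neighbors=1)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)

    def score(cols):
        return float(np.mean(cross_val_score(est, X[:, list(cols)], y, cv=cv)))

    # plain SFS
    sfs_best = {}
    current = []
    for _ in range(6):
        cands = [j for j in range(6) if j not in current]
        scores = [score(sorted(current + [j])) for j in cands]
        current = sorted(current + [cands[int(np.argmax(scores))]])
        sfs_best[len(current)] = max(scores)

    trace = sffs(X, y, est, cv_folds=5, max_d=6, seed=0)
    for d, (feats, s) in trace.best_at_size.items():
        assert s >= sfs_best[d] - 1e-12


def test_sffs_rejects_non_finite_features():
    X, y = _sffs_dataset()
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        sffs(X, y, KNeighborsClassifier(n_neighbors=1), cv_folds=5, max_d=2)


def test_planted_contrast_features_survive_screen_noise_features_do_not():
    """Class-contrasted features pass the α = 0.01 screen; pure-noise
    features are retained at roughly the α rate."""
    rng = np.random.default_rng(55)
    n = 300
    labels = np.repeat(["low", "middle", "high"], n // 3)
    shift = {"low": 0.0, "middle": 0.6, "high": 1.2}
    planted = {f"sig{i}": np.array([shift[l] for l in labels])
               + rng.standard_normal(n) for i in range(5)}
    noise = {f"noise{i}": rng.standard_normal(n) for i in range(40)}
    df = pd.DataFrame({**planted, **noise})
    res = kw_screen(df, labels)
    selected = set(res.selected(0.01))
    assert all(f"sig{i}" in selected for i in range(5))
    false_pos = sum(1 for i in range(40) if f"noise{i}" in selected)
    assert false_pos <= 3  # ~alpha rate on 40 null features
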