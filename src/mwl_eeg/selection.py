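"""Feature selection: normality-gated Kruskal-Wallis screening with
z-scoring, and Sequential Forward Floating Selection (SFFS).

Two routes mirror the two philosophies of the analysis: a filter (per-feature
rank test across the three workload classes, features kept at α = 0.05 and
α = 0.01) and a wrapper (greedy forward selection with a conditional
backward "floating" step, scored by cross-validated classifier accuracy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, cross_val_score


# ---------------------------------------------------------------------------
# filter route

def normality_screen(features: pd.DataFrame, columns: list[str] | None = None) -> pd.Series:
    """Shapiro-Wilk normality p-value per feature column; constant columns
    get p = 0 (normality rejected by convention) and are flagged via the
    returned series' ``attrs["degenerate"]`` list."""
    if columns is None:
        columns = [c for c in features.columns if c not in ("phase", "mwl", "start_s")]
    pvals = {}
    degenerate = []
    for c in columns:
        x = features[c].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError(f"feature {c}: need >= 3 samples")
        if np.ptp(x) == 0.0:
            pvals[c] = 0.0
            degenerate.append(c)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # large-N accuracy warning
            pvals[c] = float(stats.shapiro(x).pvalue)
    out = pd.Series(pvals, name="normality_p")
    out.attrs["degenerate"] = degenerate
    return out


@dataclass
class ScreenResult:
    """Per-feature Kruskal-Wallis screen over the workload classes."""

    table: pd.DataFrame  # columns: feature, H, p (+ normality_p if provided)
    alphas: tuple[float, float] = (0.05, 0.01)

    def selected(self, alpha: float) -> list[str]:
        return self.table.loc[self.table["p"] < alpha, "feature"].tolist()


def kw_screen(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    columns: list[str] | None = None,
    alphas: tuple[float, float] = (0.05, 0.01),
    normality_p: pd.Series | None = None,
) -> ScreenResult:
    """Tie-corrected Kruskal-Wallis H per feature across the workload
    classes, p-value from the chi-squared (k-1) reference distribution."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 3:
        raise ValueError(f"need 3 classes, got {len(classes)}")
    for cls in classes:
        if np.sum(labels == cls) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    if columns is None:
        columns = [c for c in features.columns if c not in ("phase", "mwl", "start_s")]
    rows = []
    for c in columns:
        x = features[c].to_numpy(dtype=float)
        groups = [x[labels == cls] for cls in classes]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            h, p = 0.0, 1.0  # identical constant groups: all mean ranks equal
        else:
            h, p = stats.kruskal(*groups)
        row = {"feature": c, "H": float(h), "p": float(p)}
        if normality_p is not None:
            row["normality_p"] = float(normality_p[c])
        rows.append(row)
    return ScreenResult(table=pd.DataFrame(rows), alphas=alphas)


def zscore(
    features: pd.DataFrame,
    columns: list[str] | None = None,
    fit_rows: np.ndarray | None = None,
) -> pd.DataFrame:
    """Standardize feature columns to zero mean / unit SD using statistics
    estimated on ``fit_rows`` only (all rows by default), applied to all
    rows. Zero-variance features standardize to 0 and are flagged in
    ``df.attrs["zscore_degenerate"]``."""
    if columns is None:
        columns = [c for c in features.columns if c not in ("phase", "mwl", "start_s")]
    out = features.copy()
    sub = features.iloc[fit_rows] if fit_rows is not None else features
    degenerate = []
    for c in columns:
        mu = sub[c].mean()
        sd = sub[c].std(ddof=0)
        if sd == 0.0 or not np.isfinite(sd):
            out[c] = 0.0
            degenerate.append(c)
        else:
            out[c] = (features[c] - mu) / sd
    out.attrs["zscore_degenerate"] = degenerate
    return out


# ---------------------------------------------------------------------------
# wrapper route

@dataclass
class SFFSTrace:
    """Record of an SFFS run: best subset found at every size, the step log,
    and the overall winner."""

    best_at_size: dict[int, tuple[tuple[str, ...], float]]
    log: list[str] = field(default_factory=list)

    @property
    def best(self) -> tuple[tuple[str, ...], float]:
        return max(self.best_at_size.values(), key=lambda t: t[1])

    def accuracy_curve(self) -> pd.DataFrame:
        rows = [
            {"d": d, "accuracy": score, "features": ",".join(feats)}
            for d, (feats, score) in sorted(self.best_at_size.items())
        ]
        return pd.DataFrame(rows)


def _cv_score(X: np.ndarray, y: np.ndarray, cols: tuple[int, ...],
              estimator, cv, cache: dict) -> float:
    key = frozenset(cols)
    if key not in cache:
        cache[key] = float(
            np.mean(cross_val_score(clone(estimator), X[:, cols], y, cv=cv,
                                    scoring="accuracy"))
        )
    return cache[key]


def sffs(
    features: pd.DataFrame | np.ndarray,
    labels,
    estimator,
    columns: list[str] | None = None,
    cv_folds: int = 10,
    max_d: int | None = None,
    seed: int = 0,
) -> SFFSTrace:
    """Sequential forward floating selection wrapped around a cross-validated
    estimator, accuracy as the criterion.

    Forward step: include the feature whose addition maximizes CV accuracy
    (ties broken toward the lowest column index). Floating step: after each
    inclusion, conditionally exclude any feature whose removal strictly
    improves on the best known criterion at the smaller size; exclusions that
    would revisit an already-visited subset are skipped (cycle check on the
    full state history).
    """
    if isinstance(features, pd.DataFrame):
        if columns is None:
            columns = [c for c in features.columns
                       if c not in ("phase", "mwl", "start_s")]
        X = features[columns].to_numpy(dtype=float)
        names = list(columns)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])] if columns is None else list(columns)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    p = X.shape[1]
    if max_d is None:
        max_d = p
    if max_d > p:
        raise ValueError(f"max_d {max_d} > feature count {p}")

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cache: dict = {}
    visited: set[frozenset] = set()
    best_at: dict[int, tuple[tuple[int, ...], float]] = {}
    log: list[str] = []
    current: list[int] = []

    def record(subset: list[int], score: float) -> None:
        d = len(subset)
        if d not in best_at or score > best_at[d][1]:
            best_at[d] = (tuple(subset), score)

    while len(current) < max_d:
        # --- forward inclusion
        candidates = [j for j in range(p) if j not in current]
        scores = [
            _cv_score(X, y, tuple(sorted(current + [j])), estimator, cv, cache)
            for j in candidates
        ]
        best_j = candidates[int(np.argmax(scores))]  # argmax ties -> lowest index
        current = sorted(current + [best_j])
        score = max(scores)
        visited.add(frozenset(current))
        record(current, score)
        log.append(f"+{names[best_j]} -> d={len(current)} acc={score:.4f}")

        # --- conditional (floating) exclusion
        while len(current) > 2:
            removals = [tuple(f for f in current if f != j) for j in current]
            rem_scores = [
                _cv_score(X, y, r, estimator, cv, cache) for r in removals
            ]
            k = int(np.argmax(rem_scores))
            d_small = len(current) - 1
            if d_small in best_at and rem_scores[k] > best_at[d_small][1]:
                new_state = frozenset(removals[k])
                if new_state in visited:
                    log.append("cycle-skip: exclusion would revisit a prior state")
                    break
                removed = [j for j in current if j not in removals[k]][0]
                current = list(removals[k])
                visited.add(new_state)
                record(current, rem_scores[k])
                log.append(
                    f"-{names[removed]} -> d={len(current)} acc={rem_scores[k]:.4f}"
                )
            else:
                break

    named = {
        d: (tuple(names[j] for j in subset), score)
        for d, (subset, score) in best_at.items()
    }
    return SFFSTrace(best_at_size=named, log=log)
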