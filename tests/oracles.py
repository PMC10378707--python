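"""Independent brute-force oracles used by the test suite.

These are deliberately literal, slow implementations of the definitions,
kept free of any code path from the package under test.
"""

from __future__ import annotations

import numpy as np


def brute_sampen(x: np.ndarray, m: int, r: float) -> float | None:
    """Sample entropy by nested loops: -ln(A/B), self-matches excluded,
    N-m templates for both lengths. Returns None when no matches exist."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    b = 0
    a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m <= r:
                b += 1
                d_m1 = max(abs(x[i + k] - x[j + k]) for k in range(m + 1))
                if d_m1 <= r:
                    a += 1
    if b == 0 or a == 0:
        return None
    return -np.log(a / b)


def brute_apen(x: np.ndarray, m: int, r: float) -> float:
    """Approximate entropy by nested loops: Phi_m - Phi_{m+1}, self-matches
    included, N-mm+1 templates of length mm."""
    x = np.asarray(x, dtype=float)
    n = len(x)

    def phi(mm: int) -> float:
        count = n - mm + 1
        total = 0.0
        for i in range(count):
            c = 0
            for j in range(count):
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if d <= r:
                    c += 1
            total += np.log(c / count)
        return total / count

    return phi(m) - phi(m + 1)


def brute_kruskal_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from the rank formula
    H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2, divided by the tie factor."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n_total)
    # average ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < n_total:
        j = i
        while j + 1 < n_total and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    grand_mean = (n_total + 1) / 2
    idx = 0
    h = 0.0
    for g in groups:
        gr = ranks[idx : idx + len(g)]
        idx += len(g)
        h += len(g) * (np.mean(gr) - grand_mean) ** 2
    h *= 12 / (n_total * (n_total + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / tie if tie > 0 else np.nan


def brute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Confusion-matrix hand computation: multi-class accuracy plus
    macro-averaged one-vs-rest precision and recall."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = sorted(set(y_true) | set(y_pred))
    correct = sum(1 for t, p in zip(y_true, y_pred) if t == p)
    precisions, recalls = [], []
    for cls in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
        precisions.append(tp / (tp + fp) if tp + fp else 0.0)
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
    return {
        "accuracy": correct / len(y_true),
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
    }


def periodogram_band_power(x: np.ndarray, fs: float, low: float, high: float) -> float:
    """Band power by direct periodogram integration (independent of the
    package's Spectrum plumbing)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.abs(np.fft.rfft(x)) ** 2 / (fs * n)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    mask = (freqs >= low) & (freqs <= high)
    return float(np.sum(psd[mask]) * fs / n)
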