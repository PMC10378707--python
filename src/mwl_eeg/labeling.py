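"""NASA-TLX scoring, phase-difference testing, and workload labeling.

The NASA Task Load Index rates six subscales (mental, physical and temporal
demand, effort, frustration, perceived performance) on a 0-100 scale and
weights them by tallies from 15 pairwise comparisons. Phases of the flight
task are compared on the weighted score; the phase ranking maps phases onto
low / middle / high mental-workload (MWL) labels which are then attached to
every EEG epoch of that phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import MWL_LEVELS, PHASES

SUBSCALES: tuple[str, ...] = (
    "mental", "physical", "temporal", "effort", "frustration", "performance",
)

#: Number of pairwise comparisons among 6 subscales: C(6,2).
N_PAIRWISE = 15


@dataclass
class TLXRecord:
    """One participant's TLX response for one flight phase."""

    participant: int
    phase: str
    ratings: dict[str, float]
    weights: dict[str, float]
    weighted_score: float | None = None

    def __post_init__(self) -> None:
        missing = set(SUBSCALES) - set(self.ratings)
        if missing:
            raise ValueError(f"missing subscale ratings: {sorted(missing)}")
        for name, r in self.ratings.items():
            if not 0.0 <= r <= 100.0:
                raise ValueError(f"rating {name}={r} outside [0, 100]")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        total = sum(self.weights.get(s, 0.0) for s in SUBSCALES)
        if not np.isclose(total, N_PAIRWISE):
            raise ValueError(f"weight tallies sum to {total}, expected {N_PAIRWISE}")


def tlx_weighted_score(record: TLXRecord, aggregator: str = "mean") -> float:
    """Aggregate the six subscale ratings into a single workload score.

    ``aggregator="mean"`` is the standard weighted TLX,
    ``sum(rating_i * weight_i) / 15``, bounded by [0, 100].
    ``aggregator="sum"`` omits the /15 normalization and can exceed 100;
    it is provided because some published phase-level scores exceed the
    rating scale and the aggregation behind them is not documented.
    """
    raw = sum(record.ratings[s] * record.weights.get(s, 0.0) for s in SUBSCALES)
    if aggregator == "mean":
        return raw / N_PAIRWISE
    if aggregator == "sum":
        return raw
    raise ValueError(f"unknown aggregator {aggregator!r}")


def score_records(records: list[TLXRecord], aggregator: str = "mean") -> pd.DataFrame:
    """Return a tidy frame of (participant, phase, score), filling weighted_score."""
    rows = []
    for rec in records:
        s = tlx_weighted_score(rec, aggregator)
        rec.weighted_score = s
        rows.append({"participant": rec.participant, "phase": rec.phase, "score": s})
    return pd.DataFrame(rows)


@dataclass
class MWLLabeling:
    """Phase → workload-level map plus the statistics supporting it."""

    phase_to_level: dict[str, str]
    phase_means: dict[str, float]
    anova_f: float
    anova_p: float
    pairwise_p: dict[tuple[str, str], float]
    alpha: float
    corrected_alpha: float
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def all_pairs_significant(self) -> bool:
        return all(p < self.corrected_alpha for p in self.pairwise_p.values())


def test_phase_differences(
    records: list[TLXRecord],
    alpha: float = 0.05,
    aggregator: str = "mean",
) -> MWLLabeling:
    """One-way ANOVA plus Bonferroni-corrected pairwise Welch t-tests on
    weighted TLX scores across the three flight phases, and the resulting
    low/middle/high label map (rank order of phase means).
    """
    df = score_records(records, aggregator)
    phases = [p for p in PHASES if p in set(df["phase"])]
    if len(phases) < 2:
        raise ValueError("need at least two phases")
    groups = {p: df.loc[df["phase"] == p, "score"].to_numpy() for p in phases}
    for p, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"phase {p!r} has fewer than 2 records")

    degenerate = all(np.var(g) == 0.0 for g in groups.values())
    notes: list[str] = []
    if degenerate:
        notes.append("all phase groups have zero variance; ANOVA undefined")
        f_stat, f_p = np.nan, np.nan
    else:
        f_stat, f_p = stats.f_oneway(*groups.values())

    n_pairs = len(phases) * (len(phases) - 1) // 2
    corrected = alpha / n_pairs
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in combinations(phases, 2):
        if np.var(groups[a]) == 0.0 and np.var(groups[b]) == 0.0:
            p = 1.0 if np.mean(groups[a]) == np.mean(groups[b]) else 0.0
            notes.append(f"pair ({a}, {b}) degenerate (zero variance)")
        else:
            p = stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue
        pairwise[(a, b)] = float(p)

    means = {p: float(np.mean(g)) for p, g in groups.items()}
    if len(set(means.values())) < len(means):
        raise ValueError(f"tied phase means {means}; explicit label override required")
    order = sorted(means, key=means.get)  # ascending score
    levels = MWL_LEVELS[: len(order)]
    phase_to_level = {phase: level for phase, level in zip(order, levels)}

    return MWLLabeling(
        phase_to_level=phase_to_level,
        phase_means=means,
        anova_f=float(f_stat),
        anova_p=float(f_p),
        pairwise_p=pairwise,
        alpha=alpha,
        corrected_alpha=round(corrected, 3),
        degenerate=degenerate,
        notes=notes,
    )


def assign_labels(labeling: MWLLabeling, features: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``mwl`` column to a feature table using the phase label map."""
    if "phase" not in features.columns:
        raise ValueError("feature table has no 'phase' column")
    unknown = set(features["phase"]) - set(labeling.phase_to_level)
    if unknown:
        raise ValueError(f"phases without a label: {sorted(unknown)}")
    out = features.copy()
    out["mwl"] = out["phase"].map(labeling.phase_to_level)
    return out
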