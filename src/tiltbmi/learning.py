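"""Session- and experiment-level learning measures.

Covers: normalizing daily decoding accuracy to a reference day,
splitting animals into learners (>= 5 consecutive training days above
the first-day performance) and nonlearners, the early/late phase split
(first/last five training days), naive-vs-expert population PSTH
distances between pooled tilt groupings, the within-session
cumulative-sum linearity analysis, and the first-300-trials fatigue
filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import SessionRecording
from .decoder import (
    DegenerateInputError,
    PsthMatrix,
    bin_spike_counts,
    make_bin_edges,
)

# Pooled tilt groupings: right fast+slow, left fast+slow, fast both
# sides, slow both sides (tilt types: 1 fast-right, 2 slow-right,
# 3 fast-left, 4 slow-left).
TILT_GROUPS: dict[str, tuple[int, int]] = {
    "RFS": (1, 2),
    "LFS": (3, 4),
    "FRL": (1, 3),
    "SRL": (2, 4),
}
GROUP_CONTRASTS: tuple[tuple[str, str], ...] = (("RFS", "LFS"), ("FRL", "SRL"))

PHASE_DAYS = 5
LEARNER_RUN_DAYS = 5
DEFAULT_FIRST_N = 300

__all__ = [
    "PerformanceSeries",
    "normalize_performance",
    "classify_learner",
    "split_phases",
    "grouped_psth",
    "tilt_pair_distance",
    "intertrial_cumsum",
    "filter_first_n",
    "TILT_GROUPS",
    "GROUP_CONTRASTS",
]


@dataclass(frozen=True)
class PerformanceSeries:
    """Daily decoding accuracy for one animal, with its normalization."""

    animal_id: str
    days: tuple[int, ...]
    accuracy: tuple[float, ...]
    reference_day: int
    normalized: tuple[float, ...]
    group: str | None = None  # learner | nonlearner | control

    def __post_init__(self) -> None:
        if any(not 0.0 <= a <= 1.0 for a in self.accuracy):
            raise ValueError("accuracies must lie in [0, 1]")
        ref_idx = self.days.index(self.reference_day)
        if not np.isclose(self.normalized[ref_idx], 0.0):
            raise ValueError("normalized series must be 0 at its reference day")


def normalize_performance(
    days: list[int],
    accuracies: list[float],
    reference_day: int,
    animal_id: str = "",
    group: str | None = None,
) -> PerformanceSeries:
    """Accuracy change from the reference day (day 0 online, day 1 offline)."""
    if reference_day not in days:
        raise ValueError(f"reference day {reference_day} not in series")
    acc = np.asarray(accuracies, dtype=float)
    ref = acc[days.index(reference_day)]
    return PerformanceSeries(
        animal_id=animal_id,
        days=tuple(days),
        accuracy=tuple(acc),
        reference_day=reference_day,
        normalized=tuple(acc - ref),
        group=group,
    )


def classify_learner(series: PerformanceSeries, strict: bool = True) -> str:
    """Learner iff >= 5 consecutive training days beat day-1 performance.

    Training days are those with day >= 1; the comparison value is the
    accuracy on the first training day.  ``strict`` uses > (default);
    False uses >=.
    """
    train = [(d, a) for d, a in zip(series.days, series.accuracy) if d >= 1]
    if len(train) < LEARNER_RUN_DAYS:
        raise DegenerateInputError("need >= 5 training days")
    day1_perf = train[0][1]
    run = 0
    for _, acc in train:
        better = acc > day1_perf if strict else acc >= day1_perf
        run = run + 1 if better else 0
        if run >= LEARNER_RUN_DAYS:
            return "learner"
    return "nonlearner"


def split_phases(training_days: list[int]) -> tuple[list[int], list[int]]:
    """(early, late) = first and last 5 training days."""
    days = sorted(d for d in training_days if d >= 1)
    if len(days) < 2 * PHASE_DAYS:
        raise DegenerateInputError("need >= 10 training days for phase split")
    return days[:PHASE_DAYS], days[-PHASE_DAYS:]


def grouped_psth(
    session: SessionRecording,
    grouping: str,
    neuron_ids: list[str] | None = None,
    bin_width_ms: float = 20.0,
    window: tuple[float, float] = (-200.0, 200.0),
    first_n: int | None = None,
) -> PsthMatrix:
    """PSTH with trials of the grouping's two tilt types pooled."""
    if grouping not in TILT_GROUPS:
        raise ValueError(f"unknown grouping {grouping!r}; one of {sorted(TILT_GROUPS)}")
    tilts = TILT_GROUPS[grouping]
    trials = session.trials if first_n is None else session.trials.iloc[:first_n]
    tids = trials.loc[trials["tilt_type"].isin(tilts), "trial_id"].to_numpy()
    if len(tids) == 0:
        raise DegenerateInputError(f"no trials in grouping {grouping}")
    roster = tuple(neuron_ids if neuron_ids is not None else session.roster())
    edges = make_bin_edges(bin_width_ms, window)
    counts = bin_spike_counts(session, roster, edges, tids)
    return PsthMatrix(
        tilt_type=tilts[0],
        neuron_ids=roster,
        bin_edges=edges,
        values=counts.mean(axis=0),
        n_trials=len(tids),
    )


def tilt_pair_distance(psth_a: PsthMatrix, psth_b: PsthMatrix) -> float:
    """Population Euclidean distance between two (grouped) tilt PSTHs.

    Per neuron, d_n = sqrt(sum over bins (a_b - b_b)^2); the population
    distance is the mean of d_n over the shared neuron set.
    """
    if psth_a.neuron_ids != psth_b.neuron_ids:
        raise ValueError("PSTHs must share the same neuron set")
    if not np.array_equal(psth_a.bin_edges, psth_b.bin_edges):
        raise ValueError("PSTHs must share bin edges")
    per_neuron = np.sqrt(((psth_a.values - psth_b.values) ** 2).sum(axis=1))
    return float(per_neuron.mean())


def naive_expert_distances(
    naive: SessionRecording,
    expert: SessionRecording,
    neuron_ids: list[str] | None = None,
    first_n: int | None = DEFAULT_FIRST_N,
) -> pd.DataFrame:
    """Distance between the pooled grouping contrasts on both days.

    One row per contrast (RFS vs LFS, FRL vs SRL) with naive- and
    expert-day population distances; points above the diagonal mean the
    tilt responses moved further apart with training.  Both days are
    truncated to the same trial count so the finite-trial noise floor
    of the PSTH distance is matched between them.
    """
    n_eff = min(naive.n_trials, expert.n_trials)
    if first_n is not None:
        n_eff = min(n_eff, first_n)
    rows = []
    for ga, gb in GROUP_CONTRASTS:
        d_naive = tilt_pair_distance(
            grouped_psth(naive, ga, neuron_ids, first_n=n_eff),
            grouped_psth(naive, gb, neuron_ids, first_n=n_eff),
        )
        d_expert = tilt_pair_distance(
            grouped_psth(expert, ga, neuron_ids, first_n=n_eff),
            grouped_psth(expert, gb, neuron_ids, first_n=n_eff),
        )
        rows.append(
            {
                "animal_id": naive.animal_id,
                "contrast": f"{ga}-{gb}",
                "naive_distance": d_naive,
                "expert_distance": d_expert,
            }
        )
    return pd.DataFrame(rows)


def expert_day(series: PerformanceSeries) -> int:
    """Training day of maximum accuracy; ties resolve to the latest day."""
    train = [(d, a) for d, a in zip(series.days, series.accuracy) if d >= 1]
    best = max(a for _, a in train)
    return max(d for d, a in train if np.isclose(a, best))


def intertrial_cumsum(outcomes: np.ndarray | list) -> tuple[float, float, float]:
    """OLS fit of the cumulative correct-trial count vs trial index.

    ``outcomes`` is binary (1 = correct, 0 = incorrect) in session
    order.  Returns (slope, intercept, r_squared); a zero-variance
    cumulative sum (all incorrect) has r^2 defined as 0.
    """
    y = np.asarray(outcomes, dtype=float)
    if len(y) < 10:
        raise DegenerateInputError("need >= 10 trials")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    csum = np.cumsum(y)
    x = np.arange(1, len(y) + 1, dtype=float)
    if np.isclose(csum.std(), 0.0):
        return 0.0, float(csum[0]), 0.0
    fit = stats.linregress(x, csum)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def filter_first_n(session: SessionRecording, n: int = DEFAULT_FIRST_N) -> SessionRecording:
    """Keep the first ``n`` trials in session order (fatigue control).

    Spikes belonging to dropped trials are excluded; shorter sessions
    pass through unchanged.
    """
    if session.n_trials <= n:
        return session
    trials = session.trials.iloc[:n].reset_index(drop=True)
    keep = set(trials["trial_id"])
    spikes = session.spikes[session.spikes["trial_id"].isin(keep)].reset_index(drop=True)
    return SessionRecording(
        animal_id=session.animal_id,
        day=session.day,
        trials=trials,
        spikes=spikes,
        neurons=session.neurons,
    )
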