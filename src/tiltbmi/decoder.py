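"""PSTH-template classifier for single-trial tilt-type decoding.

Templates are per-tilt-type peri-stimulus time histograms (mean spike
count per 20 ms bin per trial, ±200 ms around tilt onset).  A single
trial is assigned to the tilt type whose template has the smallest
Euclidean distance to the trial's binned spike counts, concatenated
across the neuron roster.  Two decoding regimes are provided:

* *online*: each day's trials are classified against templates built
  from the previous day's recording (day 1 uses the day-0 baseline),
  with the roster restricted to neurons firing on both days;
* *offline*: leave-one-out cross-validation within a session, where the
  held-out trial is removed from its own class template.

Bins are half-open ``[left, right)``; ties in distance break to the
lowest tilt-type index so decoding is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import N_TILT_TYPES, SessionRecording

DEFAULT_BIN_MS = 20.0
DEFAULT_WINDOW = (-200.0, 200.0)

__all__ = [
    "PsthMatrix",
    "TemplateSet",
    "bin_spike_counts",
    "build_psth",
    "build_templates",
    "classify_trial",
    "decode_offline",
    "decode_online",
    "reconcile_roster",
    "DegenerateInputError",
    "RosterError",
]


class DegenerateInputError(ValueError):
    """Too little data for the requested computation."""


class RosterError(ValueError):
    """Neuron roster mismatch or empty decoding roster."""


@dataclass(frozen=True)
class PsthMatrix:
    """Mean binned response of a neuron roster for one tilt type."""

    tilt_type: int
    neuron_ids: tuple[str, ...]
    bin_edges: np.ndarray  # (n_bins+1,), ms
    values: np.ndarray  # (n_neurons, n_bins), spikes per trial per bin
    n_trials: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.neuron_ids), len(self.bin_edges) - 1):
            raise ValueError("values shape does not match roster/bins")
        if (self.values < 0).any():
            raise ValueError("PSTH values must be non-negative")


@dataclass(frozen=True)
class TemplateSet:
    """One day's decoder: a PsthMatrix per tilt type on a shared roster."""

    day: int
    templates: dict[int, PsthMatrix]
    neuron_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if sorted(self.templates) != list(range(1, N_TILT_TYPES + 1)):
            raise ValueError("need one template per tilt type 1..4")
        edges0 = self.templates[1].bin_edges
        for t in self.templates.values():
            if t.neuron_ids != self.neuron_ids or not np.array_equal(t.bin_edges, edges0):
                raise ValueError("templates must share roster and bin edges")

    @property
    def bin_edges(self) -> np.ndarray:
        return self.templates[1].bin_edges

    def stacked(self) -> np.ndarray:
        """(4, n_neurons * n_bins) template matrix in tilt order."""
        return np.stack(
            [self.templates[t].values.ravel() for t in range(1, N_TILT_TYPES + 1)]
        )


def make_bin_edges(bin_width_ms: float, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    span = hi - lo
    n_bins = span / bin_width_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("window bounds must be a multiple of the bin width")
    return lo + bin_width_ms * np.arange(int(round(n_bins)) + 1)


def bin_spike_counts(
    session: SessionRecording,
    neuron_ids: list[str] | tuple[str, ...],
    bin_edges: np.ndarray,
    trial_ids: np.ndarray | list[int],
) -> np.ndarray:
    """Spike counts per (trial, neuron, bin); half-open bins.

    Spikes at or beyond the right edge are excluded.  Neurons with no
    spikes in a trial contribute zero counts.
    """
    trial_ids = np.asarray(trial_ids)
    n_bins = len(bin_edges) - 1
    counts = np.zeros((len(trial_ids), len(neuron_ids), n_bins))
    if session.spikes.empty or not len(neuron_ids):
        return counts
    neuron_pos = {nid: i for i, nid in enumerate(neuron_ids)}
    trial_pos = {tid: i for i, tid in enumerate(trial_ids)}
    sp = session.spikes
    n_idx = sp["neuron_id"].map(neuron_pos)
    t_idx = sp["trial_id"].map(trial_pos)
    keep = n_idx.notna() & t_idx.notna()
    if not keep.any():
        return counts
    times = sp.loc[keep, "time_ms"].to_numpy()
    b_idx = np.searchsorted(bin_edges, times, side="right") - 1
    in_window = (b_idx >= 0) & (b_idx < n_bins) & (times >= bin_edges[0])
    np.add.at(
        counts,
        (
            t_idx[keep].to_numpy(dtype=int)[in_window],
            n_idx[keep].to_numpy(dtype=int)[in_window],
            b_idx[in_window],
        ),
        1.0,
    )
    return counts


def build_psth(
    session: SessionRecording,
    neuron_ids: list[str] | None = None,
    bin_width_ms: float = DEFAULT_BIN_MS,
    window: tuple[float, float] = DEFAULT_WINDOW,
    trial_ids: list[int] | np.ndarray | None = None,
) -> dict[int, PsthMatrix]:
    """Per-tilt-type mean binned responses (one PsthMatrix per tilt)."""
    roster = tuple(neuron_ids if neuron_ids is not None else session.roster())
    edges = make_bin_edges(bin_width_ms, window)
    trials = session.trials
    if trial_ids is not None:
        trials = trials[trials["trial_id"].isin(set(np.asarray(trial_ids).tolist()))]
    out: dict[int, PsthMatrix] = {}
    for tilt in range(1, N_TILT_TYPES + 1):
        tids = trials.loc[trials["tilt_type"] == tilt, "trial_id"].to_numpy()
        if len(tids) == 0:
            raise DegenerateInputError(f"no trials of tilt type {tilt}")
        counts = bin_spike_counts(session, roster, edges, tids)
        out[tilt] = PsthMatrix(
            tilt_type=tilt,
            neuron_ids=roster,
            bin_edges=edges,
            values=counts.mean(axis=0),
            n_trials=len(tids),
        )
    return out


def build_templates(
    session: SessionRecording,
    neuron_ids: list[str] | None = None,
    bin_width_ms: float = DEFAULT_BIN_MS,
    window: tuple[float, float] = DEFAULT_WINDOW,
    trial_ids: list[int] | np.ndarray | None = None,
) -> TemplateSet:
    psths = build_psth(session, neuron_ids, bin_width_ms, window, trial_ids)
    return TemplateSet(day=session.day, templates=psths, neuron_ids=psths[1].neuron_ids)


def classify_trial(
    trial_counts: np.ndarray, templates: TemplateSet
) -> tuple[int, dict[int, float]]:
    """Nearest-template classification of one binned trial.

    ``trial_counts`` is (n_neurons, n_bins) on the template roster and
    bin edges.  Returns the predicted tilt type and all four Euclidean
    distances; ties break to the lowest tilt index.
    """
    n_bins = len(templates.bin_edges) - 1
    expected = (len(templates.neuron_ids), n_bins)
    if trial_counts.shape != expected:
        raise RosterError(f"trial shape {trial_counts.shape} != template shape {expected}")
    vec = trial_counts.ravel()
    stacked = templates.stacked()
    dists = np.sqrt(((stacked - vec) ** 2).sum(axis=1))
    predicted = int(np.argmin(dists)) + 1  # argmin takes first minimum -> lowest tilt
    return predicted, {t + 1: float(d) for t, d in enumerate(dists)}


def _loo_predict(counts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized leave-one-out nearest-template predictions.

    ``counts``: (n_trials, D) flattened binned responses; ``labels``:
    tilt types 1..4.  The held-out trial is removed from its own class
    mean before the distance comparison.
    """
    n = len(labels)
    sums = np.zeros((N_TILT_TYPES, counts.shape[1]))
    ns = np.zeros(N_TILT_TYPES)
    for t in range(N_TILT_TYPES):
        mask = labels == t + 1
        sums[t] = counts[mask].sum(axis=0)
        ns[t] = mask.sum()
    if (ns < 2).any():
        raise DegenerateInputError("need >= 2 trials per tilt type for leave-one-out")
    d2 = np.empty((n, N_TILT_TYPES))
    for t in range(N_TILT_TYPES):
        own = labels == t + 1
        denom = np.where(own, ns[t] - 1.0, ns[t])
        tmpl = (sums[t][None, :] - np.where(own[:, None], counts, 0.0)) / denom[:, None]
        d2[:, t] = ((counts - tmpl) ** 2).sum(axis=1)
    return np.argmin(d2, axis=1) + 1


def confusion_matrix(actual: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """4x4 counts, rows = actual tilt, columns = predicted tilt."""
    cm = np.zeros((N_TILT_TYPES, N_TILT_TYPES), dtype=int)
    np.add.at(cm, (np.asarray(actual) - 1, np.asarray(predicted) - 1), 1)
    return cm


def decode_offline(
    session: SessionRecording,
    hemisphere: str | None = None,
    first_n: int | None = None,
    bin_width_ms: float = DEFAULT_BIN_MS,
    window: tuple[float, float] = DEFAULT_WINDOW,
    neuron_ids: list[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Leave-one-out decoding of a session; returns (confusion, accuracy)."""
    if neuron_ids is None:
        neuron_ids = session.roster(hemisphere)
    if not neuron_ids:
        raise RosterError("empty decoding roster")
    trials = session.trials
    if first_n is not None:
        trials = trials.iloc[:first_n]
    labels = trials["tilt_type"].to_numpy()
    edges = make_bin_edges(bin_width_ms, window)
    counts = bin_spike_counts(session, neuron_ids, edges, trials["trial_id"].to_numpy())
    flat = counts.reshape(len(labels), -1)
    preds = _loo_predict(flat, labels)
    cm = confusion_matrix(labels, preds)
    return cm, float((preds == labels).mean())


def reconcile_roster(
    yesterday: SessionRecording, today: SessionRecording
) -> list[str]:
    """Decoding roster: neurons that fired (>=1 spike) on both days.

    Neurons that stopped firing since yesterday are dropped; neurons
    newly appearing today are recorded but become eligible only once
    they have a previous-day recording to build templates from.
    """
    y_active = set(yesterday.spikes["neuron_id"].unique())
    t_active = set(today.spikes["neuron_id"].unique())
    y_roster = set(yesterday.roster())
    t_roster = set(today.roster())
    usable = (y_active & y_roster) & (t_active & t_roster)
    return sorted(usable)


def decode_online(
    today: SessionRecording,
    yesterday: SessionRecording,
    bin_width_ms: float = DEFAULT_BIN_MS,
    window: tuple[float, float] = DEFAULT_WINDOW,
    hemisphere: str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Classify every trial of ``today`` with yesterday-derived templates.

    Returns the confusion matrix and today's trial table with
    ``predicted`` and ``outcome`` columns filled in.
    """
    roster = reconcile_roster(yesterday, today)
    if hemisphere is not None:
        keep = set(today.roster(hemisphere))
        roster = [n for n in roster if n in keep]
    if not roster:
        raise RosterError("no neurons usable by the decoder today")
    templates = build_templates(yesterday, roster, bin_width_ms, window)
    edges = templates.bin_edges
    trial_ids = today.trials["trial_id"].to_numpy()
    counts = bin_spike_counts(today, roster, edges, trial_ids)
    stacked = templates.stacked()
    flat = counts.reshape(len(trial_ids), -1)
    d2 = ((flat[:, None, :] - stacked[None, :, :]) ** 2).sum(axis=2)
    preds = np.argmin(d2, axis=1) + 1
    labels = today.trials["tilt_type"].to_numpy()
    outcomes = today.trials.copy()
    outcomes["predicted"] = preds
    outcomes["outcome"] = np.where(preds == labels, "correct", "incorrect")
    return confusion_matrix(labels, preds), outcomes
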