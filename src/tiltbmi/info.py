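"""Mutual information, shuffle bias correction, and ensemble redundancy.

Information about tilt type carried by a neuron (or ensemble) is read
off the confusion matrix of the leave-one-out PSTH-template classifier:

    I(r; s) = sum_{r,s} P[r,s] log2( P[r,s] / (P[r] P[s]) )

with plug-in probabilities from the confusion counts and the convention
0·log 0 = 0.  With four equiprobable tilt types the information is
bounded by 2 bits.  Finite sampling inflates the plug-in estimate, so a
shuffle bias is subtracted: the tilt labels are randomly permuted
(destroying any response–stimulus association), the classifier is re-run
and the information recomputed; the mean over ``n_shuffles``
permutations estimates the bias.  Only units whose bias-corrected
information is strictly positive are included in population analyses.

Spike-timing information uses 20 ms bins over the 0–200 ms post-tilt
window (10 bins); spike-count information uses a single 200 ms bin;
their difference is the temporal information contributed by spike
timing beyond the overall count.

Ensemble redundancy follows

    P = I_ensemble - sum_i I_neuron_i,

reported sign-inverted (redundancy = -P) so that larger values mean a
more redundant population code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synth import N_TILT_TYPES, SessionRecording
from .decoder import (
    DegenerateInputError,
    bin_spike_counts,
    confusion_matrix,
    make_bin_edges,
    _loo_predict,
)

INFO_WINDOW = (0.0, 200.0)
TIMING_BIN_MS = 20.0
COUNT_BIN_MS = 200.0
DEFAULT_N_SHUFFLES = 50

__all__ = [
    "InfoEstimate",
    "RedundancyResult",
    "mutual_information",
    "bias_corrected_information",
    "timing_and_count_information",
    "redundancy",
    "info_redundancy_correlation",
]


@dataclass(frozen=True)
class InfoEstimate:
    """Raw, bias, and bias-corrected information in bits for one unit."""

    raw_info: float
    bias: float
    corrected_info: float
    n_shuffles: int
    mode: str  # "timing" | "count" | "ensemble"

    @property
    def included(self) -> bool:
        """Strictly-positive corrected information qualifies for analysis."""
        return self.corrected_info > 0.0


@dataclass(frozen=True)
class RedundancyResult:
    ensemble_info: float
    sum_single_info: float
    n_neurons_included: int

    @property
    def p_value_bits(self) -> float:
        """P = I_ensemble - sum of single-neuron information (bits)."""
        return self.ensemble_info - self.sum_single_info

    @property
    def redundancy(self) -> float:
        """Sign-inverted P: positive when the code is redundant."""
        return -self.p_value_bits


def mutual_information(cm: np.ndarray) -> float:
    """Mutual information (bits) of a confusion matrix of counts."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix has no counts")
    p = cm / total
    pr = p.sum(axis=1, keepdims=True)  # actual-tilt marginal
    ps = p.sum(axis=0, keepdims=True)  # predicted-tilt marginal
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pr * ps))
    return float(np.nansum(terms))


def bias_corrected_information(
    responses: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator = 0,
    mode: str = "timing",
) -> InfoEstimate:
    """Shuffle-bias-corrected information of binned trial responses.

    ``responses`` is (n_trials, D); ``labels`` are tilt types 1..4 with
    at least two trials per type.  Raw information comes from the
    leave-one-out nearest-template confusion matrix; the bias is the
    mean information over ``n_shuffles`` label permutations with the
    classification re-run against each shuffled labelling.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    labels = np.asarray(labels)
    responses = np.asarray(responses, dtype=float)
    if responses.ndim == 1:
        responses = responses[:, None]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    preds = _loo_predict(responses, labels)
    raw = mutual_information(confusion_matrix(labels, preds))
    bias_vals = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = rng.permutation(labels)
        sp = _loo_predict(responses, shuffled)
        bias_vals[k] = mutual_information(confusion_matrix(shuffled, sp))
    bias = float(bias_vals.mean())
    return InfoEstimate(
        raw_info=raw,
        bias=bias,
        corrected_info=raw - bias,
        n_shuffles=n_shuffles,
        mode=mode,
    )


def _neuron_responses(
    session: SessionRecording,
    neuron_ids: list[str],
    bin_ms: float,
    first_n: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    trials = session.trials if first_n is None else session.trials.iloc[:first_n]
    edges = make_bin_edges(bin_ms, INFO_WINDOW)
    counts = bin_spike_counts(session, neuron_ids, edges, trials["trial_id"].to_numpy())
    return counts.reshape(len(trials), -1), trials["tilt_type"].to_numpy()


def timing_and_count_information(
    session: SessionRecording,
    neuron_id: str,
    first_n: int | None = 300,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator = 0,
) -> tuple[InfoEstimate, InfoEstimate]:
    """Spike-timing (20 ms bins) and spike-count (one 200 ms bin) information.

    Both use the 0–200 ms post-tilt window and the same shuffle bias
    correction; temporal information is ``timing.corrected_info -
    count.corrected_info``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    timing_resp, labels = _neuron_responses(session, [neuron_id], TIMING_BIN_MS, first_n)
    count_resp, _ = _neuron_responses(session, [neuron_id], COUNT_BIN_MS, first_n)
    timing = bias_corrected_information(timing_resp, labels, n_shuffles, rng, mode="timing")
    count = bias_corrected_information(count_resp, labels, n_shuffles, rng, mode="count")
    return timing, count


def redundancy(
    session: SessionRecording,
    hemisphere: str | None = None,
    first_n: int | None = 300,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int | np.random.Generator = 0,
    neuron_ids: list[str] | None = None,
) -> RedundancyResult:
    """Ensemble-vs-single-neuron information redundancy for one hemisphere.

    The ensemble estimate decodes all the hemisphere's neurons jointly;
    the single-neuron sum includes only neurons whose bias-corrected
    information is strictly positive.  Both use 20 ms timing bins over
    0–200 ms.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if neuron_ids is None:
        neuron_ids = session.roster(hemisphere)
    if not neuron_ids:
        raise DegenerateInputError("no neurons in hemisphere")
    singles: list[InfoEstimate] = []
    for nid in neuron_ids:
        resp, labels = _neuron_responses(session, [nid], TIMING_BIN_MS, first_n)
        singles.append(bias_corrected_information(resp, labels, n_shuffles, rng, mode="timing"))
    included = [e for e in singles if e.included]
    if not included:
        raise DegenerateInputError("no neurons with positive corrected information")
    if len(neuron_ids) == 1:
        # single-neuron hemisphere: the ensemble IS the neuron, P identically 0
        return RedundancyResult(
            ensemble_info=singles[0].corrected_info,
            sum_single_info=singles[0].corrected_info,
            n_neurons_included=1,
        )
    ens_resp, labels = _neuron_responses(session, list(neuron_ids), TIMING_BIN_MS, first_n)
    ensemble = bias_corrected_information(ens_resp, labels, n_shuffles, rng, mode="ensemble")
    return RedundancyResult(
        ensemble_info=ensemble.corrected_info,
        sum_single_info=float(sum(e.corrected_info for e in included)),
        n_neurons_included=len(included),
    )


def info_redundancy_correlation(
    mean_info_per_day: np.ndarray, redundancy_z_per_day: np.ndarray
) -> float:
    """Pearson r between per-day mean neuron information and redundancy z.

    Returns NaN when either series has zero variance (undefined
    correlation, reported as missing).
    """
    x = np.asarray(mean_info_per_day, dtype=float)
    y = np.asarray(redundancy_z_per_day, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired days")
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
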