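"""Single-neuron response characterization.

A neuron is *responsive* to a tilt type when its fine-binned (2 ms)
PSTH shows at least 5 consecutive bins above a background-derived
threshold (background mean + 2 SD of the pre-tilt 2 ms bin values) and
the firing in that detected window is significantly above the per-trial
background rate (one-sided paired t-test at p < 0.001).  For
responsive neurons the peak response (PR) is the maximum-bin spike
count per trial after subtracting the background expectation per bin,
and the peak latency (PL) is that bin's center time.  Across tilt
types, only the most responsive profile (largest PR) is kept so each
neuron contributes one observation per day.

The normalized variance (NV) is a Fano-factor-style preparedness
measure of the pre-tilt state: trial-to-trial variance of the spike
count in a single 200 ms background bin divided by the offset mean,
NV = var(c) / (mean(c) + eps) with eps = 0.01.  Per-tilt NVs are
z-scored against the baseline session and averaged over the four tilt
types into one value per hemisphere per day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synth import N_TILT_TYPES, SessionRecording
from .decoder import DegenerateInputError, bin_spike_counts, make_bin_edges

FINE_BIN_MS = 2.0
BACKGROUND_WINDOW = (-200.0, 0.0)
RESPONSE_WINDOW = (0.0, 200.0)
MIN_CONSECUTIVE_BINS = 5
DEFAULT_THRESHOLD_SD = 2.0
DEFAULT_ALPHA = 0.001
NV_EPS = 0.01
NV_BIN_S = 0.2

__all__ = [
    "ResponseProfile",
    "detect_responsive",
    "peak_response_latency",
    "most_responsive_profile",
    "normalized_variance",
    "session_normalized_variance",
    "zscore_to_baseline",
]


@dataclass(frozen=True)
class ResponseProfile:
    neuron_id: str
    tilt_type: int
    responsive: bool
    peak_response: float | None  # spikes/trial, background-subtracted
    peak_latency_ms: float | None  # bin-center time after tilt onset
    response_window_ms: tuple[float, float] | None


def _longest_run_window(above: np.ndarray) -> tuple[int, int] | None:
    """First run of >= MIN_CONSECUTIVE_BINS supra-threshold bins, as index bounds."""
    run_start, best = None, None
    count = 0
    for i, flag in enumerate(above):
        if flag:
            if count == 0:
                run_start = i
            count += 1
            if count >= MIN_CONSECUTIVE_BINS and best is None:
                best = run_start
        else:
            count = 0
    if best is None:
        return None
    # extend to the full contiguous run starting at best
    end = best
    while end < len(above) and above[end]:
        end += 1
    return best, end


def detect_responsive(
    session: SessionRecording,
    neuron_id: str,
    tilt_type: int,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    alpha: float = DEFAULT_ALPHA,
    trial_ids: np.ndarray | None = None,
) -> tuple[bool, tuple[float, float] | None]:
    """Responsiveness test for one neuron × tilt type.

    Returns ``(responsive, response_window_ms)`` where the window covers
    the detected supra-threshold run in the 0–200 ms PSTH.
    """
    trials = session.trials
    tids = trials.loc[trials["tilt_type"] == tilt_type, "trial_id"].to_numpy()
    if trial_ids is not None:
        tids = tids[np.isin(tids, trial_ids)]
    if len(tids) < 2:
        raise DegenerateInputError("need >= 2 trials of the tilt type")

    bg_edges = make_bin_edges(FINE_BIN_MS, BACKGROUND_WINDOW)
    rs_edges = make_bin_edges(FINE_BIN_MS, RESPONSE_WINDOW)
    bg_counts = bin_spike_counts(session, [neuron_id], bg_edges, tids)[:, 0, :]
    rs_counts = bin_spike_counts(session, [neuron_id], rs_edges, tids)[:, 0, :]

    bg_psth = bg_counts.mean(axis=0)  # spikes/trial per 2 ms bin
    rs_psth = rs_counts.mean(axis=0)
    thresh = bg_psth.mean() + threshold_sd * bg_psth.std(ddof=1)
    above = rs_psth > thresh
    run = _longest_run_window(above)
    if run is None:
        return False, None
    i0, i1 = run
    window = (float(rs_edges[i0]), float(rs_edges[i1]))
    if window[1] - window[0] < MIN_CONSECUTIVE_BINS * FINE_BIN_MS:
        return False, None

    # paired test: per-trial mean rate in the detected window vs background
    win_rate = rs_counts[:, i0:i1].mean(axis=1)
    bg_rate = bg_counts.mean(axis=1)
    diff = win_rate - bg_rate
    if np.allclose(diff.std(ddof=1), 0.0):
        significant = bool(diff.mean() > 0)
    else:
        t_res = stats.ttest_rel(win_rate, bg_rate, alternative="greater")
        significant = bool(t_res.pvalue < alpha)
    return (True, window) if significant else (False, None)


def peak_response_latency(
    session: SessionRecording,
    neuron_id: str,
    tilt_type: int,
    trial_ids: np.ndarray | None = None,
    bin_ms: float = FINE_BIN_MS,
) -> tuple[float, float]:
    """Peak response (spikes/trial, background-subtracted) and its latency.

    PR = (max-bin spike count / n_trials) - background spikes per bin
    per trial, with the background rate estimated from the pre-tilt
    window of the same trials; PL is the center of the peak bin relative
    to tilt onset.
    """
    trials = session.trials
    tids = trials.loc[trials["tilt_type"] == tilt_type, "trial_id"].to_numpy()
    if trial_ids is not None:
        tids = tids[np.isin(tids, trial_ids)]
    if len(tids) == 0:
        raise DegenerateInputError("no trials of the tilt type")
    rs_edges = make_bin_edges(bin_ms, RESPONSE_WINDOW)
    bg_edges = make_bin_edges(bin_ms, BACKGROUND_WINDOW)
    rs = bin_spike_counts(session, [neuron_id], rs_edges, tids)[:, 0, :]
    bg = bin_spike_counts(session, [neuron_id], bg_edges, tids)[:, 0, :]
    psth = rs.mean(axis=0)
    bg_per_bin = bg.mean()  # spikes per trial per bin
    peak_idx = int(np.argmax(psth))
    pr = float(psth[peak_idx] - bg_per_bin)
    centers = (rs_edges[:-1] + rs_edges[1:]) / 2.0
    return pr, float(centers[peak_idx])


def most_responsive_profile(
    session: SessionRecording,
    neuron_id: str,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    alpha: float = DEFAULT_ALPHA,
    trial_ids: np.ndarray | None = None,
) -> ResponseProfile:
    """One observation per neuron: the tilt type with the largest PR.

    Non-responsive neurons return a profile with ``responsive=False``
    and no PR/PL.
    """
    best: ResponseProfile | None = None
    for tilt in range(1, N_TILT_TYPES + 1):
        responsive, window = detect_responsive(
            session, neuron_id, tilt, threshold_sd, alpha, trial_ids
        )
        if not responsive:
            continue
        pr, pl = peak_response_latency(session, neuron_id, tilt, trial_ids)
        if best is None or (best.peak_response is not None and pr > best.peak_response):
            best = ResponseProfile(
                neuron_id=neuron_id,
                tilt_type=tilt,
                responsive=True,
                peak_response=pr,
                peak_latency_ms=pl,
                response_window_ms=window,
            )
    if best is None:
        return ResponseProfile(neuron_id, 0, False, None, None, None)
    return best


def normalized_variance(
    session: SessionRecording,
    neuron_id: str,
    tilt_type: int,
    first_n: int | None = 300,
    eps: float = NV_EPS,
    use_rate: bool = False,
) -> float:
    """Fano-style normalized variance of pre-tilt 200 ms spike counts.

    Counts per trial come from the single background bin [-200, 0) ms.
    Default form: NV = var(c) / (mean(c) + eps).  With ``use_rate`` the
    counts are first scaled to spikes/s by the 200 ms bin constant,
    which multiplies the ratio by 1/0.2.
    """
    trials = session.trials if first_n is None else session.trials.iloc[:first_n]
    tids = trials.loc[trials["tilt_type"] == tilt_type, "trial_id"].to_numpy()
    if len(tids) < 10:
        raise DegenerateInputError("need >= 10 trials of the tilt type")
    edges = make_bin_edges(200.0, BACKGROUND_WINDOW)
    counts = bin_spike_counts(session, [neuron_id], edges, tids)[:, 0, 0]
    if use_rate:
        counts = counts / NV_BIN_S
    return float(counts.var(ddof=1) / (counts.mean() + eps))


def session_normalized_variance(
    session: SessionRecording,
    hemisphere: str,
    baseline: SessionRecording,
    first_n: int | None = 300,
    eps: float = NV_EPS,
) -> float:
    """Per-day hemisphere NV: per-tilt values z-scored to baseline, averaged.

    The baseline spread is taken across that hemisphere's neurons for
    each tilt type; the four per-tilt mean z-scores are averaged into a
    single value for the hemisphere-day.
    """
    roster = session.roster(hemisphere)
    base_roster = baseline.roster(hemisphere)
    z_per_tilt = []
    for tilt in range(1, N_TILT_TYPES + 1):
        day_vals = np.array(
            [normalized_variance(session, n, tilt, first_n, eps) for n in roster]
        )
        base_vals = np.array(
            [normalized_variance(baseline, n, tilt, first_n, eps) for n in base_roster]
        )
        z = zscore_to_baseline(day_vals, base_vals)
        z_per_tilt.append(np.nanmean(z))
    return float(np.mean(z_per_tilt))


def zscore_to_baseline(values: np.ndarray, baseline_values: np.ndarray) -> np.ndarray:
    """z = (value - baseline mean) / baseline SD; NaN when SD is zero."""
    values = np.asarray(values, dtype=float)
    base = np.asarray(baseline_values, dtype=float)
    if len(base) < 2:
        raise DegenerateInputError("baseline needs >= 2 observations")
    sd = base.std(ddof=1)
    if np.isclose(sd, 0.0):
        return np.full_like(values, np.nan)
    return (values - base.mean()) / sd
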