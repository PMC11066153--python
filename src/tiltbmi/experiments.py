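"""Canned simulation experiments exercising the full analysis chain.

Each function sets up a controlled synthetic condition (known tuning,
known group structure), runs the relevant pipeline pieces, and returns
summary numbers.  These are the package's self-characterization
experiments: chance-level behavior, bias-correction nulls, parameter
recovery, timing/count dissociation, and end-to-end learner recovery.

All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import synth, decoder, info, response, learning

__all__ = [
    "intertrial_linearity",
    "bias_correction_null",
    "duplicated_redundancy",
    "separation_recovery",
    "timing_count_dissociation",
    "learner_recovery",
    "poisson_normalized_variance",
]


def _flat_traj(n_days: int = 1) -> synth.TrajectorySpec:
    return synth.nonlearner_trajectory(n_days, drift_sd=0.0, disengagement_per_day=0.0)


def _uniform_specs(amps4, background=5.0, latencies=None, jitter=2.0, width=15.0):
    out = []
    for i, a in enumerate(amps4):
        out.append(
            synth.NeuronSpec(
                neuron_id=f"e{i:02d}",
                hemisphere="direct",
                background_rate=background,
                amplitudes=tuple(a),
                latencies=tuple(latencies[i] if latencies else (80.0,) * 4),
                jitter_sd=jitter,
                response_width=width,
            )
        )
    return out


def intertrial_linearity(
    n_sessions: int = 1000, n_trials: int = 300, p_correct: float = 0.5, seed: int = 0
) -> dict:
    """Cumulative-sum linearity of i.i.d. binary outcome sessions.

    Returns the fraction of sessions with r^2 > 0.99 and the mean slope
    (which estimates the per-trial success probability).
    """
    rng = np.random.default_rng(seed)
    above, slopes = 0, []
    for _ in range(n_sessions):
        outcomes = (rng.uniform(size=n_trials) < p_correct).astype(int)
        slope, _, r2 = learning.intertrial_cumsum(outcomes)
        above += r2 > 0.99
        slopes.append(slope)
    return {
        "fraction_r2_above_0.99": above / n_sessions,
        "mean_slope": float(np.mean(slopes)),
        "n_sessions": n_sessions,
    }


def bias_correction_null(
    n_seeds: int = 20, n_trials: int = 400, n_shuffles: int = 50, seed: int = 0
) -> dict:
    """Mean bias-corrected information of tilt-independent neurons.

    The ground truth is exactly 0 bits; the shuffle correction should
    recover it to within ~0.01 bits on average.
    """
    rng = np.random.default_rng(seed)
    specs = _uniform_specs([(0.0, 0.0, 0.0, 0.0)], background=10.0)
    vals = []
    for _ in range(n_seeds):
        rec = synth.simulate_session(specs, 0, _flat_traj(), n_trials, rng)
        resp, labels = info._neuron_responses(rec, [specs[0].neuron_id], 20.0, None)
        est = info.bias_corrected_information(resp, labels, n_shuffles, rng)
        vals.append(est.corrected_info)
    return {"mean_corrected_bits": float(np.mean(vals)), "n_seeds": n_seeds}


def duplicated_redundancy(n_seeds: int = 20, n_trials: int = 160, seed: int = 0) -> dict:
    """Redundancy of a neuron recorded twice (identical spike trains).

    The duplicated ensemble adds nothing over one copy while the
    single-neuron sum doubles, so the inverted redundancy must come out
    positive in essentially every run.
    """
    rng = np.random.default_rng(seed)
    specs = _uniform_specs([(90.0, 0.0, 0.0, 0.0)], background=2.0)
    positive = 0
    for _ in range(n_seeds):
        rec = synth.simulate_session(specs, 0, _flat_traj(), n_trials, rng)
        dup = rec.spikes[rec.spikes["neuron_id"] == specs[0].neuron_id].assign(
            neuron_id="copy"
        )
        rec2 = synth.SessionRecording(
            animal_id=rec.animal_id,
            day=rec.day,
            trials=rec.trials,
            spikes=pd.concat([rec.spikes, dup], ignore_index=True),
            neurons=pd.concat(
                [rec.neurons, pd.DataFrame({"neuron_id": ["copy"], "hemisphere": ["direct"]})],
                ignore_index=True,
            ),
        )
        res = info.redundancy(rec2, first_n=None, n_shuffles=10, seed=rng)
        positive += res.redundancy > 0
    return {"fraction_positive": positive / n_seeds, "n_seeds": n_seeds}


def separation_recovery(
    levels: tuple = (0.0, 12.0, 24.0, 36.0, 48.0),
    n_seeds: int = 10,
    n_trials: int = 400,
    seed: int = 0,
) -> dict:
    """Offline accuracy as a function of tilt-type amplitude separation.

    Returns per-level mean accuracy across seeds, the Spearman rank
    correlation of accuracy with separation, and the per-seed accuracy
    at zero separation (which must sit at 4-way chance).
    """
    rng = np.random.default_rng(seed)
    mean_acc, zero_accs = [], []
    for sep in levels:
        accs = []
        for _ in range(n_seeds):
            amps = [
                (20.0 + sep, 20.0, 20.0, 20.0),
                (20.0, 20.0 + sep, 20.0, 20.0),
            ]
            specs = _uniform_specs(amps, background=5.0)
            rec = synth.simulate_session(specs, 0, _flat_traj(), n_trials, rng)
            accs.append(decoder.decode_offline(rec)[1])
        mean_acc.append(float(np.mean(accs)))
        if sep == 0.0:
            zero_accs = accs
    rho = float(stats.spearmanr(levels, mean_acc).statistic)
    return {
        "levels": list(levels),
        "mean_accuracy": mean_acc,
        "spearman_rho": rho,
        "zero_separation_accuracies": zero_accs,
        "n_trials": n_trials,
    }


def timing_count_dissociation(n_seeds: int = 10, n_trials: int = 300, seed: int = 0) -> dict:
    """Information decomposition for latency-only vs rate-only tuning.

    Latency-tuned neurons (equal spike counts, distinct latencies) carry
    timing but no count information; rate-tuned neurons (shared latency,
    distinct amplitudes) carry the same information in both codes.
    """
    rng = np.random.default_rng(seed)
    lat_specs = _uniform_specs(
        [(60.0,) * 4], latencies=[(20.0, 70.0, 120.0, 170.0)],
        background=2.0, jitter=3.0, width=8.0,
    )
    rate_specs = _uniform_specs([(60.0, 25.0, 5.0, 0.0)], background=3.0, jitter=3.0)
    lat_timing, lat_count, rate_diff = [], [], []
    for _ in range(n_seeds):
        rec = synth.simulate_session(lat_specs, 0, _flat_traj(), n_trials, rng)
        t, c = info.timing_and_count_information(
            rec, lat_specs[0].neuron_id, first_n=None, n_shuffles=20, seed=rng
        )
        lat_timing.append(t.corrected_info)
        lat_count.append(c.corrected_info)
        rec = synth.simulate_session(rate_specs, 0, _flat_traj(), n_trials, rng)
        t, c = info.timing_and_count_information(
            rec, rate_specs[0].neuron_id, first_n=None, n_shuffles=20, seed=rng
        )
        rate_diff.append(t.corrected_info - c.corrected_info)

    def ci95(x):
        x = np.asarray(x)
        half = 1.96 * x.std(ddof=1) / np.sqrt(len(x))
        return float(x.mean() - half), float(x.mean() + half)

    return {
        "latency_timing_mean": float(np.mean(lat_timing)),
        "latency_timing_ci95": ci95(lat_timing),
        "latency_count_mean": float(np.mean(lat_count)),
        "latency_count_ci95": ci95(lat_count),
        "rate_timing_minus_count_mean": float(np.mean(rate_diff)),
        "rate_timing_minus_count_ci95": ci95(rate_diff),
        "n_seeds": n_seeds,
    }


def learner_recovery(
    n_cohort_seeds: int = 10,
    n_learners: int = 4,
    n_nonlearners: int = 4,
    n_days: int = 10,
    n_trials: int = 120,
    n_neurons: int = 6,
    seed: int = 0,
) -> dict:
    """End-to-end group recovery: simulate, decode daily, relabel animals."""
    rng = np.random.default_rng(seed)
    correct = total = 0
    per_seed = []
    for _ in range(n_cohort_seeds):
        cohort_seed = int(rng.integers(0, 2**31 - 1))
        sessions, ledger = synth.simulate_experiment(
            {"learner": n_learners, "nonlearner": n_nonlearners},
            n_neurons_per_hemisphere=n_neurons,
            n_days=n_days,
            n_trials=n_trials,
            seed=cohort_seed,
        )
        seed_correct = 0
        for animal, recs in sessions.items():
            days, accs = [], []
            for rec in recs[1:]:
                _, acc = decoder.decode_offline(rec, hemisphere="direct", first_n=300)
                days.append(rec.day)
                accs.append(acc)
            series = learning.normalize_performance(days, accs, days[0], animal)
            label = learning.classify_learner(series)
            seed_correct += label == ledger["animals"][animal]["group"]
        per_seed.append(seed_correct)
        correct += seed_correct
        total += n_learners + n_nonlearners
    return {
        "fraction_correct": correct / total,
        "per_seed_correct": per_seed,
        "animals_per_seed": n_learners + n_nonlearners,
        "n_cohort_seeds": n_cohort_seeds,
    }


def poisson_normalized_variance(n_trials: int = 4000, seed: int = 0) -> dict:
    """NV of a constant-rate Poisson neuron (ground truth Fano = 1)."""
    specs = _uniform_specs([(0.0, 0.0, 0.0, 0.0)], background=10.0)
    rec = synth.simulate_session(specs, 0, _flat_traj(), n_trials, seed)
    nv = response.normalized_variance(rec, specs[0].neuron_id, 1, first_n=None)
    return {"nv": nv, "trials_per_tilt": n_trials // 4}
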