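"""Synthetic spike-train generator for the tilt-BMI task.

Emulates session recordings from rats standing on a tilting platform:
four tilt types (1 = fast right, 2 = slow right, 3 = fast left,
4 = slow left) delivered in randomized balanced order, spike times
recorded relative to tilt onset in a ±200 ms window, neurons split into
a *direct* hemisphere (drives the decoder) and an *indirect* hemisphere
(recorded only).  Each neuron fires as an inhomogeneous Poisson process:
a constant background rate plus, on each trial, a Gaussian bump of
excess rate tuned to the trial's tilt type.  Day-by-day trajectories
reshape the tuning to mimic learning (growing tilt-type separation of
direct neurons), non-learning (flat), or yoked control animals.

Ground-truth parameters for every simulated day are returned so that
downstream estimators (peak response, latency, information) can be
checked against what was actually generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

N_TILT_TYPES = 4
WINDOW_MS = (-200.0, 200.0)
TILT_LABELS = {1: "fast_right", 2: "slow_right", 3: "fast_left", 4: "slow_left"}

__all__ = [
    "NeuronSpec",
    "TrajectorySpec",
    "SessionRecording",
    "simulate_session",
    "simulate_experiment",
    "learner_trajectory",
    "nonlearner_trajectory",
    "control_trajectory",
    "sample_neuron_specs",
    "write_session",
    "read_session",
]


class ParameterError(ValueError):
    """Raised when a simulation spec violates its invariants."""


@dataclass(frozen=True)
class NeuronSpec:
    """Tuning parameters of one simulated neuron.

    Rates are in spikes/s, times in ms relative to tilt onset.  The four
    amplitudes/latencies index tilt types 1..4.
    """

    neuron_id: str
    hemisphere: str  # "direct" | "indirect"
    background_rate: float
    amplitudes: tuple[float, float, float, float]
    latencies: tuple[float, float, float, float]
    jitter_sd: float
    response_width: float

    def __post_init__(self) -> None:
        if self.hemisphere not in ("direct", "indirect"):
            raise ParameterError(f"unknown hemisphere {self.hemisphere!r}")
        if self.background_rate < 0:
            raise ParameterError("background_rate must be >= 0")
        if len(self.amplitudes) != N_TILT_TYPES or any(a < 0 for a in self.amplitudes):
            raise ParameterError("need 4 non-negative amplitudes")
        if len(self.latencies) != N_TILT_TYPES or any(
            not 0.0 <= l <= 200.0 for l in self.latencies
        ):
            raise ParameterError("latencies must lie in [0, 200] ms")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")
        if self.response_width <= 0:
            raise ParameterError("response_width must be > 0")


@dataclass(frozen=True)
class TrajectorySpec:
    """Per-day multipliers/shifts applied to a cohort's neuron specs.

    Arrays are indexed by day 0..n_days where day 0 is the baseline
    session and must be the identity (multiplier 1, shift 0).  Keys of
    each dict are hemisphere roles ("direct", "indirect").

    * ``amplitude_separation`` scales each neuron's tilt-type amplitude
      spread about its mean amplitude (1 = unchanged).
    * ``latency_shift`` is an additive shift in ms.
    * ``jitter_scale`` multiplies the trial-to-trial jitter SD.
    * ``background_scale`` multiplies the background rate.
    """

    group: str  # "learner" | "nonlearner" | "control"
    n_days: int
    amplitude_separation: dict[str, np.ndarray]
    latency_shift: dict[str, np.ndarray]
    jitter_scale: dict[str, np.ndarray]
    background_scale: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.group not in ("learner", "nonlearner", "control"):
            raise ParameterError(f"unknown group {self.group!r}")
        if self.n_days < 1:
            raise ParameterError("n_days must be >= 1")
        for name in ("amplitude_separation", "jitter_scale", "background_scale"):
            d = getattr(self, name)
            for role, arr in d.items():
                if len(arr) != self.n_days + 1:
                    raise ParameterError(f"{name}[{role}] must have n_days+1 entries")
                if not np.isclose(arr[0], 1.0):
                    raise ParameterError(f"{name}[{role}] day 0 must be identity (1)")
        for role, arr in self.latency_shift.items():
            if len(arr) != self.n_days + 1:
                raise ParameterError(f"latency_shift[{role}] must have n_days+1 entries")
            if not np.isclose(arr[0], 0.0):
                raise ParameterError(f"latency_shift[{role}] day 0 must be identity (0)")


@dataclass
class SessionRecording:
    """One animal-day of spikes and trials.

    ``trials`` columns: trial_id, tilt_type (1..4), outcome
    ("correct" | "incorrect" | "n/a").  ``spikes`` columns: neuron_id,
    trial_id, time_ms (relative to tilt onset, in [-200, 200)).
    ``neurons`` columns: neuron_id, hemisphere.
    """

    animal_id: str
    day: int
    trials: pd.DataFrame
    spikes: pd.DataFrame
    neurons: pd.DataFrame

    def __post_init__(self) -> None:
        bad_tilt = set(self.trials["tilt_type"].unique()) - set(range(1, N_TILT_TYPES + 1))
        if bad_tilt:
            raise ParameterError(f"tilt types outside 1..4: {sorted(bad_tilt)}")
        known_trials = set(self.trials["trial_id"])
        known_neurons = set(self.neurons["neuron_id"])
        if not set(self.spikes["trial_id"]).issubset(known_trials):
            raise ParameterError("spikes reference unknown trials")
        if not set(self.spikes["neuron_id"]).issubset(known_neurons):
            raise ParameterError("spikes reference unknown neurons")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def roster(self, hemisphere: str | None = None) -> list[str]:
        """Neuron ids, optionally restricted to one hemisphere role."""
        df = self.neurons
        if hemisphere is not None:
            df = df[df["hemisphere"] == hemisphere]
        return list(df["neuron_id"])


def _flat(n_days: int, value: float = 1.0) -> np.ndarray:
    a = np.full(n_days + 1, value)
    a[0] = value if value in (0.0, 1.0) else value
    return a


def _identity_traj(group: str, n_days: int) -> dict[str, dict[str, np.ndarray]]:
    roles = ("direct", "indirect")
    return {
        "amplitude_separation": {r: np.ones(n_days + 1) for r in roles},
        "latency_shift": {r: np.zeros(n_days + 1) for r in roles},
        "jitter_scale": {r: np.ones(n_days + 1) for r in roles},
        "background_scale": {r: np.ones(n_days + 1) for r in roles},
    }


BACKGROUND_DRIFT_PER_DAY = 0.02  # slow rise in background rate, all groups


def _drifting_background(n_days: int) -> np.ndarray:
    """Shared slow background-rate drift (recording degradation)."""
    days = np.arange(n_days + 1, dtype=float)
    scale = 1.0 + BACKGROUND_DRIFT_PER_DAY * days
    scale[0] = 1.0
    return scale


def learner_trajectory(
    n_days: int,
    max_separation: float = 2.5,
    tau_days: float = 5.0,
    indirect_latency_peak_ms: float = 20.0,
    late_jitter_scale: float = 0.6,
) -> TrajectorySpec:
    """Trajectory of a learning animal.

    Direct-neuron tilt-type separation rises monotonically with a fast
    early phase and a slow late phase (saturating exponential with time
    constant ``tau_days``); direct jitter shrinks late in training
    (temporal precision gain).  Indirect neurons transiently shift their
    response latency in the early phase and relax back late.  All
    groups share a slow monotone rise in background rate.
    """
    d = _identity_traj("learner", n_days)
    for role in ("direct", "indirect"):
        d["background_scale"][role] = _drifting_background(n_days)
    days = np.arange(n_days + 1, dtype=float)
    ramp = 1.0 + (max_separation - 1.0) * (1.0 - np.exp(-days / tau_days))
    ramp[0] = 1.0
    d["amplitude_separation"]["direct"] = ramp
    jit = 1.0 + (late_jitter_scale - 1.0) * (1.0 - np.exp(-days / (2 * tau_days)))
    jit[0] = 1.0
    d["jitter_scale"]["direct"] = jit
    # indirect latency: up early, back down late
    lat = indirect_latency_peak_ms * (days / tau_days) * np.exp(1.0 - days / tau_days)
    lat[0] = 0.0
    d["latency_shift"]["indirect"] = lat
    return TrajectorySpec(group="learner", n_days=n_days, **d)


def nonlearner_trajectory(
    n_days: int,
    drift_sd: float = 0.03,
    seed: int | None = None,
    disengagement_per_day: float = 0.02,
) -> TrajectorySpec:
    """Trajectory of a non-learning animal.

    Tilt-type separation declines slowly (``disengagement_per_day``):
    animals that fail to gain reward disengage from the task and their
    evoked responses to the different tilts drift back together.
    Background rate drifts up with day-to-day noise, as for all groups.
    """
    d = _identity_traj("nonlearner", n_days)
    rng = np.random.default_rng(seed)
    days = np.arange(n_days + 1, dtype=float)
    sep = np.clip(1.0 - disengagement_per_day * days, 0.0, None)
    sep[0] = 1.0
    d["amplitude_separation"]["direct"] = sep
    d["amplitude_separation"]["indirect"] = sep.copy()
    for role in ("direct", "indirect"):
        noise = rng.normal(0.0, drift_sd, n_days + 1) if drift_sd > 0 else 0.0
        scale = _drifting_background(n_days) + noise
        scale[0] = 1.0
        d["background_scale"][role] = np.clip(scale, 0.5, 2.0)
    return TrajectorySpec(group="nonlearner", n_days=n_days, **d)


def control_trajectory(n_days: int, drift_sd: float = 0.03, seed: int | None = None) -> TrajectorySpec:
    """Yoked control: tuning identical to day 0 up to background drift noise."""
    t = nonlearner_trajectory(n_days, drift_sd=drift_sd, seed=seed, disengagement_per_day=0.0)
    return TrajectorySpec(
        group="control",
        n_days=n_days,
        amplitude_separation=t.amplitude_separation,
        latency_shift=t.latency_shift,
        jitter_scale=t.jitter_scale,
        background_scale=t.background_scale,
    )


def adjusted_spec(spec: NeuronSpec, day: int, trajectory: TrajectorySpec) -> NeuronSpec:
    """Apply a trajectory's day-``day`` adjustment to a base neuron spec."""
    if not 0 <= day <= trajectory.n_days:
        raise ParameterError(f"day {day} outside trajectory range 0..{trajectory.n_days}")
    role = spec.hemisphere
    sep = float(trajectory.amplitude_separation[role][day])
    shift = float(trajectory.latency_shift[role][day])
    jsc = float(trajectory.jitter_scale[role][day])
    bsc = float(trajectory.background_scale[role][day])
    amps = np.asarray(spec.amplitudes, dtype=float)
    mean_amp = amps.mean()
    new_amps = np.clip(mean_amp + sep * (amps - mean_amp), 0.0, None)
    new_lats = np.clip(np.asarray(spec.latencies, dtype=float) + shift, 0.0, 200.0)
    return NeuronSpec(
        neuron_id=spec.neuron_id,
        hemisphere=spec.hemisphere,
        background_rate=spec.background_rate * bsc,
        amplitudes=tuple(new_amps),
        latencies=tuple(new_lats),
        jitter_sd=spec.jitter_sd * jsc,
        response_width=spec.response_width,
    )


def _rate(t_ms: np.ndarray, bg: float, amp: np.ndarray, center: np.ndarray, width: float) -> np.ndarray:
    return bg + amp * np.exp(-((t_ms - center) ** 2) / (2.0 * width**2))


def simulate_session(
    neurons: list[NeuronSpec],
    day: int,
    trajectory: TrajectorySpec,
    n_trials: int,
    seed: int | np.random.Generator,
    animal_id: str = "sim",
) -> SessionRecording:
    """Simulate one session by thinning an inhomogeneous Poisson process.

    Trial order is a seeded random permutation balanced across the four
    tilt types (``n_trials`` must be divisible by 4).  For each trial
    the neuron's rate is background + a Gaussian bump of the
    day-adjusted amplitude for that trial's tilt type, centred at
    latency + N(0, jitter_sd), truncated to the ±200 ms window.
    """
    if n_trials % N_TILT_TYPES != 0:
        raise ParameterError("n_trials must be divisible by 4")
    if not neurons:
        raise ParameterError("need at least one neuron")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    tilt_types = np.tile(np.arange(1, N_TILT_TYPES + 1), n_trials // N_TILT_TYPES)
    tilt_types = rng.permutation(tilt_types)
    trial_ids = np.arange(n_trials)

    t0, t1 = WINDOW_MS
    window_s = (t1 - t0) / 1000.0

    spike_neurons: list[np.ndarray] = []
    spike_trials: list[np.ndarray] = []
    spike_times: list[np.ndarray] = []

    for spec in neurons:
        day_spec = adjusted_spec(spec, day, trajectory)
        amps = np.asarray(day_spec.amplitudes)[tilt_types - 1]
        lats = np.asarray(day_spec.latencies)[tilt_types - 1]
        centers = lats + rng.normal(0.0, day_spec.jitter_sd, n_trials)
        lam_max = day_spec.background_rate + amps  # per-trial thinning bound
        n_cand = rng.poisson(lam_max * window_s)
        total = int(n_cand.sum())
        if total == 0:
            continue
        cand_trial = np.repeat(trial_ids, n_cand)
        t = rng.uniform(t0, t1, total)
        lam = _rate(
            t,
            day_spec.background_rate,
            amps[cand_trial],
            centers[cand_trial],
            day_spec.response_width,
        )
        keep = rng.uniform(0.0, 1.0, total) * lam_max[cand_trial] < lam
        spike_neurons.append(np.full(keep.sum(), spec.neuron_id, dtype=object))
        spike_trials.append(cand_trial[keep])
        spike_times.append(t[keep])

    if spike_times:
        spikes = pd.DataFrame(
            {
                "neuron_id": np.concatenate(spike_neurons),
                "trial_id": np.concatenate(spike_trials).astype(int),
                "time_ms": np.concatenate(spike_times),
            }
        )
        spikes = spikes.sort_values(["neuron_id", "trial_id", "time_ms"], kind="stable").reset_index(drop=True)
    else:
        spikes = pd.DataFrame({"neuron_id": pd.Series(dtype=object), "trial_id": pd.Series(dtype=int), "time_ms": pd.Series(dtype=float)})

    trials = pd.DataFrame(
        {"trial_id": trial_ids, "tilt_type": tilt_types.astype(int), "outcome": "n/a"}
    )
    neuron_table = pd.DataFrame(
        {"neuron_id": [n.neuron_id for n in neurons], "hemisphere": [n.hemisphere for n in neurons]}
    )
    return SessionRecording(animal_id=animal_id, day=day, trials=trials, spikes=spikes, neurons=neuron_table)


def sample_neuron_specs(
    n_per_hemisphere: int,
    rng: np.random.Generator,
    background_range: tuple[float, float] = (3.0, 12.0),
    base_amplitude_range: tuple[float, float] = (15.0, 40.0),
    tuning_spread: float = 0.5,
    latency_range: tuple[float, float] = (30.0, 110.0),
    jitter_range: tuple[float, float] = (5.0, 15.0),
    width_range: tuple[float, float] = (10.0, 25.0),
    prefix: str = "n",
) -> list[NeuronSpec]:
    """Draw a plausible baseline roster for both hemispheres.

    Each neuron gets a base amplitude with a random per-tilt modulation
    (relative spread ``tuning_spread``), giving weak-but-present tilt
    tuning at baseline that trajectories can later separate or leave
    flat.
    """
    specs = []
    for hemi in ("direct", "indirect"):
        for i in range(n_per_hemisphere):
            base = rng.uniform(*base_amplitude_range)
            mods = np.clip(1.0 + rng.normal(0.0, tuning_spread, N_TILT_TYPES), 0.05, None)
            lat = rng.uniform(*latency_range)
            lat_mods = np.clip(lat + rng.normal(0.0, 10.0, N_TILT_TYPES), 0.0, 200.0)
            specs.append(
                NeuronSpec(
                    neuron_id=f"{prefix}_{hemi}_{i:02d}",
                    hemisphere=hemi,
                    background_rate=float(rng.uniform(*background_range)),
                    amplitudes=tuple(base * mods),
                    latencies=tuple(lat_mods),
                    jitter_sd=float(rng.uniform(*jitter_range)),
                    response_width=float(rng.uniform(*width_range)),
                )
            )
    return specs


def simulate_experiment(
    groups: dict[str, int],
    n_neurons_per_hemisphere: int,
    n_days: int,
    n_trials: int,
    seed: int,
    baseline_trials: int = 400,
    trajectory_kwargs: dict | None = None,
) -> tuple[dict[str, list[SessionRecording]], dict]:
    """Simulate a cohort: baseline (day 0) + ``n_days`` training sessions.

    ``groups`` maps group name ("learner"/"nonlearner"/"control") to the
    number of animals.  Returns ``(sessions, ledger)`` where ``sessions``
    maps animal id to its ordered day-0..day-n list and ``ledger``
    records group labels and every day-adjusted neuron spec (the ground
    truth for recovery tests).
    """
    if n_days < 1:
        raise ParameterError("n_days must be >= 1")
    if baseline_trials % N_TILT_TYPES != 0 or n_trials % N_TILT_TYPES != 0:
        raise ParameterError("trial counts must be divisible by 4")
    trajectory_kwargs = trajectory_kwargs or {}
    rng = np.random.default_rng(seed)
    factories = {
        "learner": lambda s: learner_trajectory(n_days, **trajectory_kwargs),
        "nonlearner": lambda s: nonlearner_trajectory(n_days, seed=s),
        "control": lambda s: control_trajectory(n_days, seed=s),
    }
    sessions: dict[str, list[SessionRecording]] = {}
    ledger: dict = {"seed": seed, "animals": {}}
    idx = 0
    for group, count in groups.items():
        if group not in factories:
            raise ParameterError(f"unknown group {group!r}")
        for _ in range(count):
            animal_id = f"{group[0]}rat{idx:02d}"
            idx += 1
            traj_seed = int(rng.integers(0, 2**31 - 1))
            traj = factories[group](traj_seed)
            specs = sample_neuron_specs(n_neurons_per_hemisphere, rng, prefix=animal_id)
            day_specs = {
                day: [asdict(adjusted_spec(s, day, traj)) for s in specs]
                for day in range(n_days + 1)
            }
            ledger["animals"][animal_id] = {"group": group, "day_specs": day_specs}
            recs = []
            for day in range(n_days + 1):
                nt = baseline_trials if day == 0 else n_trials
                recs.append(
                    simulate_session(specs, day, traj, nt, rng, animal_id=animal_id)
                )
            sessions[animal_id] = recs
    return sessions, ledger


# ---------------------------------------------------------------------------
# CSV persistence (one directory per session)

def write_session(rec: SessionRecording, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = rec.trials.copy()
    trials["day"] = rec.day
    trials["animal_id"] = rec.animal_id
    trials.to_csv(out / "trials.csv", index=False)
    rec.spikes.to_csv(out / "spikes.csv", index=False)
    rec.neurons.to_csv(out / "neurons.csv", index=False)
    return out


def read_session(in_dir: str | Path) -> SessionRecording:
    p = Path(in_dir)
    # keep_default_na: the "n/a" outcome is a literal value, not missing data
    trials = pd.read_csv(p / "trials.csv", keep_default_na=False)
    trials["trial_id"] = trials["trial_id"].astype(int)
    trials["tilt_type"] = trials["tilt_type"].astype(int)
    trials["day"] = trials["day"].astype(int)
    spikes = pd.read_csv(p / "spikes.csv", dtype={"neuron_id": str, "trial_id": int})
    if spikes.empty:
        spikes = pd.DataFrame({"neuron_id": pd.Series(dtype=object), "trial_id": pd.Series(dtype=int), "time_ms": pd.Series(dtype=float)})
    neurons = pd.read_csv(p / "neurons.csv", dtype=str)
    animal_id = str(trials["animal_id"].iloc[0])
    day = int(trials["day"].iloc[0])
    return SessionRecording(
        animal_id=animal_id,
        day=day,
        trials=trials[["trial_id", "tilt_type", "outcome"]].reset_index(drop=True),
        spikes=spikes,
        neurons=neurons,
    )


def write_ledger(ledger: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(ledger, indent=1, default=_default))
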