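"""Shared fixtures: hand-built and simulated sessions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tiltbmi import synth


def make_session(
    trial_tilts: list[int],
    spikes: list[tuple[str, int, float]],
    neurons: list[tuple[str, str]] | None = None,
    animal_id: str = "toy",
    day: int = 1,
) -> synth.SessionRecording:
    """Hand-built session: tilt types in trial order, explicit spike list."""
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(len(trial_tilts)),
            "tilt_type": trial_tilts,
            "outcome": "n/a",
        }
    )
    if neurons is None:
        ids = sorted({s[0] for s in spikes}) or ["n0"]
        neurons = [(n, "direct") for n in ids]
    spike_df = pd.DataFrame(spikes, columns=["neuron_id", "trial_id", "time_ms"])
    if spike_df.empty:
        spike_df = pd.DataFrame(
            {
                "neuron_id": pd.Series(dtype=object),
                "trial_id": pd.Series(dtype=int),
                "time_ms": pd.Series(dtype=float),
            }
        )
    neuron_df = pd.DataFrame(neurons, columns=["neuron_id", "hemisphere"])
    return synth.SessionRecording(
        animal_id=animal_id, day=day, trials=trials, spikes=spike_df, neurons=neuron_df
    )


def tuned_specs(
    amplitudes_by_neuron: list[tuple[float, float, float, float]],
    latencies_by_neuron: list[tuple[float, float, float, float]] | None = None,
    background: float = 5.0,
    jitter: float = 2.0,
    width: float = 15.0,
    hemisphere: str = "direct",
) -> list[synth.NeuronSpec]:
    """Specs with explicit per-tilt tuning for controlled simulations."""
    out = []
    for i, amps in enumerate(amplitudes_by_neuron):
        lats = latencies_by_neuron[i] if latencies_by_neuron else (80.0,) * 4
        out.append(
            synth.NeuronSpec(
                neuron_id=f"t{i:02d}",
                hemisphere=hemisphere,
                background_rate=background,
                amplitudes=tuple(amps),
                latencies=tuple(lats),
                jitter_sd=jitter,
                response_width=width,
            )
        )
    return out


def flat_trajectory(n_days: int = 1) -> synth.TrajectorySpec:
    """Identity trajectory (no drift) for isolating session-level behavior."""
    return synth.nonlearner_trajectory(n_days, drift_sd=0.0, disengagement_per_day=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def untuned_session():
    """400 balanced trials from a single flat 10 spikes/s Poisson neuron."""
    specs = tuned_specs([(0.0, 0.0, 0.0, 0.0)], background=10.0)
    return synth.simulate_session(specs, 0, flat_trajectory(), 400, seed=7)


@pytest.fixture
def strongly_tuned_session():
    """Four neurons, one strongly tuned to each tilt type; 200 trials."""
    amps = [
        (400.0, 0.0, 0.0, 0.0),
        (0.0, 400.0, 0.0, 0.0),
        (0.0, 0.0, 400.0, 0.0),
        (0.0, 0.0, 0.0, 400.0),
    ]
    specs = tuned_specs(amps, background=0.0, jitter=1.0, width=20.0)
    return synth.simulate_session(specs, 0, flat_trajectory(), 200, seed=11)
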