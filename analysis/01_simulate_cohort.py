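#!/usr/bin/env python
"""Simulate the synthetic tilt-BMI cohort.

One learner, one nonlearner, and one yoked control animal, each with a
400-trial day-0 baseline (100 per tilt type) and 10 training days of
120 trials, 6 neurons per hemisphere.  Sessions are written as CSV
tables under results/run/sessions/ together with the ground-truth
tuning ledger used by the later recovery checks.
"""

import json
from pathlib import Path

from tiltbmi import synth

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "run"
OUT = ROOT / "results" / "run"
SEED = 20240419


def main() -> None:
    sessions, ledger = synth.simulate_experiment(
        groups={"learner": 1, "nonlearner": 1, "control": 1},
        n_neurons_per_hemisphere=6,
        n_days=10,
        n_trials=120,
        baseline_trials=400,
        seed=SEED,
    )
    n = 0
    for animal, recs in sessions.items():
        for rec in recs:
            synth.write_session(rec, DATA / "sessions" / animal / f"day{rec.day:02d}")
            n += 1
    OUT.mkdir(parents=True, exist_ok=True)
    synth.write_ledger(ledger, DATA / "ground_truth.json")
    groups = {a: v["group"] for a, v in ledger["animals"].items()}
    print(f"wrote {n} sessions for {len(groups)} animals -> {DATA}")
    print(json.dumps(groups, indent=1))


if __name__ == "__main__":
    main()
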