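#!/usr/bin/env python
"""Learning-phase analysis: group labels, phases, naive-vs-expert distances.

Classifies each animal as learner or nonlearner from its offline
performance series (>= 5 consecutive training days above day 1), splits
training into early/late phases, and computes naive-day vs expert-day
population PSTH distances for the pooled tilt contrasts (right-vs-left
and fast-vs-slow).  Writes group_labels.csv and distance_points.csv
under results/run/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tiltbmi import synth, learning

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "run"
RUN = ROOT / "results" / "run"
FIRST_N = 300


def main() -> None:
    perf = pd.read_csv(RUN / "performance.csv")
    truth = {
        a: v["group"]
        for a, v in json.loads((DATA / "ground_truth.json").read_text())["animals"].items()
    }
    label_rows, dist_frames = [], []
    for animal, sub in perf.groupby("animal_id"):
        sub = sub.sort_values("day")
        days = sub["day"].tolist()
        series = learning.normalize_performance(
            days, sub["offline_accuracy"].tolist(), reference_day=days[0],
            animal_id=str(animal),
        )
        assigned = (
            "control" if truth[animal] == "control" else learning.classify_learner(series)
        )
        early, late = learning.split_phases(days)
        expert = learning.expert_day(series)
        norm = dict(zip(series.days, series.normalized))
        label_rows.append(
            {
                "animal_id": animal, "true_group": truth[animal],
                "assigned_group": assigned, "expert_day": expert,
                "early_mean_gain": float(np.mean([norm[d] for d in early])),
                "late_mean_gain": float(np.mean([norm[d] for d in late])),
            }
        )
        sessions_dir = DATA / "sessions" / str(animal)
        naive = synth.read_session(sessions_dir / "day00")
        expert_rec = synth.read_session(sessions_dir / f"day{expert:02d}")
        dist_frames.append(
            learning.naive_expert_distances(
                naive, expert_rec, neuron_ids=naive.roster("direct"), first_n=FIRST_N
            )
        )
    labels = pd.DataFrame(label_rows)
    dists = pd.concat(dist_frames, ignore_index=True)
    labels.to_csv(RUN / "group_labels.csv", index=False)
    dists.to_csv(RUN / "distance_points.csv", index=False)
    print(labels.round(3).to_string(index=False))
    print("\nnaive vs expert population PSTH distances (direct neurons):")
    print(dists.round(3).to_string(index=False))
    above = (dists["expert_distance"] > dists["naive_distance"]).groupby(
        dists["animal_id"]
    ).mean()
    print("\nfraction of contrasts above the identity line per animal:")
    print(above.round(2).to_string())


if __name__ == "__main__":
    main()
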