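#!/usr/bin/env python
"""Information and redundancy of direct vs indirect ensembles.

For every animal-day and hemisphere: per-neuron spike-timing (20 ms
bins) and spike-count (one 200 ms bin) bias-corrected information over
the 0-200 ms post-tilt window, ensemble redundancy, and per-animal
Pearson correlations between mean neuron information and the
redundancy z-score across training days.  Writes information.csv,
redundancy.csv and info_redundancy_correlation.csv under results/run/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tiltbmi import synth, info, response
from tiltbmi.decoder import DegenerateInputError

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "run"
RUN = ROOT / "results" / "run"
FIRST_N = 300
N_SHUFFLES = 50
SEED = 11


def main() -> None:
    rng = np.random.default_rng(SEED)
    info_rows, red_rows = [], []
    for animal_dir in sorted((DATA / "sessions").iterdir()):
        recs = [synth.read_session(d) for d in sorted(animal_dir.iterdir())]
        for rec in recs[1:]:
            for hemi in ("direct", "indirect"):
                for nid in rec.roster(hemi):
                    timing, count = info.timing_and_count_information(
                        rec, nid, first_n=FIRST_N, n_shuffles=N_SHUFFLES, seed=rng
                    )
                    for est in (timing, count):
                        info_rows.append(
                            {
                                "animal_id": rec.animal_id, "day": rec.day,
                                "unit": nid, "hemisphere": hemi, "mode": est.mode,
                                "raw_bits": est.raw_info, "bias_bits": est.bias,
                                "corrected_bits": est.corrected_info,
                                "included": est.included,
                            }
                        )
                try:
                    red = info.redundancy(
                        rec, hemi, first_n=FIRST_N, n_shuffles=N_SHUFFLES, seed=rng
                    )
                except DegenerateInputError:
                    continue
                red_rows.append(
                    {
                        "animal_id": rec.animal_id, "day": rec.day, "hemisphere": hemi,
                        "ensemble_bits": red.ensemble_info,
                        "sum_single_bits": red.sum_single_info,
                        "redundancy_bits": red.redundancy,
                        "n_included": red.n_neurons_included,
                    }
                )
    info_df = pd.DataFrame(info_rows)
    red_df = pd.DataFrame(red_rows)
    info_df.to_csv(RUN / "information.csv", index=False)
    red_df.to_csv(RUN / "redundancy.csv", index=False)

    # per-animal correlation: mean corrected timing info vs redundancy z
    corr_rows = []
    for (animal, hemi), sub in red_df.groupby(["animal_id", "hemisphere"]):
        sub = sub.sort_values("day")
        z = response.zscore_to_baseline(
            sub["redundancy_bits"].to_numpy(), sub["redundancy_bits"].to_numpy()
        )
        mi = (
            info_df.query("animal_id == @animal and hemisphere == @hemi and mode == 'timing'")
            .groupby("day")["corrected_bits"].mean()
            .reindex(sub["day"]).to_numpy()
        )
        r = info.info_redundancy_correlation(mi, z) if len(sub) >= 3 else float("nan")
        corr_rows.append({"animal_id": animal, "hemisphere": hemi, "pearson_r": r})
    corr_df = pd.DataFrame(corr_rows)
    corr_df.to_csv(RUN / "info_redundancy_correlation.csv", index=False)

    print(f"wrote {len(info_df)} information rows, {len(red_df)} redundancy rows")
    print("\nmean corrected timing information (bits) by hemisphere:")
    print(
        info_df.query("mode == 'timing'")
        .groupby(["animal_id", "hemisphere"])["corrected_bits"].mean()
        .round(3).to_string()
    )
    print("\ninfo-redundancy Pearson r per animal/hemisphere:")
    print(corr_df.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
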