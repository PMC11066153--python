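"""End-to-end pipeline: simulate -> decode -> metrics -> learning analysis.

Each stage reads and writes plain CSV/JSON under the run directory so
every intermediate is inspectable and re-runnable.  A manifest records
the configuration, a hash of it, and per-stage row counts; the whole
run is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth, decoder, info, response, learning

log = logging.getLogger("tiltbmi")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Defaults follow the experimental conventions: 20 ms decoder bins on
    a ±200 ms window, information in the 0–200 ms post-tilt window with
    50 label shuffles for bias correction, first 300 trials analyzed,
    NV epsilon 0.01, 400-trial baseline (100 per tilt type).
    """

    seed: int = 0
    groups: dict = field(default_factory=lambda: {"learner": 1, "nonlearner": 1, "control": 1})
    n_neurons_per_hemisphere: int = 6
    n_days: int = 10
    n_trials: int = 120
    baseline_trials: int = 400
    bin_width_ms: float = 20.0
    window: tuple = (-200.0, 200.0)
    first_n: int = 300
    n_shuffles: int = 50
    threshold_sd: float = 2.0
    alpha: float = 0.001
    nv_eps: float = 0.01
    out_dir: str = "runs/run0"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "window" in raw:
        raw["window"] = tuple(raw["window"])
    return PipelineConfig(**raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig, out: Path):
    sessions, ledger = synth.simulate_experiment(
        groups=cfg.groups,
        n_neurons_per_hemisphere=cfg.n_neurons_per_hemisphere,
        n_days=cfg.n_days,
        n_trials=cfg.n_trials,
        baseline_trials=cfg.baseline_trials,
        seed=cfg.seed,
    )
    for animal, recs in sessions.items():
        for rec in recs:
            synth.write_session(rec, out / "sessions" / animal / f"day{rec.day:02d}")
    synth.write_ledger(ledger, out / "ground_truth.json")
    return sessions, ledger


@_stage("decode")
def stage_decode(cfg: PipelineConfig, sessions: dict, out: Path) -> pd.DataFrame:
    rows = []
    for animal, recs in sessions.items():
        for prev, rec in zip(recs[:-1], recs[1:]):
            _, off_acc = decoder.decode_offline(
                rec, hemisphere="direct", first_n=cfg.first_n,
                bin_width_ms=cfg.bin_width_ms, window=cfg.window,
            )
            cm_on, outcomes = decoder.decode_online(rec, prev, cfg.bin_width_ms, cfg.window, hemisphere="direct")
            on_acc = float((outcomes["outcome"] == "correct").mean())
            slope, intercept, r2 = learning.intertrial_cumsum(
                (outcomes["outcome"].iloc[: cfg.first_n] == "correct").astype(int).to_numpy()
            )
            rows.append(
                {
                    "animal_id": animal,
                    "day": rec.day,
                    "offline_accuracy": off_acc,
                    "online_accuracy": on_acc,
                    "cumsum_slope": slope,
                    "cumsum_intercept": intercept,
                    "cumsum_r2": r2,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "performance.csv", index=False)
    return df


@_stage("metrics")
def stage_metrics(cfg: PipelineConfig, sessions: dict, out: Path) -> dict[str, pd.DataFrame]:
    rng = np.random.default_rng(cfg.seed + 1)
    info_rows, red_rows, nv_rows, resp_rows = [], [], [], []
    for animal, recs in sessions.items():
        baseline = recs[0]
        for rec in recs[1:]:
            for hemi in ("direct", "indirect"):
                roster = rec.roster(hemi)
                for nid in roster:
                    timing, count = info.timing_and_count_information(
                        rec, nid, first_n=cfg.first_n, n_shuffles=cfg.n_shuffles, seed=rng
                    )
                    for est in (timing, count):
                        info_rows.append(
                            {
                                "animal_id": animal,
                                "day": rec.day,
                                "unit": nid,
                                "hemisphere": hemi,
                                "mode": est.mode,
                                "raw_bits": est.raw_info,
                                "bias_bits": est.bias,
                                "corrected_bits": est.corrected_info,
                                "included": est.included,
                            }
                        )
                try:
                    red = info.redundancy(
                        rec, hemi, first_n=cfg.first_n, n_shuffles=cfg.n_shuffles, seed=rng
                    )
                    red_rows.append(
                        {
                            "animal_id": animal,
                            "day": rec.day,
                            "hemisphere": hemi,
                            "ensemble_bits": red.ensemble_info,
                            "sum_single_bits": red.sum_single_info,
                            "p_bits": red.p_value_bits,
                            "redundancy_bits": red.redundancy,
                            "n_included": red.n_neurons_included,
                        }
                    )
                except decoder.DegenerateInputError:
                    log.warning("no informative neurons: %s day %d %s", animal, rec.day, hemi)
                nv_rows.append(
                    {
                        "animal_id": animal,
                        "day": rec.day,
                        "hemisphere": hemi,
                        "nv_z": response.session_normalized_variance(
                            rec, hemi, baseline, first_n=cfg.first_n, eps=cfg.nv_eps
                        ),
                    }
                )
                for nid in roster:
                    prof = response.most_responsive_profile(
                        rec, nid, threshold_sd=cfg.threshold_sd, alpha=cfg.alpha
                    )
                    resp_rows.append(
                        {
                            "animal_id": animal,
                            "day": rec.day,
                            "unit": nid,
                            "hemisphere": hemi,
                            "responsive": prof.responsive,
                            "tilt_type": prof.tilt_type,
                            "peak_response": prof.peak_response,
                            "peak_latency_ms": prof.peak_latency_ms,
                        }
                    )
    tables = {
        "information": pd.DataFrame(info_rows),
        "redundancy": pd.DataFrame(red_rows),
        "normalized_variance": pd.DataFrame(nv_rows),
        "response_profiles": pd.DataFrame(resp_rows),
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    return tables


@_stage("analyze")
def stage_analyze(
    cfg: PipelineConfig, sessions: dict, ledger: dict, perf: pd.DataFrame, out: Path
) -> pd.DataFrame:
    rows = []
    dist_frames = []
    for animal, recs in sessions.items():
        sub = perf[perf["animal_id"] == animal].sort_values("day")
        days = sub["day"].tolist()
        series = learning.normalize_performance(
            days, sub["offline_accuracy"].tolist(), reference_day=days[0], animal_id=animal
        )
        true_group = ledger["animals"][animal]["group"]
        label = (
            "control"
            if true_group == "control"
            else learning.classify_learner(series)
        )
        expert = learning.expert_day(series)
        rows.append(
            {
                "animal_id": animal,
                "true_group": true_group,
                "assigned_group": label,
                "expert_day": expert,
                "mean_late_normalized": float(np.mean(series.normalized[-learning.PHASE_DAYS:])),
            }
        )
        naive_rec = recs[0]
        expert_rec = next(r for r in recs if r.day == expert)
        dist_frames.append(
            learning.naive_expert_distances(
                naive_rec,
                learning.filter_first_n(expert_rec, cfg.first_n),
                neuron_ids=naive_rec.roster("direct"),
                first_n=cfg.first_n,
            )
        )
    groups_df = pd.DataFrame(rows)
    groups_df.to_csv(out / "group_labels.csv", index=False)
    pd.concat(dist_frames, ignore_index=True).to_csv(out / "distance_points.csv", index=False)
    return groups_df


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages under ``cfg.out_dir``; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    sessions, ledger = stage_simulate(cfg, out)
    perf = stage_decode(cfg, sessions, out)
    tables = stage_metrics(cfg, sessions, out)
    groups = stage_analyze(cfg, sessions, ledger, perf, out)
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "elapsed_s": round(time.perf_counter() - t0, 2),
        "row_counts": {
            "performance": len(perf),
            **{k: len(v) for k, v in tables.items()},
            "group_labels": len(groups),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def check_manifest(run_dir: str | Path) -> bool:
    """True when the stored config hash matches the stored config."""
    manifest = json.loads((Path(run_dir) / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["window"] = tuple(float(w) for w in cfg_dict["window"])
    recomputed = PipelineConfig(**cfg_dict).config_hash()
    ok = recomputed == manifest["config_hash"]
    if not ok:
        log.warning("manifest config hash mismatch: %s != %s", recomputed, manifest["config_hash"])
    return ok
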