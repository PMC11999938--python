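"""End-to-end orchestration: simulate -> preprocess -> train -> transfer -> assess."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np

from . import assess, sim, transfer
from .errors import EmgForceError, ValidationError
from .io import RunConfig, save_estimator, save_samples
from .model import build_estimator, evaluate, split_train_val_test, train
from .preprocess import preprocess_cohort

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full study on synthetic cohorts and write all artifacts.

    Stages: simulate a healthy source cohort and train the source network;
    simulate healthy-child and CP target cohorts; calibrate per-gesture
    target networks with a transfer strategy; produce the deviation-score
    assessment report.  Every artifact is stamped with the config hash and
    the per-stage seeds.

    Returns a dict of the principal metrics; raises with a stage-named
    diagnostic on failure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pre_cfg = config.preprocess_config()
    est_cfg = config.estimator_config()
    if pre_cfg.window != est_cfg.input_length:
        raise ValidationError(
            f"preprocess window {pre_cfg.window} != estimator input_length "
            f"{est_cfg.input_length}")
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    report: dict = {"stamp": stamp, "timings": {}}
    simcfg = dict(config.sim)
    tl = dict(config.transfer)

    def stage(name):
        return _Stage(name, report["timings"])

    try:
        with stage("simulate"):
            source_cohort = sim.make_cohort(
                n_subjects=simcfg.get("source_subjects", 4), group="HA",
                gestures=("SRC",), reps=simcfg.get("source_reps", 4),
                seed=config.stage_seed("sim_source"),
                fs=simcfg.get("fs", 2000.0),
                ramp_s=simcfg.get("ramp_s", 3.0),
                plateau_s=simcfg.get("plateau_s", 3.0),
            )
            hc_cohort = sim.make_cohort(
                n_subjects=simcfg.get("hc_subjects", 4), group="HC",
                gestures=tuple(simcfg.get("gestures", ("G1", "G2"))),
                reps=simcfg.get("reps", 4),
                seed=config.stage_seed("sim_hc"),
                fs=simcfg.get("fs", 2000.0),
                ramp_s=simcfg.get("ramp_s", 3.0),
                plateau_s=simcfg.get("plateau_s", 3.0),
            )
            cp_cohort = sim.make_cohort(
                n_subjects=simcfg.get("cp_subjects", 4), group="CP",
                gestures=tuple(simcfg.get("gestures", ("G1", "G2"))),
                reps=simcfg.get("reps", 4),
                seed=config.stage_seed("sim_cp"),
                fs=simcfg.get("fs", 2000.0),
                ramp_s=simcfg.get("ramp_s", 3.0),
                plateau_s=simcfg.get("plateau_s", 3.0),
            )

        with stage("preprocess"):
            source_samples = preprocess_cohort(source_cohort, pre_cfg)
            hc_samples = preprocess_cohort(hc_cohort, pre_cfg)
            save_samples(source_samples, out_dir / "source_samples.npz")
            save_samples(hc_samples, out_dir / "hc_samples.npz")

        with stage("train_source"):
            tr, va, te = split_train_val_test(
                source_samples, seed=config.stage_seed("split"))
            source = build_estimator(est_cfg, seed=config.stage_seed("init"))
            train(source, tr, va, seed=config.stage_seed("train"),
                  max_epochs=tl.get("source_epochs", est_cfg.max_epochs))
            report["source_test"] = evaluate(source, te)
            save_estimator(source, out_dir / "source_model.npz")

        with stage("transfer"):
            strategy = tl.get("strategy", "TL1")
            gestures = sorted(set(hc_samples.gestures))
            models = {}
            for gesture in gestures:
                gset = hc_samples.subset(hc_samples.gestures == gesture)
                models[gesture] = transfer.calibrate(
                    source, strategy, gset,
                    seed=config.stage_seed(f"calibrate_{gesture}"),
                    epochs=tl.get("calib_epochs", 50))
                save_estimator(models[gesture], out_dir / f"target_{gesture}.npz")

        with stage("assess"):
            assessment = assess.cohort_report(
                models, hc_cohort + cp_cohort, grouping="HCvsCP", cfg=pre_cfg)
            assessment["scores"].to_csv(out_dir / "deviation_scores.csv", index=False)
            assessment["summaries"].to_csv(out_dir / "group_summaries.csv", index=False)
            report["assessment"] = {
                "summaries": assessment["summaries"].to_dict(orient="records"),
                "tests": [
                    {**t, "labels": list(t["labels"])} for t in assessment["tests"]
                ],
            }
    except EmgForceError as exc:
        raise EmgForceError(f"pipeline stage failed: {exc}") from exc
    return report


class _Stage:
    def __init__(self, name: str, timings: dict):
        self.name, self.timings = name, timings

    def __enter__(self):
        logger.info("stage %s started", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.timings[self.name] = round(time.perf_counter() - self.t0, 3)
        logger.info("stage %s finished in %.1fs%s", self.name,
                    self.timings[self.name], " (FAILED)" if exc else "")
        return False
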