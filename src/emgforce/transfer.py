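"""Layer-freezing transfer calibration and cross-validation harnesses.

Three transfer strategies calibrate a trained source network on target data:

* ``TL1`` — transfer all parameters, all layers trainable;
* ``TL2`` — transfer all parameters, freeze the first LSTM block;
* ``TL3`` — transfer all parameters, freeze the first two LSTM blocks;

plus two baselines: ``non_TL`` (same architecture, fresh parameters, no
transfer) and ``source_only`` (apply the source network unmodified).

Frozen blocks are excluded from gradient updates and their batch-norm
layers are pinned to running statistics, so every array of a frozen block
is bit-identical before and after calibration.

Harnesses: leave-one-subject-out evaluation (one fold per subject, 9:1
window-level train/val split inside each fold) and the training:test-ratio
experiment (subject-level resampling at ratios such as 15:1 ... 1:15, no
validation set, repeated folds per cell).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UnknownModeError, ValidationError
from .model import (
    ForceEstimator,
    build_estimator,
    evaluate,
    train,
)
from .preprocess import SampleSet

STRATEGY_FROZEN_DEPTH = {"TL1": 0, "TL2": 1, "TL3": 2}
STRATEGIES = ("TL1", "TL2", "TL3", "non_TL", "source_only")


@dataclass(frozen=True)
class TransferStrategy:
    name: str

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise UnknownModeError(f"unknown transfer strategy {self.name!r}")

    @property
    def frozen_depth(self) -> int:
        return STRATEGY_FROZEN_DEPTH.get(self.name, 0)

    @property
    def transfers_parameters(self) -> bool:
        return self.name in STRATEGY_FROZEN_DEPTH


def _as_strategy(strategy) -> TransferStrategy:
    return strategy if isinstance(strategy, TransferStrategy) else TransferStrategy(str(strategy))


def calibrate(
    source: ForceEstimator,
    strategy,
    data: SampleSet,
    seed: int = 0,
    epochs: int = 50,
    val: SampleSet | None = None,
    lr: float | None = None,
) -> ForceEstimator:
    """Calibrate the source network on target data under one strategy.

    ``non_TL`` re-initializes the architecture from scratch; the TL
    strategies start from the source parameters with the first
    ``frozen_depth`` blocks frozen.  Calibration runs a fixed epoch budget
    (default 50) with early stopping only if a validation set is supplied.
    ``lr`` overrides the learning rate during calibration (fine-tuning at a
    reduced rate tempers overfitting to very small calibration sets).
    """
    strategy = _as_strategy(strategy)
    if strategy.name == "source_only":
        raise ValidationError("source_only performs no calibration")
    if len(data) == 0:
        raise ValidationError("empty calibration set")
    if strategy.frozen_depth >= len(source.config.layer_units):
        raise ValidationError(
            f"{strategy.name} freezes {strategy.frozen_depth} layers but the "
            f"network has only {len(source.config.layer_units)}"
        )
    if strategy.transfers_parameters:
        target = source.copy()
        target.history = {"train_loss": [], "val_loss": []}
    else:
        target = build_estimator(copy.deepcopy(source.config), seed=seed)
    if lr is not None:
        target.config.learning_rate = lr
    target.net.frozen_depth = strategy.frozen_depth
    if epochs > 0:
        train(target, data, val, max_epochs=epochs, seed=seed,
              early_stopping=val is not None and len(val or []) > 0)
    else:
        target.is_trained = True
    return target


@dataclass
class ExperimentReport:
    """Per-fold metrics plus the aggregation the protocol prescribes."""

    rows: list[dict] = field(default_factory=list)
    seed: int = 0
    protocol: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def aggregate(self, by=("strategy",)) -> pd.DataFrame:
        df = self.to_dataframe()
        by = [b for b in by if b in df.columns]
        return df.groupby(list(by), as_index=False).agg(
            rmse_mean=("rmse", "mean"), rmse_sd=("rmse", "std"),
            r2_mean=("r2", "mean"), n_folds=("rmse", "size"),
        )

    def to_dict(self) -> dict:
        return {"protocol": self.protocol, "seed": self.seed, "rows": self.rows}


def _window_split(samples: SampleSet, frac_train: float, rng) -> tuple[SampleSet, SampleSet]:
    n = len(samples)
    order = rng.permutation(n)
    n_train = max(int(round(frac_train * n)), 1)
    return samples.subset(order[:n_train]), samples.subset(order[n_train:])


def loso_evaluate(
    samples_by_subject: dict[str, SampleSet],
    source: ForceEstimator,
    strategy,
    seed: int = 0,
    calib_epochs: int = 50,
) -> ExperimentReport:
    """Leave-one-subject-out evaluation of a calibration strategy.

    Each fold holds one subject out entirely; the remaining subjects'
    windows are split 9:1 into calibration-train and validation sets.
    """
    strategy = _as_strategy(strategy)
    subjects = sorted(samples_by_subject)
    if len(subjects) < 2:
        raise ValidationError("LOSO needs at least 2 subjects")
    report = ExperimentReport(seed=seed, protocol="loso")
    rng = np.random.default_rng(seed)
    for fold, test_subject in enumerate(subjects):
        test_set = samples_by_subject[test_subject]
        if len(test_set) == 0:
            report.rows.append({"fold": fold, "test_subject": test_subject,
                                "skipped": True})
            continue
        pool = SampleSet.concatenate(
            [samples_by_subject[s] for s in subjects if s != test_subject])
        fold_seed = int(rng.integers(2 ** 31))
        if strategy.name == "source_only":
            est = source
        else:
            tr, va = _window_split(pool, 0.9, np.random.default_rng(fold_seed))
            est = calibrate(source, strategy, tr, seed=fold_seed,
                            epochs=calib_epochs, val=va)
        metrics = evaluate(est, test_set)
        report.rows.append({
            "fold": fold, "test_subject": test_subject,
            "strategy": strategy.name, "rmse": metrics["rmse"],
            "r2": metrics["r2"], "n_test": metrics["n"], "seed": fold_seed,
        })
    return report


def ratio_experiment(
    samples_by_subject: dict[str, SampleSet],
    source: ForceEstimator,
    ratios: list[tuple[int, int]],
    strategies=("TL1", "non_TL"),
    seed: int = 0,
    n_resamples: int = 16,
    calib_epochs: int = 50,
) -> ExperimentReport:
    """Training:test-ratio experiment with subject-level resampling.

    For every (train_n, test_n) ratio and every strategy, ``n_resamples``
    random subject-level splits are drawn (without replacement, no
    validation set) and the test RMSE is averaged per cell.
    """
    subjects = sorted(samples_by_subject)
    n_subj = len(subjects)
    for train_n, test_n in ratios:
        if train_n + test_n > n_subj:
            raise ValidationError(
                f"ratio {train_n}:{test_n} exceeds the {n_subj}-subject cohort")
        if train_n < 1 or test_n < 1:
            raise ValidationError("both sides of a ratio must be >= 1")
    strategies = [_as_strategy(s) for s in strategies]
    report = ExperimentReport(seed=seed, protocol="ratio")
    rng = np.random.default_rng(seed)
    for train_n, test_n in ratios:
        for resample in range(n_resamples):
            perm = rng.permutation(n_subj)
            train_subjects = [subjects[i] for i in perm[:train_n]]
            test_subjects = [subjects[i] for i in perm[train_n:train_n + test_n]]
            train_pool = SampleSet.concatenate(
                [samples_by_subject[s] for s in train_subjects])
            test_pool = SampleSet.concatenate(
                [samples_by_subject[s] for s in test_subjects])
            resample_seed = int(rng.integers(2 ** 31))
            for strategy in strategies:
                if strategy.name == "source_only":
                    est = source
                else:
                    est = calibrate(source, strategy, train_pool,
                                    seed=resample_seed, epochs=calib_epochs)
                metrics = evaluate(est, test_pool)
                report.rows.append({
                    "ratio": f"{train_n}:{test_n}", "train_n": train_n,
                    "test_n": test_n, "resample": resample,
                    "strategy": strategy.name, "rmse": metrics["rmse"],
                    "r2": metrics["r2"], "seed": resample_seed,
                    "train_subjects": train_subjects,
                    "test_subjects": test_subjects,
                })
    return report
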