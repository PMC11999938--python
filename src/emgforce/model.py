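"""Stacked-LSTM force estimator and its evaluation metrics.

The regressor maps a 500-sample normalized-envelope window to one scalar
normalized-force value.  The architecture follows the selected source
network: up to three LSTM layers (default 256-128-64 units), each followed
by batch normalization and dropout (default 0.4), terminated by a dense
single-output layer; loss is the RMSE, optimized by Adam at an initial
learning rate of 0.001 with batch size 100 and early stopping on the
validation loss.

Metrics
-------
``rmse``       root-mean-square error x 100 (percent of normalized force).
``r_squared``  squared Pearson correlation between estimated and measured
               force, in [0, 1].
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import TrainingError, ValidationError
from .nn import Adam, StackedLSTMRegressor, rmse_loss_and_grad
from .preprocess import SampleSet


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(y_true, y_pred) -> float:
    """Root-mean-square error in percent of the normalized force scale."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValidationError("rmse: length mismatch")
    if y_true.size == 0:
        raise ValidationError("rmse: empty input")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)) * 100.0)


def r_squared(x, y) -> float:
    """Squared Pearson correlation between estimated (x) and measured (y) force."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("r_squared: need two equal-length vectors, n >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.sum(xc * xc))
    syy = float(np.sum(yc * yc))
    if sxx == 0.0 or syy == 0.0:
        raise ValidationError("r_squared undefined for zero-variance input")
    sxy = float(np.sum(xc * yc))
    return sxy * sxy / (sxx * syy)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

@dataclass
class EstimatorConfig:
    layer_units: tuple[int, ...] = (256, 128, 64)
    dropout: float = 0.4
    batch_size: int = 100
    learning_rate: float = 1e-3
    max_epochs: int = 300
    patience: int = 20               # early-stopping patience on validation loss
    input_length: int = 500

    def __post_init__(self):
        self.layer_units = tuple(int(u) for u in self.layer_units)
        if not 1 <= len(self.layer_units) <= 3:
            raise ValidationError("1 to 3 recurrent layers are supported")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1 or self.input_length < 1:
            raise ValidationError("batch_size, max_epochs, input_length must be >= 1")


@dataclass
class ForceEstimator:
    """A (possibly trained) stacked-LSTM force regressor."""

    config: EstimatorConfig
    net: StackedLSTMRegressor
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})
    is_trained: bool = False

    @property
    def n_layers(self) -> int:
        return len(self.config.layer_units)

    def copy(self) -> "ForceEstimator":
        return ForceEstimator(
            config=copy.deepcopy(self.config),
            net=copy.deepcopy(self.net),
            history=copy.deepcopy(self.history),
            is_trained=self.is_trained,
        )


def build_estimator(cfg: EstimatorConfig, seed: int = 0,
                    dtype=np.float32) -> ForceEstimator:
    """Construct an untrained estimator with seeded initial parameters."""
    net = StackedLSTMRegressor(cfg.layer_units, cfg.dropout, seed=seed, dtype=dtype)
    return ForceEstimator(config=cfg, net=net)


def train(
    est: ForceEstimator,
    train_set: SampleSet,
    val_set: SampleSet | None = None,
    max_epochs: int | None = None,
    seed: int = 0,
    early_stopping: bool | None = None,
) -> ForceEstimator:
    """Train in place, minimizing RMSE; returns ``est`` for chaining.

    With a non-empty validation set the parameters with the best validation
    loss are restored at the end (early stopping, default patience from the
    config); without one, training runs the full epoch budget.
    """
    if len(train_set) == 0:
        raise ValidationError("empty training set")
    if train_set.window_length != est.config.input_length:
        raise ValidationError(
            f"window length {train_set.window_length} != configured "
            f"input_length {est.config.input_length}"
        )
    max_epochs = max_epochs or est.config.max_epochs
    use_val = val_set is not None and len(val_set) > 0
    if early_stopping is None:
        early_stopping = use_val
    rng = np.random.default_rng(seed)
    opt = Adam(lr=est.config.learning_rate)
    X, y = train_set.windows, train_set.targets
    n = len(X)
    bs = min(est.config.batch_size, n)

    best_val = np.inf
    best_weights = None
    since_best = 0
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            pred = est.net.forward(X[idx], train=True, rng=rng)
            loss, dpred = rmse_loss_and_grad(pred, y[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            epoch_losses.append(loss)
            est.net.backward(dpred)
            opt.step(est.net)
        est.history["train_loss"].append(float(np.mean(epoch_losses)))

        if use_val:
            val_pred = _predict_windows(est, val_set.windows)
            val_loss = float(np.sqrt(np.mean((val_pred - val_set.targets) ** 2)))
            est.history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_weights = est.net.get_weights()
                since_best = 0
            else:
                since_best += 1
                if early_stopping and since_best >= est.config.patience:
                    break
    if use_val and best_weights is not None:
        est.net.set_weights(best_weights)
    est.is_trained = True
    return est


def _predict_windows(est: ForceEstimator, windows: np.ndarray,
                     batch: int = 256) -> np.ndarray:
    preds = [est.net.forward(windows[s:s + batch], train=False)
             for s in range(0, len(windows), batch)]
    return np.concatenate(preds) if preds else np.empty(0)


def predict(est: ForceEstimator, samples: SampleSet) -> np.ndarray:
    """One deterministic scalar prediction per window (dropout off)."""
    if len(samples) == 0:
        return np.empty(0)
    if samples.window_length != est.config.input_length:
        raise ValidationError(
            f"window length {samples.window_length} != configured "
            f"input_length {est.config.input_length}"
        )
    return _predict_windows(est, samples.windows)


def evaluate(est: ForceEstimator, samples: SampleSet) -> dict:
    """RMSE (%) and R^2 of the estimator on a sample set."""
    y_pred = predict(est, samples)
    out = {"rmse": rmse(samples.targets, y_pred), "n": len(samples)}
    try:
        out["r2"] = r_squared(y_pred, samples.targets)
    except ValidationError:
        out["r2"] = float("nan")
    return out


def split_train_val_test(
    samples: SampleSet, seed: int = 0, fractions=(0.8, 0.1, 0.1),
    by_subject: bool = False,
) -> tuple[SampleSet, SampleSet, SampleSet]:
    """Random 8:1:1 split at the window level (or subject level on request).

    The window-level split mirrors the source-network protocol; the
    subject-level alternative avoids leaking subject identity across splits
    and is offered for honest subject-independent benchmarking.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    if by_subject:
        subjects = np.unique(samples.subjects)
        subjects = subjects[rng.permutation(len(subjects))]
        n = len(subjects)
        n_train = max(int(round(fractions[0] * n)), 1)
        n_val = int(round(fractions[1] * n))
        groups = (subjects[:n_train], subjects[n_train:n_train + n_val],
                  subjects[n_train + n_val:])
        return tuple(samples.subset(np.isin(samples.subjects, g)) for g in groups)
    n = len(samples)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return (samples.subset(order[:n_train]),
            samples.subset(order[n_train:n_train + n_val]),
            samples.subset(order[n_train + n_val:]))
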