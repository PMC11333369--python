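"""Feedforward network mapping body/movement features to profile parameters.

Architecture: 13 input features -> hidden layers of 32, 24 and 12 ReLU units
-> 4 outputs (peak value, peak time, start time, end time). Training
minimizes the L1 loss (sum of absolute differences over samples and the four
profile features) with Adam, dropout 0.1, L2 weight regularization
(lambda = 1e-3), batch size 64, up to 200 epochs with early stopping on a
20% validation split, and a learning-rate schedule that halves the rate when
the training loss plateaus. Inputs and targets are z-standardized with
training-set statistics so the four heterogeneous targets contribute
comparably to the loss.

Transfer learning adapts a trained model to a new subject using only that
subject's extreme-speed (0.5 and 1.8 m/s) cycles: all layers are fine-tuned
at one tenth of the initial learning rate while the standardization
statistics stay frozen.

The network, backpropagation and the Adam optimizer are implemented directly
on numpy arrays; everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError
from .gait_synth import GaitCycle, SubjectProfile

#: canonical feature order of the 13-dimensional input
FEATURE_NAMES = (
    "sex", "mass", "height", "bmi", "thigh_length", "calf_length",
    "foot_length", "torso_length", "pelvis_width", "speed", "stride_length",
    "cadence", "max_heel_clearance")

#: canonical target order of the 4-dimensional output
TARGET_NAMES = ("peak_value", "peak_time", "start_time", "end_time")

EXTREME_SPEEDS = (0.5, 1.8)  # m/s, transfer-learning speeds


def feature_vector(subject: SubjectProfile, cycle: GaitCycle) -> np.ndarray:
    """The 13 input features in canonical order (sex encoded 0=female, 1=male)."""
    return np.array([
        1.0 if subject.sex == "male" else 0.0,
        subject.mass, subject.height, subject.bmi,
        subject.thigh_length, subject.calf_length, subject.foot_length,
        subject.torso_length, subject.pelvis_width,
        cycle.speed, cycle.stride_length, cycle.cadence,
        cycle.max_heel_clearance])


def profile_targets(profile) -> np.ndarray:
    """The 4 prediction targets of one assistance profile, canonical order."""
    return np.array([profile.peak_value, profile.peak_time,
                     profile.start_time, profile.end_time])


@dataclass(frozen=True)
class TrainingConfig:
    hidden_sizes: tuple = (32, 24, 12)
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 64
    dropout: float = 0.1
    l2: float = 1e-3  # lambda of the L2 weight penalty
    patience: int = 20  # early-stopping patience, epochs
    lr_plateau: int = 10  # epochs of flat training loss before halving LR
    lr_factor: float = 0.5
    validation_fraction: float = 0.2
    transfer_epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ConfigurationError("validation_fraction must lie in (0, 1)")
        for name in ("epochs", "learning_rate", "batch_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.l2 < 0 or self.patience < 0 or self.transfer_epochs < 0:
            raise ConfigurationError("l2/patience/transfer_epochs must be >= 0")


def l1_loss(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Sum of absolute differences over all samples and all four features."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise DomainError(
            f"shape mismatch: {actual.shape} vs {predicted.shape}")
    return float(np.sum(np.abs(actual - predicted)))


@dataclass
class FNNModel:
    """Trained network: weights, standardization statistics and config."""

    weights: list  # [W1, b1, W2, b2, ...]
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    config: TrainingConfig
    history: dict = field(default_factory=dict)

    def forward(self, x_std: np.ndarray) -> np.ndarray:
        """Forward pass on standardized inputs (no dropout)."""
        h = x_std
        n_layers = len(self.weights) // 2
        for layer in range(n_layers):
            w, b = self.weights[2 * layer], self.weights[2 * layer + 1]
            h = h @ w + b
            if layer < n_layers - 1:
                h = np.maximum(h, 0.0)
        return h

    def copy(self) -> "FNNModel":
        return FNNModel(
            weights=[w.copy() for w in self.weights],
            x_mean=self.x_mean.copy(), x_std=self.x_std.copy(),
            y_mean=self.y_mean.copy(), y_std=self.y_std.copy(),
            config=self.config, history=copy.deepcopy(self.history))


def _init_weights(sizes: tuple, rng: np.random.Generator) -> list:
    """Uniform fan-in initialization: W ~ U(-1/sqrt(n_in), 1/sqrt(n_in))."""
    weights = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(n_in)
        weights.append(rng.uniform(-bound, bound, size=(n_in, n_out)))
        weights.append(rng.uniform(-bound, bound, size=n_out))
    return weights


def _forward_train(weights: list, x: np.ndarray, dropout: float,
                   rng: np.random.Generator):
    """Forward pass with inverted dropout; returns output and a tape."""
    n_layers = len(weights) // 2
    h = x
    tape = []
    for layer in range(n_layers):
        w, b = weights[2 * layer], weights[2 * layer + 1]
        z = h @ w + b
        if layer < n_layers - 1:
            act = np.maximum(z, 0.0)
            if dropout > 0.0:
                mask = (rng.uniform(size=act.shape) >= dropout) / (1.0 - dropout)
                out = act * mask
            else:
                mask = None
                out = act
            tape.append((h, z, mask))
            h = out
        else:
            tape.append((h, z, None))
            h = z
    return h, tape


def _backward(weights: list, tape: list, grad_out: np.ndarray,
              l2: float) -> list:
    """Gradients of (loss + l2 * sum W^2) w.r.t. every weight array."""
    n_layers = len(weights) // 2
    grads = [None] * len(weights)
    delta = grad_out
    for layer in range(n_layers - 1, -1, -1):
        h_in, z, mask = tape[layer]
        if layer < n_layers - 1:
            if mask is not None:
                delta = delta * mask
            delta = delta * (z > 0.0)
        w = weights[2 * layer]
        grads[2 * layer] = h_in.T @ delta + 2.0 * l2 * w
        grads[2 * layer + 1] = delta.sum(axis=0)
        if layer > 0:
            delta = delta @ w.T
    return grads


class _Adam:
    def __init__(self, weights: list, lr: float, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(w) for w in weights]
        self.v = [np.zeros_like(w) for w in weights]
        self.t = 0

    def step(self, weights: list, grads: list):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, (w, g) in enumerate(zip(weights, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g**2
            w -= self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c)
                                                + self.eps)


def _standardize_stats(arr: np.ndarray):
    mean = arr.mean(axis=0)
    std = arr.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return mean, std


def _run_epochs(model: FNNModel, x_std: np.ndarray, y_std: np.ndarray,
                x_val: np.ndarray | None, y_val: np.ndarray | None,
                epochs: int, lr: float, rng: np.random.Generator,
                early_stopping: bool) -> FNNModel:
    """Shared training loop; mutates and returns ``model`` (best weights)."""
    cfg = model.config
    opt = _Adam(model.weights, lr)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_weights = [w.copy() for w in model.weights]
    since_best = 0
    since_plateau = 0
    best_train = np.inf
    n = x_std.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_std[idx], y_std[idx]
            pred, tape = _forward_train(model.weights, xb, cfg.dropout, rng)
            resid = pred - yb
            epoch_loss += float(np.sum(np.abs(resid)))
            grad = np.sign(resid) / len(idx)  # mean-per-batch L1
            grads = _backward(model.weights, tape, grad, cfg.l2)
            opt.step(model.weights, grads)
        train_loss = epoch_loss / n
        history["train_loss"].append(train_loss)
        history["lr"].append(opt.lr)
        if x_val is not None and len(x_val):
            val_pred = model.forward(x_val)
            val_loss = float(np.mean(np.abs(val_pred - y_val)))
        else:
            val_loss = train_loss
        history["val_loss"].append(val_loss)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = [w.copy() for w in model.weights]
            since_best = 0
        else:
            since_best += 1
            if early_stopping and since_best > cfg.patience:
                break
        if train_loss < best_train - 1e-12:
            best_train = train_loss
            since_plateau = 0
        else:
            since_plateau += 1
            if since_plateau >= cfg.lr_plateau:
                opt.lr *= cfg.lr_factor
                since_plateau = 0
    if early_stopping:
        model.weights = best_weights
    for key, values in history.items():
        model.history.setdefault(key, []).extend(values)
    return model


def train(features: np.ndarray, targets: np.ndarray,
          config: TrainingConfig | None = None) -> FNNModel:
    """Train the network on (n, 13) features and (n, 4) profile targets.

    Deterministic under ``config.seed``: the shuffle, the 80/20 split, weight
    initialization and dropout masks all derive from one generator. Returns
    the model with the best-validation-loss weights and the loss history.
    """
    config = config or TrainingConfig()
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if features.ndim != 2 or features.shape[1] != len(FEATURE_NAMES):
        raise DomainError(f"features must be (n, {len(FEATURE_NAMES)})")
    if targets.shape != (features.shape[0], len(TARGET_NAMES)):
        raise DomainError(f"targets must be (n, {len(TARGET_NAMES)})")
    n = features.shape[0]
    if n < 2 * config.batch_size:
        raise DomainError("need at least two batches of training data")

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    x_mean, x_std_ = _standardize_stats(features[train_idx])
    y_mean, y_std_ = _standardize_stats(targets[train_idx])
    xs = (features - x_mean) / x_std_
    ys = (targets - y_mean) / y_std_

    sizes = (len(FEATURE_NAMES),) + tuple(config.hidden_sizes) \
        + (len(TARGET_NAMES),)
    model = FNNModel(
        weights=_init_weights(sizes, rng),
        x_mean=x_mean, x_std=x_std_, y_mean=y_mean, y_std=y_std_,
        config=config)
    return _run_epochs(model, xs[train_idx], ys[train_idx], xs[val_idx],
                       ys[val_idx], config.epochs, config.learning_rate, rng,
                       early_stopping=True)


def transfer(model: FNNModel, features: np.ndarray, targets: np.ndarray,
             speeds: np.ndarray, epochs: int | None = None) -> FNNModel:
    """Fine-tune on a new subject's extreme-speed cycles; returns a new model.

    All layers are updated at 0.1x the initial learning rate. ``speeds`` must
    contain only the extreme speeds (0.5 / 1.8 m/s) — the guard prevents
    leakage of evaluation-speed data into fine-tuning. Zero epochs returns an
    identical copy.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    speeds = np.asarray(speeds, dtype=float)
    if features.shape[0] == 0:
        raise DomainError("fine-tuning set must be non-empty")
    if speeds.shape[0] != features.shape[0]:
        raise DomainError("speeds must align with features")
    bad = ~np.any(np.isclose(speeds[:, None], EXTREME_SPEEDS, atol=1e-6),
                  axis=1)
    if np.any(bad):
        raise DomainError(
            f"fine-tuning data contains non-extreme speeds: "
            f"{sorted(set(np.round(speeds[bad], 3)))}")
    epochs = model.config.transfer_epochs if epochs is None else epochs
    tuned = model.copy()
    if epochs == 0:
        return tuned
    rng = np.random.default_rng(model.config.seed + 1)
    xs = (features - model.x_mean) / model.x_std
    ys = (targets - model.y_mean) / model.y_std
    return _run_epochs(tuned, xs, ys, None, None, epochs,
                       0.1 * model.config.learning_rate, rng,
                       early_stopping=False)


def predict(model: FNNModel, features: np.ndarray):
    """Predict the four profile parameters for one or more feature vectors.

    Times are clipped to [0, 100]; if the predicted ordering violates
    t1 < t2 < t3 the three times are re-ordered and the sample is flagged.
    Returns ``(params, reordered)`` with params of shape (n, 4) in canonical
    target order and ``reordered`` a boolean array.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != len(FEATURE_NAMES):
        raise DomainError(f"expected {len(FEATURE_NAMES)} features")
    xs = (x - model.x_mean) / model.x_std
    raw = model.forward(xs) * model.y_std + model.y_mean
    params = raw.copy()
    params[:, 0] = np.maximum(params[:, 0], 0.0)  # peak value
    params[:, 1:] = np.clip(params[:, 1:], 0.0, 100.0)  # times
    # canonical order is (peak_value, t2, t1, t3); enforce t1 < t2 < t3
    times = params[:, [2, 1, 3]]
    sorted_times = np.sort(times, axis=1)
    reordered = np.any(times != sorted_times, axis=1)
    params[:, [2, 1, 3]] = sorted_times
    return params, reordered


def save_model(model: FNNModel, path):
    """Write the model as JSON: weights, standardization stats, config."""
    import dataclasses
    import json
    from pathlib import Path

    blob = {
        "feature_names": list(FEATURE_NAMES),
        "target_names": list(TARGET_NAMES),
        "weights": [w.tolist() for w in model.weights],
        "x_mean": model.x_mean.tolist(), "x_std": model.x_std.tolist(),
        "y_mean": model.y_mean.tolist(), "y_std": model.y_std.tolist(),
        "config": dataclasses.asdict(model.config),
        "history": model.history,
    }
    Path(path).write_text(json.dumps(blob))


def load_model(path) -> FNNModel:
    """Read a model written by :func:`save_model`."""
    import json
    from pathlib import Path

    blob = json.loads(Path(path).read_text())
    if tuple(blob["feature_names"]) != FEATURE_NAMES:
        raise DomainError("checkpoint feature order does not match")
    cfg = blob["config"]
    cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
    return FNNModel(
        weights=[np.asarray(w, dtype=float) for w in blob["weights"]],
        x_mean=np.asarray(blob["x_mean"]), x_std=np.asarray(blob["x_std"]),
        y_mean=np.asarray(blob["y_mean"]), y_std=np.asarray(blob["y_std"]),
        config=TrainingConfig(**cfg), history=blob.get("history", {}))


def predicted_profiles(model: FNNModel, features: np.ndarray,
                       min_gap: float = 1.0) -> list:
    """Predictions as AssistanceProfile objects (knots nudged apart if needed)."""
    from .profile_param import AssistanceProfile
    params, _ = predict(model, features)
    profiles = []
    for peak, t2, t1, t3 in params:
        t1 = float(np.clip(t1, 0.0, 100.0 - 2.0 * min_gap))
        t2 = float(np.clip(t2, t1 + min_gap, 100.0 - min_gap))
        t3 = float(np.clip(t3, t2 + min_gap, 100.0))
        profiles.append(AssistanceProfile(
            peak_value=float(max(peak, 0.0)), start_time=t1, peak_time=t2,
            end_time=t3))
    return profiles
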