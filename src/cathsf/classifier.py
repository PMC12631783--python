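"""The layer-block feed-forward superfamily classifier.

The network maps a pooled embedding vector to a probability distribution
over CATH superfamilies.  Its body is ``n_layer_blocks`` repetitions of a
fixed *layer block* — dense layer → LeakyReLU → batch normalization →
dropout — followed by a dense output layer with softmax.  The best
published configuration of this family uses 2 blocks, layer size 2048,
dropout 0.3 on concatenated AA+3Di embeddings; those are the config
defaults.

Training minimizes categorical cross-entropy with Adam, early-stops on
validation loss, and restores the best-validation weights.  The paper
behind this architecture reports only the architecture and its
hyperparameter grid, not the training protocol; the loop here (Adam,
batch 256, ≤ 200 epochs, patience 10) is a conventional choice and every
knob is visible on :class:`ClassifierConfig`.

Everything is plain numpy: forward, backward (including the batch-norm
gradient), and the optimizer.  At the desk scales this package targets a
full training run takes seconds on one CPU, and a framework-free
implementation keeps training bit-reproducible for a fixed seed.

Inference uses batch-norm running statistics and no dropout, so
predictions are deterministic.  ``predict_with_rejection`` implements the
confidence heuristic for open-set use: with over a thousand superfamilies
in the label space, a top-class probability below a threshold such as 0.9
is treated as "no reliable assignment" rather than forced into a class.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .embedding import INPUT_TYPES, PooledEmbedding
from .errors import ChannelMismatchError, ConfigurationError, IntegrityError

__all__ = [
    "ClassifierConfig", "TrainedClassifier", "Prediction",
    "build_classifier", "train_classifier", "predict_proba",
    "predict_with_rejection", "stack_embeddings",
    "save_classifier", "load_classifier",
]

_BN_EPS = 1e-5


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and training hyperparameters.

    The input dimension is inferred from the data at build time and is
    deliberately not a config field.
    """

    n_layer_blocks: int = 2
    layer_size: int = 2048
    dropout_rate: float = 0.3
    input_type: str = "AA+3Di"
    leaky_slope: float = 0.05
    seed: int = 0
    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 1e-4
    patience: int = 10
    standardize: bool = False
    class_weighting: bool = False

    def __post_init__(self):
        if self.n_layer_blocks < 1:
            raise ConfigurationError("n_layer_blocks must be >= 1")
        if self.layer_size < 1:
            raise ConfigurationError("layer_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.input_type not in INPUT_TYPES:
            raise ConfigurationError(f"unknown input_type {self.input_type!r}")
        if self.leaky_slope <= 0:
            raise ConfigurationError("leaky_slope must be > 0")
        if self.epochs < 1 or self.batch_size < 1 or self.patience < 0:
            raise ConfigurationError("invalid training hyperparameters")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")


@dataclass
class TrainedClassifier:
    """A (possibly untrained) classifier with its weights and provenance."""

    config: ClassifierConfig
    label_space: tuple[str, ...]
    input_dim: int
    params: dict[str, np.ndarray]
    training_log: list[dict] = field(default_factory=list)
    trained: bool = False
    # per-feature standardization fitted on train, when enabled
    feature_mean: Optional[np.ndarray] = None
    feature_std: Optional[np.ndarray] = None

    @property
    def n_classes(self) -> int:
        return len(self.label_space)

    def architecture(self) -> list[str]:
        """Human-readable layer descriptor list."""
        c = self.config
        block = [f"dense({c.layer_size})", f"leaky_relu({c.leaky_slope})",
                 "batch_norm", f"dropout({c.dropout_rate})"]
        return block * c.n_layer_blocks + [f"dense({self.n_classes})",
                                           "softmax"]


@dataclass(frozen=True)
class Prediction:
    """One confidence-thresholded prediction."""

    domain_id: str
    label: Optional[str]  # None when rejected
    confidence: float
    rejected: bool


def build_classifier(config: ClassifierConfig, input_dim: int,
                     n_classes: Optional[int] = None,
                     label_space: Optional[Sequence[str]] = None,
                     ) -> TrainedClassifier:
    """Initialize an untrained classifier with seeded He-style weights."""
    if label_space is not None:
        label_space = tuple(label_space)
        if n_classes is not None and n_classes != len(label_space):
            raise ConfigurationError("n_classes contradicts label_space")
        n_classes = len(label_space)
    if n_classes is None:
        raise ConfigurationError("need n_classes or label_space")
    if n_classes < 2:
        raise ConfigurationError("need at least 2 classes")
    if input_dim < 1:
        raise ConfigurationError("input_dim must be >= 1")
    if label_space is None:
        label_space = tuple(str(i) for i in range(n_classes))
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    fan_in = input_dim
    for b in range(config.n_layer_blocks):
        params[f"W{b}"] = rng.standard_normal(
            (fan_in, config.layer_size)) * np.sqrt(2.0 / fan_in)
        params[f"b{b}"] = np.zeros(config.layer_size)
        params[f"gamma{b}"] = np.ones(config.layer_size)
        params[f"beta{b}"] = np.zeros(config.layer_size)
        params[f"rmean{b}"] = np.zeros(config.layer_size)
        params[f"rvar{b}"] = np.ones(config.layer_size)
        fan_in = config.layer_size
    params["Wout"] = rng.standard_normal(
        (fan_in, n_classes)) * np.sqrt(2.0 / fan_in)
    params["bout"] = np.zeros(n_classes)
    return TrainedClassifier(config=config, label_space=label_space,
                             input_dim=input_dim, params=params)


def _leaky_relu(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: TrainedClassifier, x: np.ndarray, training: bool,
             rng: Optional[np.random.Generator] = None):
    """Forward pass; in training mode returns the cache for backprop and
    updates batch-norm running statistics in place."""
    c = model.config
    p = model.params
    cache = {"x": x}
    h = x
    for b in range(c.n_layer_blocks):
        z = h @ p[f"W{b}"] + p[f"b{b}"]
        a = _leaky_relu(z, c.leaky_slope)
        if training:
            mu = a.mean(axis=0)
            var = a.var(axis=0)
            p[f"rmean{b}"] = 0.9 * p[f"rmean{b}"] + 0.1 * mu
            p[f"rvar{b}"] = 0.9 * p[f"rvar{b}"] + 0.1 * var
        else:
            mu, var = p[f"rmean{b}"], p[f"rvar{b}"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        a_hat = (a - mu) * inv_std
        y = p[f"gamma{b}"] * a_hat + p[f"beta{b}"]
        if training and c.dropout_rate > 0:
            mask = (rng.random(y.shape) >= c.dropout_rate) / (
                1.0 - c.dropout_rate)
            y = y * mask
        else:
            mask = None
        cache[f"h{b}"] = h
        cache[f"z{b}"] = z
        cache[f"a{b}"] = a
        cache[f"ahat{b}"] = a_hat
        cache[f"invstd{b}"] = inv_std
        cache[f"mask{b}"] = mask
        h = y
    logits = h @ p["Wout"] + p["bout"]
    cache["hlast"] = h
    return _softmax(logits), cache


def _backward(model: TrainedClassifier, cache: dict, probs: np.ndarray,
              y_onehot: np.ndarray,
              sample_weight: Optional[np.ndarray]) -> dict[str, np.ndarray]:
    """Gradients of the mean (weighted) cross-entropy w.r.t. parameters."""
    c = model.config
    p = model.params
    n = probs.shape[0]
    if sample_weight is None:
        dlogits = (probs - y_onehot) / n
    else:
        w = sample_weight[:, None] / sample_weight.sum()
        dlogits = (probs - y_onehot) * w
    grads = {
        "Wout": cache["hlast"].T @ dlogits,
        "bout": dlogits.sum(axis=0),
    }
    dh = dlogits @ p["Wout"].T
    for b in reversed(range(c.n_layer_blocks)):
        if cache[f"mask{b}"] is not None:
            dh = dh * cache[f"mask{b}"]
        a_hat = cache[f"ahat{b}"]
        inv_std = cache[f"invstd{b}"]
        grads[f"gamma{b}"] = (dh * a_hat).sum(axis=0)
        grads[f"beta{b}"] = dh.sum(axis=0)
        # batch-norm backward (batch statistics)
        dahat = dh * p[f"gamma{b}"]
        m = dh.shape[0]
        da = (inv_std / m) * (
            m * dahat - dahat.sum(axis=0)
            - a_hat * (dahat * a_hat).sum(axis=0))
        dz = da * np.where(cache[f"z{b}"] > 0, 1.0, c.leaky_slope)
        grads[f"W{b}"] = cache[f"h{b}"].T @ dz
        grads[f"b{b}"] = dz.sum(axis=0)
        dh = dz @ p[f"W{b}"].T
    return grads


class _Adam:
    def __init__(self, keys: Sequence[str], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _xentropy(probs: np.ndarray, y: np.ndarray,
              sample_weight: Optional[np.ndarray] = None) -> float:
    logp = -np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))
    if sample_weight is None:
        return float(logp.mean())
    return float((logp * sample_weight).sum() / sample_weight.sum())


def _prepare_x(model: TrainedClassifier, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != model.input_dim:
        raise IntegrityError(
            f"input has shape {x.shape}, model expects (*, {model.input_dim})")
    if model.feature_mean is not None:
        x = (x - model.feature_mean) / model.feature_std
    return x


def train_classifier(model: TrainedClassifier,
                     x_train: np.ndarray, y_train: np.ndarray,
                     x_val: np.ndarray, y_val: np.ndarray,
                     ) -> TrainedClassifier:
    """Train in place by mini-batch Adam on cross-entropy.

    Early stopping watches the validation loss with the configured
    patience and restores the best-validation weights before returning.
    For a fixed config, seed and data the training log is reproducible.
    """
    c = model.config
    x_train = np.asarray(x_train, dtype=np.float64)
    x_val = np.asarray(x_val, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    if len(x_train) == 0:
        raise IntegrityError("empty training set")
    for nm, x, y in (("train", x_train, y_train), ("val", x_val, y_val)):
        if x.ndim != 2 or x.shape[1] != model.input_dim:
            raise IntegrityError(
                f"{nm} embeddings have shape {x.shape}, model expects "
                f"(*, {model.input_dim})")
        if len(x) != len(y):
            raise IntegrityError(f"{nm}: {len(x)} vectors, {len(y)} labels")
        if len(y) and (y.min() < 0 or y.max() >= model.n_classes):
            raise IntegrityError(f"{nm} class indices outside "
                                 f"[0, {model.n_classes})")
    if c.standardize:
        model.feature_mean = x_train.mean(axis=0)
        model.feature_std = x_train.std(axis=0) + 1e-8
    x_train = _prepare_x(model, x_train)
    x_val = _prepare_x(model, x_val)
    class_weight = None
    if c.class_weighting:
        counts = np.bincount(y_train, minlength=model.n_classes).astype(float)
        inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        class_weight = inv * counts.sum() / max(inv @ counts, 1e-12)

    rng = np.random.default_rng(c.seed + 1)
    opt = _Adam([k for k in model.params if not k.startswith("r")],
                c.learning_rate)
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    best_log: list[dict] = []
    stale = 0
    n = len(x_train)
    for epoch in range(c.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, c.batch_size):
            idx = order[start:start + c.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            probs, cache = _forward(model, xb, training=True, rng=rng)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            sw = class_weight[yb] if class_weight is not None else None
            grads = _backward(model, cache, probs, onehot, sw)
            opt.step(model.params, grads)
            epoch_loss += _xentropy(probs, yb, sw) * len(yb)
        val_probs, _ = _forward(model, x_val, training=False)
        val_loss = _xentropy(val_probs, y_val) if len(y_val) else float("nan")
        val_acc = (float((val_probs.argmax(axis=1) == y_val).mean())
                   if len(y_val) else float("nan"))
        model.training_log.append({
            "epoch": epoch,
            "train_loss": epoch_loss / n,
            "val_loss": val_loss,
            "val_accuracy": val_acc,
        })
        if len(y_val) and val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_log = list(model.training_log)
            stale = 0
        else:
            stale += 1
            if len(y_val) and stale > c.patience:
                break
    if len(y_val):
        model.params = best_params
        model.training_log = best_log + model.training_log[len(best_log):]
    model.trained = True
    return model


def predict_proba(model: TrainedClassifier,
                  vectors: np.ndarray | Sequence[PooledEmbedding],
                  ) -> np.ndarray:
    """Class-probability matrix (n × n_classes), inference mode.

    Batch norm uses running statistics and dropout is off, so the result
    is deterministic; rows sum to 1 (softmax).
    """
    if not model.trained:
        raise ConfigurationError("model is not trained")
    if not isinstance(vectors, np.ndarray):
        vectors = stack_embeddings(vectors, model.config.input_type)
    x = _prepare_x(model, vectors)
    probs, _ = _forward(model, x, training=False)
    return probs


def predict_with_rejection(model: TrainedClassifier,
                           vectors: np.ndarray | Sequence[PooledEmbedding],
                           confidence_threshold: float = 0.9,
                           domain_ids: Optional[Sequence[str]] = None,
                           ) -> list[Prediction]:
    """Predict labels, rejecting low-confidence calls.

    A sample is assigned its argmax superfamily when the top probability
    is ≥ ``confidence_threshold`` and rejected otherwise; the confidence
    is always reported.  Ties go to the lowest class index.
    """
    if not 0.0 <= confidence_threshold <= 1.0:
        raise ConfigurationError("confidence threshold must be in [0, 1]")
    if domain_ids is None:
        if isinstance(vectors, np.ndarray):
            domain_ids = [str(i) for i in range(len(vectors))]
        else:
            domain_ids = [v.domain_id for v in vectors]
    probs = predict_proba(model, vectors)
    out = []
    for did, row in zip(domain_ids, probs):
        k = int(row.argmax())
        conf = float(row[k])
        rejected = conf < confidence_threshold
        out.append(Prediction(domain_id=did,
                              label=None if rejected else model.label_space[k],
                              confidence=conf, rejected=rejected))
    return out


def stack_embeddings(vectors: Sequence[PooledEmbedding],
                     input_type: str) -> np.ndarray:
    """Stack pooled embeddings into a matrix, checking channel agreement."""
    bad = [v.domain_id for v in vectors if v.channel != input_type]
    if bad:
        raise ChannelMismatchError(
            f"{len(bad)} vectors are not {input_type!r} channel "
            f"(e.g. {bad[:3]})")
    return np.stack([np.asarray(v.vector, dtype=np.float64) for v in vectors])


def save_classifier(model: TrainedClassifier, directory: str) -> None:
    """Persist as JSON config + label space and an .npz weight container."""
    os.makedirs(directory, exist_ok=True)
    meta = {
        "config": asdict(model.config),
        "label_space": list(model.label_space),
        "input_dim": model.input_dim,
        "trained": model.trained,
        "training_log": model.training_log,
        "standardized": model.feature_mean is not None,
    }
    with open(os.path.join(directory, "model.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    arrays = dict(model.params)
    if model.feature_mean is not None:
        arrays["feature_mean"] = model.feature_mean
        arrays["feature_std"] = model.feature_std
    np.savez(os.path.join(directory, "weights.npz"), **arrays)


def load_classifier(directory: str) -> TrainedClassifier:
    with open(os.path.join(directory, "model.json")) as fh:
        meta = json.load(fh)
    data = np.load(os.path.join(directory, "weights.npz"))
    params = {k: data[k] for k in data.files
              if k not in ("feature_mean", "feature_std")}
    model = TrainedClassifier(
        config=ClassifierConfig(**meta["config"]),
        label_space=tuple(meta["label_space"]),
        input_dim=int(meta["input_dim"]),
        params=params,
        training_log=meta["training_log"],
        trained=bool(meta["trained"]),
    )
    if meta.get("standardized"):
        model.feature_mean = data["feature_mean"]
        model.feature_std = data["feature_std"]
    return model
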