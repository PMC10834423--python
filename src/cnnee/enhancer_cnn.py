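"""A 1-D convolutional enhancer classifier with squeeze-and-excitation blocks.

The network consumes the 4 × 400 multi-omics signal matrix of a 4 kb window
and emits a sigmoid probability that the window contains an active enhancer.
Six catalogued architectures differ in their (conv, max-pool, dense) layer
counts; every convolution is followed by an SE block (global average squeeze,
two-layer excitation with a reduction ratio, sigmoid gating, channel rescale).

The implementation is self-contained NumPy: explicit forward/backward passes
for each layer, Adam updates, binary cross-entropy on the logit.  Besides
keeping the dependency footprint to the numerics stack, owning the backward
pass is what lets Grad-CAM read gradients at the final convolutional block
(`TrainedClassifier.final_conv_features`).  Bit-reproducibility for a given
seed is promised for single-threaded CPU execution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .signal_matrix import (
    InputMatrix,
    NormStats,
    compute_norm_stats,
    normalize_matrix,
)
from .training_data import TrainingExample

logger = logging.getLogger("cnnee")

__all__ = [
    "MODEL_CATALOGUE",
    "ModelSpec",
    "TrainConfig",
    "MetricReport",
    "TrainedClassifier",
    "ModelConfigError",
    "build_model",
    "train",
    "compute_metrics",
    "cross_validate",
    "predict_windows",
    "ablate_assay",
    "save_classifier",
    "load_classifier",
]

# (n_conv, n_pool, n_dense) per catalogued model
MODEL_CATALOGUE: dict[int, tuple[int, int, int]] = {
    1: (6, 1, 1),
    2: (7, 2, 1),
    3: (6, 2, 1),
    4: (7, 3, 1),
    5: (1, 1, 1),
    6: (5, 1, 1),
}


class ModelConfigError(ValueError):
    """Architecture that cannot be built (bad counts, collapsed length)."""


@dataclass
class ModelSpec:
    """Architecture hyper-parameters of one catalogue entry.

    Channel widths, kernel size and SE reduction are free hyper-parameters;
    only the layer counts are fixed by the catalogue.
    """

    model_id: int
    n_conv: int
    n_pool: int
    n_dense: int
    channels: list[int]
    kernel_bins: int = 5
    se_reduction: int = 4
    pool_size: int = 4
    dense_hidden: int = 64

    def __post_init__(self) -> None:
        if self.model_id in MODEL_CATALOGUE:
            expected = MODEL_CATALOGUE[self.model_id]
            got = (self.n_conv, self.n_pool, self.n_dense)
            if got != expected:
                raise ModelConfigError(
                    f"model {self.model_id} must have (conv, pool, dense) = "
                    f"{expected}, got {got}"
                )
        if len(self.channels) != self.n_conv:
            raise ModelConfigError(
                f"need {self.n_conv} channel widths, got {len(self.channels)}"
            )
        if self.kernel_bins % 2 == 0:
            raise ModelConfigError("kernel width must be odd (same padding)")

    @classmethod
    def from_catalogue(
        cls, model_id: int, base_channels: int = 16, channel_cap: int = 64, **kw
    ) -> "ModelSpec":
        if model_id not in MODEL_CATALOGUE:
            raise ModelConfigError(f"unknown model id {model_id}")
        n_conv, n_pool, n_dense = MODEL_CATALOGUE[model_id]
        channels = [min(base_channels * 2**i, channel_cap) for i in range(n_conv)]
        return cls(model_id, n_conv, n_pool, n_dense, channels, **kw)


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 3e-3
    seed: int = 0
    weight_decay: float = 0.0


# ---------------------------------------------------------------------------
# Layers (explicit forward/backward)
# ---------------------------------------------------------------------------

class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv1D(_Layer):
    """Same-padded 1-D convolution via im2col; x is (B, C_in, L)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = rng.normal(0.0, scale, size=(c_in * k, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        # (B, C, L, k) -> (B, L, C*k)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B, L, C * self.k)
        self._cols, self._in_shape = cols, x.shape
        y = cols @ self.W + self.b
        return np.ascontiguousarray(y.transpose(0, 2, 1))  # (B, c_out, L)

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, _, L = g.shape
        gy = np.ascontiguousarray(g.transpose(0, 2, 1))  # (B, L, c_out)
        flat_cols = self._cols.reshape(-1, self.c_in * self.k)
        flat_gy = gy.reshape(-1, self.c_out)
        self.dW[...] = flat_cols.T @ flat_gy
        self.db[...] = flat_gy.sum(axis=0)
        dcols = (gy @ self.W.T).reshape(B, L, self.c_in, self.k)
        pad = self.k // 2
        dxp = np.zeros((B, self.c_in, L + 2 * pad))
        for j in range(self.k):
            dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pad : pad + L]


class _ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class _SEBlock(_Layer):
    """Squeeze-and-excitation: global average pool → bottleneck → gate."""

    def __init__(self, c: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, c // reduction)
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / c), size=(c, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, c))
        self.b2 = np.zeros(c)
        self.dW1, self.db1 = np.zeros_like(self.W1), np.zeros_like(self.b1)
        self.dW2, self.db2 = np.zeros_like(self.W2), np.zeros_like(self.b2)
        self.params = [self.W1, self.b1, self.W2, self.b2]
        self.grads = [self.dW1, self.db1, self.dW2, self.db2]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x.mean(axis=2)  # (B, C) squeeze
        h_pre = z @ self.W1 + self.b1
        h = np.maximum(h_pre, 0.0)
        s = 1.0 / (1.0 + np.exp(-(h @ self.W2 + self.b2)))  # channel gates
        self._z, self._h_pre, self._h, self._s = z, h_pre, h, s
        return x * s[:, :, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        x, s, h = self._x, self._s, self._h
        L = x.shape[2]
        ds = (g * x).sum(axis=2) * s * (1.0 - s)
        self.dW2[...] = h.T @ ds
        self.db2[...] = ds.sum(axis=0)
        dh = (ds @ self.W2.T) * (self._h_pre > 0)
        self.dW1[...] = self._z.T @ dh
        self.db1[...] = dh.sum(axis=0)
        dz = dh @ self.W1.T
        return g * s[:, :, None] + dz[:, :, None] / L


class _MaxPool1D(_Layer):
    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        n = L // self.size
        if n < 1:
            raise ModelConfigError(
                f"max-pooling over {self.size} collapses length {L} below 1"
            )
        xt = x[:, :, : n * self.size].reshape(B, C, n, self.size)
        self._argmax = xt.argmax(axis=3)
        self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        B, C, n = g.shape
        dx = np.zeros(self._in_shape)
        dxt = dx[:, :, : n * self.size].reshape(B, C, n, self.size)
        bi, ci, ni = np.ogrid[:B, :C, :n]
        dxt[bi, ci, ni, self._argmax] = g
        return dx


class _GlobalAvgPool(_Layer):
    """Temporal global average pooling, (B, C, L) → (B, C).

    Placing this between the conv stack and the dense head makes the
    classifier translation-invariant over the window and makes the
    gradient-weighted class-activation map exact: with a single dense output
    layer, the globally averaged gradient per channel equals the dense weight
    over L, so the weighted activation sum is the class evidence map itself.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        L = self._shape[2]
        return np.repeat(g[:, :, None], L, axis=2) / L


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW, self.db = np.zeros_like(self.W), np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    loss: float
    tp: int
    fp: int
    fn: int
    tn: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "loss": self.loss,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
        }


class TrainedClassifier:
    """A catalogued CNN and (after `train`) its fitted state.

    ``predict_proba`` accepts raw (un-normalized) input matrices and applies
    the stored training normalization itself, so the probability contract
    (output strictly inside (0, 1)) cannot be broken by misuse.
    """

    def __init__(self, spec: ModelSpec, input_shape: tuple[int, int] = (4, 400),
                 init_seed: int = 0):
        self.spec = spec
        self.input_shape = input_shape
        self.norm_stats: NormStats | None = None
        self.training_log: list[dict] = []
        self.fitted = False
        rng = np.random.default_rng(np.random.SeedSequence(init_seed,
                                                           spawn_key=(101,)))
        layers: list[_Layer] = []
        c, length = input_shape
        pools_placed = 0
        for i in range(spec.n_conv):
            layers.append(_Conv1D(c, spec.channels[i], spec.kernel_bins, rng))
            layers.append(_ReLU())
            layers.append(_SEBlock(spec.channels[i], spec.se_reduction, rng))
            c = spec.channels[i]
            if pools_placed < spec.n_pool:
                layers.append(_MaxPool1D(spec.pool_size))
                pools_placed += 1
                length //= spec.pool_size
                if length < 1:
                    raise ModelConfigError(
                        "pooling schedule collapses the temporal dimension"
                    )
        # the end of the final conv block (its SE gate) is where Grad-CAM reads
        last_se = max(i for i, l in enumerate(layers) if isinstance(l, _SEBlock))
        self._feature_cut = last_se + 1
        layers.append(_GlobalAvgPool())
        n_flat = c
        for _ in range(spec.n_dense - 1):
            layers.append(_Dense(n_flat, spec.dense_hidden, rng))
            layers.append(_ReLU())
            n_flat = spec.dense_hidden
        layers.append(_Dense(n_flat, 1, rng))
        self.layers = layers

    # -- introspection -----------------------------------------------------
    def layer_counts(self) -> dict[str, int]:
        return {
            "conv": sum(isinstance(l, _Conv1D) for l in self.layers),
            "pool": sum(isinstance(l, _MaxPool1D) for l in self.layers),
            "dense": sum(isinstance(l, _Dense) for l in self.layers),
            "se": sum(isinstance(l, _SEBlock) for l in self.layers),
        }

    # -- forward/backward --------------------------------------------------
    def _logits(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]

    def _backward(self, dlogit: np.ndarray, stop_at: int = 0) -> np.ndarray:
        g = dlogit[:, None]
        for layer in reversed(self.layers[stop_at:]):
            g = layer.backward(g)
        return g

    def _prepare(self, matrices: Sequence[InputMatrix]) -> np.ndarray:
        if self.norm_stats is not None:
            matrices = [normalize_matrix(m, self.norm_stats) for m in matrices]
        return np.stack([m.values for m in matrices])

    def predict_proba(self, matrices: Sequence[InputMatrix],
                      batch_size: int = 256) -> np.ndarray:
        """Sigmoid probabilities in the open interval (0, 1).

        Valid on an unfitted model (random-initialization output); training
        state only changes the stored normalization and weights.
        """
        x = self._prepare(matrices)
        probs = np.empty(len(x))
        for i in range(0, len(x), batch_size):
            z = self._logits(x[i : i + batch_size])
            probs[i : i + batch_size] = 1.0 / (1.0 + np.exp(-z))
        eps = 1e-12
        return np.clip(probs, eps, 1.0 - eps)

    def final_conv_features(
        self, matrix: InputMatrix
    ) -> tuple[np.ndarray, np.ndarray]:
        """Activation maps of the final conv block and d(logit)/d(maps).

        Returns ``(A, dA)``, each of shape (channels, length'), where A is the
        output of the last convolution's SE gate and dA the gradient of the
        pre-sigmoid score with respect to it.
        """
        if not self.fitted:
            raise ModelConfigError("classifier is not fitted")
        if not any(isinstance(l, _Conv1D) for l in self.layers):
            raise ModelConfigError("model exposes no convolutional layer")
        h = self._prepare([matrix])
        A: np.ndarray | None = None
        for i, layer in enumerate(self.layers):
            h = layer.forward(h)
            if i == self._feature_cut - 1:
                A = h
        assert A is not None
        g = np.ones((1, 1))
        for layer in reversed(self.layers[self._feature_cut :]):
            g = layer.backward(g)
        # the gradient arriving at the cut is d logit / d A
        return A[0], g[0]

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(p, g) for layer in self.layers
                for p, g in zip(layer.params, layer.grads)]


def build_model(spec: ModelSpec, input_shape: tuple[int, int] = (4, 400),
                init_seed: int = 0) -> TrainedClassifier:
    """Instantiate an unfitted classifier for one catalogue entry."""
    return TrainedClassifier(spec, input_shape, init_seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (1.0 / (1.0 + np.exp(-z)) - y) / len(z)
    return loss, grad


class _Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]], lr: float,
                 weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            if self.wd:
                g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(model: TrainedClassifier, dataset: Sequence[TrainingExample],
          config: TrainConfig | None = None) -> TrainedClassifier:
    """Fit in place with Adam on binary cross-entropy; returns the model.

    Normalization statistics (per-assay mean/sd of log1p signal) are estimated
    on the training matrices and stored so prediction can reuse them.
    """
    config = config or TrainConfig()
    labels = np.array([ex.label for ex in dataset], dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    model.norm_stats = compute_norm_stats([ex.matrix for ex in dataset])
    x = np.stack(
        [normalize_matrix(ex.matrix, model.norm_stats).values for ex in dataset]
    )
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.parameters(), config.learning_rate, config.weight_decay)
    model.training_log = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(x), config.batch_size):
            idx = order[i : i + config.batch_size]
            z = model._logits(x[idx])
            loss, dz = _bce_with_logits(z, labels[idx])
            model._backward(dz)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        model.training_log.append(
            {"epoch": epoch, "loss": epoch_loss / n_batches,
             "lr": config.learning_rate, "seed": config.seed}
        )
    model.fitted = True
    return model


# ---------------------------------------------------------------------------
# Metrics, cross-validation, prediction
# ---------------------------------------------------------------------------

def compute_metrics(labels: np.ndarray, probs: np.ndarray,
                    threshold: float = 0.5) -> MetricReport:
    """Confusion-count metrics with the strict ``prob > threshold`` call rule.

    A probability exactly equal to the threshold is classified negative.
    Undefined precision/recall (zero denominator) is reported as 0 with a
    logged warning.
    """
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise ValueError(
            f"labels ({labels.shape}) and probs ({probs.shape}) differ in length"
        )
    pred = probs > threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    accuracy = (tp + tn) / len(labels) if len(labels) else 0.0
    if tp + fp == 0:
        logger.warning("no positive predictions; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("no positive labels; recall reported as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    p = np.clip(probs, 1e-12, 1 - 1e-12)
    loss = float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))
    return MetricReport(accuracy, precision, recall, f1, loss, tp, fp, fn, tn)


def _stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    out = [np.sort(np.array(f, dtype=int)) for f in folds]
    if any(len(np.unique(labels[f])) < 2 for f in out):
        raise ValueError(
            f"stratified {k}-fold split left a fold without both classes"
        )
    return out


def cross_validate(
    spec: ModelSpec,
    dataset: Sequence[TrainingExample],
    k: int = 5,
    config: TrainConfig | None = None,
    seed: int = 0,
    input_shape: tuple[int, int] = (4, 400),
) -> tuple[list[MetricReport], MetricReport]:
    """Stratified k-fold CV; every example is validated exactly once.

    Returns per-fold reports and their arithmetic mean (confusion counts are
    summed across folds).
    """
    config = config or TrainConfig()
    if len(dataset) < k:
        raise ValueError(f"dataset of {len(dataset)} cannot form {k} folds")
    labels = np.array([ex.label for ex in dataset])
    folds = _stratified_folds(labels, k, seed)
    reports: list[MetricReport] = []
    for fold_i, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(dataset)), val_idx)
        model = build_model(spec, input_shape, init_seed=seed + fold_i)
        fold_config = TrainConfig(
            epochs=config.epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate, seed=config.seed + fold_i,
            weight_decay=config.weight_decay,
        )
        train(model, [dataset[i] for i in train_idx], fold_config)
        probs = model.predict_proba([dataset[i].matrix for i in val_idx])
        reports.append(compute_metrics(labels[val_idx], probs))
        logger.info("fold %d/%d: F1 %.4f", fold_i + 1, k, reports[-1].f1)
    mean = MetricReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        loss=float(np.mean([r.loss for r in reports])),
        tp=sum(r.tp for r in reports), fp=sum(r.fp for r in reports),
        fn=sum(r.fn for r in reports), tn=sum(r.tn for r in reports),
    )
    return reports, mean


def predict_windows(
    model: TrainedClassifier,
    windows: Sequence[InputMatrix],
    threshold: float = 0.5,
) -> list[tuple[InputMatrix, float, bool]]:
    """One (window, probability, is_positive) record per input window."""
    if not model.fitted:
        raise ModelConfigError("classifier is not fitted")
    if not windows:
        return []
    probs = model.predict_proba(windows)
    return [(w, float(p), bool(p > threshold)) for w, p in zip(windows, probs)]


def save_classifier(model: TrainedClassifier, path) -> None:
    """Checkpoint: weights (.npz) + JSON manifest (spec, stats, log)."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.parameters())}
    np.savez(path, **arrays)
    manifest = {
        "spec": {
            "model_id": model.spec.model_id, "n_conv": model.spec.n_conv,
            "n_pool": model.spec.n_pool, "n_dense": model.spec.n_dense,
            "channels": model.spec.channels,
            "kernel_bins": model.spec.kernel_bins,
            "se_reduction": model.spec.se_reduction,
            "pool_size": model.spec.pool_size,
            "dense_hidden": model.spec.dense_hidden,
        },
        "input_shape": list(model.input_shape),
        "norm_stats": model.norm_stats.to_json() if model.norm_stats else None,
        "training_log": model.training_log,
        "fitted": model.fitted,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest))


def load_classifier(path) -> TrainedClassifier:
    import json
    from pathlib import Path

    path = Path(path)
    manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec = ModelSpec(**manifest["spec"])
    model = TrainedClassifier(spec, tuple(manifest["input_shape"]))
    arrays = np.load(path)
    for i, (p, _) in enumerate(model.parameters()):
        p[...] = arrays[f"p{i}"]
    if manifest["norm_stats"] is not None:
        model.norm_stats = NormStats.from_json(manifest["norm_stats"])
    model.training_log = manifest["training_log"]
    model.fitted = manifest["fitted"]
    return model


def ablate_assay(dataset: Sequence[TrainingExample], assay: str
                 ) -> list[TrainingExample]:
    """Remove one assay's information by zeroing its row in every matrix.

    Zeroing (rather than reshaping to 3 rows) keeps the architecture fixed so
    ablation comparisons differ only in the information supplied.
    """
    out = []
    for ex in dataset:
        m = ex.matrix
        row = m.assay_order.index(assay)
        values = m.values.copy()
        values[row] = 0.0
        out.append(TrainingExample(
            matrix=InputMatrix(m.window, values, m.assay_order),
            label=ex.label, origin=ex.origin,
        ))
    return out
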