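"""Temporal convolutional network for six-axis IMU window classification.

The network is a stack of homogeneous blocks — dilated causal 1D
convolution → batch normalization → ReLU → dropout — with *no* residual
connections, followed by a dense head (one hidden fully connected layer
whose width is a tuned hyperparameter, then a softmax output over the seven
motion sets).  Inputs are standardized windows shaped (samples, time,
channels); default windows are 100 time steps x 6 channels (2 s at 50 Hz).

Dilations cycle through (1, 2, 4, 8, 16, 32) across blocks rather than
doubling indefinitely, so deep stacks keep a bounded but window-covering
receptive field: at the defaults (20 blocks, kernel 3) the receptive field
is 1 + sum((k - 1) * d) = 385 time steps >= 100.

Everything — layers, backpropagation and the Adam optimizer — is
implemented in NumPy, so training is deterministic given the seed.
:class:`TCNClassifier` follows the scikit-learn estimator protocol;
:func:`build_tcn` / :func:`train` / :func:`predict` / :func:`tune` are the
pipeline-level wrappers.  The tuner is a seeded random search maximizing
validation accuracy.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Any, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from bafawubu.exceptions import ConfigurationError
from bafawubu.movements import CLASS_ORDER, as_code
from bafawubu.preprocess import ChannelStandardizer, WindowedDataset

DEFAULT_CLASS_CODES = tuple(c.value for c in CLASS_ORDER)


@dataclasses.dataclass(frozen=True)
class TcnConfig:
    """Architecture and training hyperparameters.

    Defaults follow the deployed recognizer where stated (20 blocks,
    dropout 0.44, 1000 epochs, 7 classes); kernel size, filter count,
    dilation cycle, dense width, optimizer settings and batch size are
    unstated there and default to standard small-model choices.
    """

    n_blocks: int = 20
    filters: int = 32
    kernel_size: int = 3
    dilations: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    dropout: float = 0.44
    dense_units: int = 64
    n_classes: int = 7
    learning_rate: float = 1e-3
    epochs: int = 1000
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be at least 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")

    @property
    def receptive_field(self) -> int:
        """1 + sum over blocks of (kernel_size - 1) * dilation."""
        rf = 1
        for i in range(self.n_blocks):
            rf += (self.kernel_size - 1) * self.dilations[i % len(self.dilations)]
        return rf


# ---------------------------------------------------------------------------
# layers


class _CausalConv1d:
    """Dilated causal convolution over (N, C, T); left zero padding keeps T."""

    kind = "conv"

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))  # He init for ReLU stacks
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * kernel))
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.dilation = dilation
        self.c_in = c_in

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, t = x.shape
        pad = (self.kernel - 1) * self.dilation
        xp = np.concatenate([np.zeros((n, c, pad)), x], axis=2)
        cols = np.empty((n, c * self.kernel, t))
        for k in range(self.kernel):
            cols[:, k * c:(k + 1) * c, :] = xp[:, :, k * self.dilation:
                                               k * self.dilation + t]
        self._cols = cols
        self._t = t
        return np.matmul(self.W, cols) + self.b[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, t = grad.shape
        self.dW = np.tensordot(grad, self._cols, axes=([0, 2], [0, 2]))
        self.db = grad.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, grad)
        pad = (self.kernel - 1) * self.dilation
        dxp = np.zeros((n, self.c_in, t + pad))
        for k in range(self.kernel):
            dxp[:, :, k * self.dilation: k * self.dilation + t] += \
                dcols[:, k * self.c_in:(k + 1) * self.c_in, :]
        self._cols = None
        return dxp[:, :, pad:]

    def grads(self):
        return {"W": self.dW, "b": self.db}


class _BatchNorm1d:
    """Per-channel batch normalization over the (N, T) axes."""

    kind = "batchnorm"

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        if training:
            self._xhat = xhat
            self._inv = inv
            self._n_eff = x.shape[0] * x.shape[2]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, n = self._xhat, self._inv, self._n_eff
        self.dgamma = (grad * xhat).sum(axis=(0, 2))
        self.dbeta = grad.sum(axis=(0, 2))
        gxh = grad * self.gamma[None, :, None]
        mean_g = gxh.mean(axis=(0, 2))
        mean_gx = (gxh * xhat).mean(axis=(0, 2))
        dx = (gxh - mean_g[None, :, None] - xhat * mean_gx[None, :, None]) \
            * inv[None, :, None]
        self._xhat = None
        return dx

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}


class _ReLU:
    kind = "relu"

    def params(self):
        return {}

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        out = grad * self._mask
        self._mask = None
        return out

    def grads(self):
        return {}


class _Dropout:
    kind = "dropout"

    def __init__(self, rate: float):
        self.rate = rate

    def params(self):
        return {}

    def forward(self, x, training, rng: np.random.Generator | None = None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out

    def grads(self):
        return {}


class _GlobalAvgPool:
    """(N, C, T) -> (N, C) mean over time."""

    kind = "pool"

    def params(self):
        return {}

    def forward(self, x, training):
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._t, axis=2) / self._t

    def grads(self):
        return {}


class _Dense:
    kind = "dense"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_out, n_in))
        self.b = np.zeros(n_out)

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x, training):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW = grad.T @ self._x
        self.db = grad.sum(axis=0)
        out = grad @ self.W
        self._x = None
        return out

    def grads(self):
        return {"W": self.dW, "b": self.db}


class _Adam:
    def __init__(self, layers, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in layer.params().items()}
                  for layer in layers]
        self.v = [{k: np.zeros_like(v) for k, v in layer.params().items()}
                  for layer in layers]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            grads = layer.grads()
            for name, param in layer.params().items():
                g = grads[name]
                m[name] = b1 * m[name] + (1 - b1) * g
                v[name] = b2 * v[name] + (1 - b2) * g * g
                param -= self.lr * (m[name] / corr1) / \
                    (np.sqrt(v[name] / corr2) + self.eps)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# estimator


class TCNClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style TCN classifier over (m, time, channels) windows.

    Parameters mirror :class:`TcnConfig`.  Fitted attributes:

    ``classes_`` — the seven movement codes in canonical order;
    ``layers_`` — the layer stack (blocks then head);
    ``history_`` — dict of per-epoch ``train_loss``, ``train_acc``,
    ``val_acc`` (``val_acc`` empty when no validation set is given);
    ``n_features_in_`` / ``window_len_`` — input geometry.
    """

    def __init__(self, n_blocks: int = 20, filters: int = 32,
                 kernel_size: int = 3,
                 dilations: tuple[int, ...] = (1, 2, 4, 8, 16, 32),
                 dropout: float = 0.44, dense_units: int = 64,
                 n_classes: int = 7, learning_rate: float = 1e-3,
                 epochs: int = 1000, batch_size: int = 64, seed: int = 0):
        self.n_blocks = n_blocks
        self.filters = filters
        self.kernel_size = kernel_size
        self.dilations = dilations
        self.dropout = dropout
        self.dense_units = dense_units
        self.n_classes = n_classes
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    # -- construction ------------------------------------------------------

    def _config(self) -> TcnConfig:
        return TcnConfig(self.n_blocks, self.filters, self.kernel_size,
                         tuple(self.dilations), self.dropout, self.dense_units,
                         self.n_classes, self.learning_rate, self.epochs,
                         self.batch_size, self.seed)

    def build(self, n_channels: int = 6, window_len: int = 100) -> "TCNClassifier":
        """Construct the (untrained) layer stack for the given geometry."""
        cfg = self._config()
        if cfg.receptive_field < window_len:
            raise ConfigurationError(
                f"receptive field {cfg.receptive_field} < window length "
                f"{window_len}; increase blocks, kernel or dilations")
        rng = np.random.default_rng(self.seed)
        layers: list = []
        c_in = n_channels
        for i in range(self.n_blocks):
            dilation = self.dilations[i % len(self.dilations)]
            layers.append(_CausalConv1d(c_in, self.filters, self.kernel_size,
                                        dilation, rng))
            layers.append(_BatchNorm1d(self.filters))
            layers.append(_ReLU())
            layers.append(_Dropout(self.dropout))
            c_in = self.filters
        layers.append(_GlobalAvgPool())
        layers.append(_Dense(self.filters, self.dense_units, rng))
        layers.append(_ReLU())
        layers.append(_Dense(self.dense_units, self.n_classes, rng))
        self.layers_ = layers
        self.n_features_in_ = n_channels
        self.window_len_ = window_len
        self.classes_ = np.asarray(DEFAULT_CLASS_CODES[: self.n_classes],
                                   dtype=object)
        return self

    def architecture_summary(self) -> dict:
        """Structural audit of the built network.

        Reports the block count, the within-block layer ordering, the
        dropout rate, the number of softmax (dense output) heads, the
        number of parameter groups and — structurally guaranteed, since the
        forward pass is a plain sequential loop with no addition nodes —
        the absence of residual connections.
        """
        if not hasattr(self, "layers_"):
            self.build()
        kinds = [layer.kind for layer in self.layers_]
        n_param_groups = sum(1 for layer in self.layers_ if layer.params())
        return {
            "n_blocks": self.n_blocks,
            "block_layout": ("conv", "batchnorm", "relu", "dropout"),
            "dropout": self.dropout,
            "has_residual_connections": False,
            "n_softmax_heads": 1,
            "n_dense_layers": sum(1 for k in kinds if k == "dense"),
            "n_parameter_groups": n_param_groups,
            "receptive_field": self._config().receptive_field,
            "layer_kinds": kinds,
        }

    # -- forward/backward --------------------------------------------------

    def _forward(self, x: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        out = x
        for layer in self.layers_:
            if layer.kind == "dropout":
                out = layer.forward(out, training, rng)
            else:
                out = layer.forward(out, training)
        return out

    def _backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers_):
            grad = layer.backward(grad)

    @staticmethod
    def _to_nct(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (m, time, channels)")
        return np.transpose(X, (0, 2, 1))

    def _encode_labels(self, y) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes_)}
        try:
            return np.asarray([index[as_code(label)] for label in y])
        except KeyError as exc:
            raise ValueError(f"label {exc} outside the model's class map")

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Minimize cross-entropy with Adam for ``epochs`` epochs.

        ``X`` is (m, time, channels) standardized windows.  When a
        validation set is given, per-epoch validation accuracy is recorded
        in ``history_``.  Training is fully deterministic given ``seed``.
        Non-finite loss (divergence) stops the loop early.
        """
        x = self._to_nct(X)
        m, n_channels, window_len = x.shape
        self.build(n_channels=n_channels, window_len=window_len)
        labels = self._encode_labels(y)
        optimizer = _Adam(self.layers_, self.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
        history = {"train_loss": [], "train_acc": [], "val_acc": []}
        eye = np.eye(self.n_classes)
        for _epoch in range(self.epochs):
            perm = rng.permutation(m)
            total_loss = 0.0
            total_correct = 0
            diverged = False
            for start in range(0, m, self.batch_size):
                idx = perm[start:start + self.batch_size]
                logits = self._forward(x[idx], training=True, rng=rng)
                probs = _softmax(logits)
                p_true = np.clip(probs[np.arange(len(idx)), labels[idx]],
                                 1e-12, None)
                loss = -np.mean(np.log(p_true))
                if not np.isfinite(loss):
                    diverged = True
                    break
                total_loss += loss * len(idx)
                total_correct += int((logits.argmax(axis=1) == labels[idx]).sum())
                grad = (probs - eye[labels[idx]]) / len(idx)
                self._backward(grad)
                optimizer.step()
            if diverged:
                break
            history["train_loss"].append(total_loss / m)
            history["train_acc"].append(total_correct / m)
            if X_val is not None:
                history["val_acc"].append(
                    float(np.mean(self.predict(X_val) == np.asarray(
                        [as_code(label) for label in y_val], dtype=object))))
        self.history_ = history
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "layers_"):
            raise ValueError("model is not fitted")
        x = self._to_nct(X)
        if x.shape[1] != self.n_features_in_ or x.shape[2] != self.window_len_:
            raise ValueError(
                f"windows must be ({self.window_len_}, {self.n_features_in_}); "
                f"got ({x.shape[2]}, {x.shape[1]})")
        chunks = []
        for start in range(0, len(x), 256):
            logits = self._forward(x[start:start + 256], training=False)
            chunks.append(_softmax(logits))
        return np.concatenate(chunks, axis=0)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]

    def score(self, X, y) -> float:
        y = np.asarray([as_code(label) for label in y], dtype=object)
        return float(np.mean(self.predict(X) == y))

    # -- persistence -------------------------------------------------------

    def _weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers_):
            for name, value in layer.params().items():
                out[f"{i}:{name}"] = value
            if layer.kind == "batchnorm":
                out[f"{i}:running_mean"] = layer.running_mean
                out[f"{i}:running_var"] = layer.running_var
        return out

    def _load_weights(self, blob: Mapping[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers_):
            for name in layer.params():
                getattr(layer, name)[...] = blob[f"{i}:{name}"]
            if layer.kind == "batchnorm":
                layer.running_mean[...] = blob[f"{i}:running_mean"]
                layer.running_var[...] = blob[f"{i}:running_var"]


# ---------------------------------------------------------------------------
# bundle + pipeline wrappers


@dataclasses.dataclass
class ModelBundle:
    """Trained (or untrained) model plus everything inference needs:
    channel standardization statistics and the index↔class map."""

    model: TCNClassifier
    channel_stats: ChannelStandardizer | None = None
    class_map: dict[int, str] = dataclasses.field(
        default_factory=lambda: dict(enumerate(DEFAULT_CLASS_CODES)))

    def __post_init__(self) -> None:
        codes = list(self.class_map.values())
        if len(set(codes)) != len(codes):
            raise ValueError("class_map codes must be unique")

    def save(self, directory: str | pathlib.Path) -> None:
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = dataclasses.asdict(self.model._config())
        cfg["window_len"] = getattr(self.model, "window_len_", 100)
        cfg["n_channels"] = getattr(self.model, "n_features_in_", 6)
        (directory / "config.json").write_text(json.dumps(cfg, indent=2))
        np.savez(directory / "weights.npz", **self.model._weights())
        with open(directory / "class_map.csv", "w") as fh:
            fh.write("index,class\n")
            for idx, code in sorted(self.class_map.items()):
                fh.write(f"{idx},{code}\n")
        if self.channel_stats is not None and self.channel_stats._is_fitted():
            with open(directory / "channel_stats.csv", "w") as fh:
                fh.write("channel,mean,sd\n")
                for ch, (mu, sd) in enumerate(zip(self.channel_stats.mean_,
                                                  self.channel_stats.sd_)):
                    fh.write(f"{ch},{float(mu)!r},{float(sd)!r}\n")

    @classmethod
    def load(cls, directory: str | pathlib.Path) -> "ModelBundle":
        directory = pathlib.Path(directory)
        cfg = json.loads((directory / "config.json").read_text())
        window_len = cfg.pop("window_len", 100)
        n_channels = cfg.pop("n_channels", 6)
        cfg["dilations"] = tuple(cfg["dilations"])
        model = TCNClassifier(**cfg)
        model.build(n_channels=n_channels, window_len=window_len)
        with np.load(directory / "weights.npz") as blob:
            model._load_weights(blob)
        class_map = {}
        for line in (directory / "class_map.csv").read_text().splitlines()[1:]:
            idx, code = line.split(",")
            class_map[int(idx)] = code
        stats = None
        stats_path = directory / "channel_stats.csv"
        if stats_path.exists():
            rows = [line.split(",") for line in
                    stats_path.read_text().splitlines()[1:]]
            stats = ChannelStandardizer()
            stats.mean_ = np.asarray([float(r[1]) for r in rows])
            stats.sd_ = np.asarray([float(r[2]) for r in rows])
        return cls(model=model, channel_stats=stats, class_map=class_map)


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Train/validation partition: two-thirds training by default, split at
    window or subject granularity (subject-wise prevents identity leakage)."""

    train_frac: float = 2.0 / 3.0
    unit: str = "subject"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        if self.unit not in ("window", "subject"):
            raise ValueError("unit must be 'window' or 'subject'")


def split_dataset(dataset: WindowedDataset,
                  spec: SplitSpec = SplitSpec()) -> tuple[WindowedDataset,
                                                          WindowedDataset]:
    """Seeded shuffled train/validation split.

    Window unit: sizes are within one window of the requested fractions.
    Subject unit: whole subjects are assigned to one side only (the window
    counts then follow the subjects' window counts).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(spec.seed)
    if spec.unit == "window":
        perm = rng.permutation(len(dataset))
        n_train = int(round(spec.train_frac * len(dataset)))
        return dataset.subset(perm[:n_train]), dataset.subset(perm[n_train:])
    if dataset.subject_ids is None:
        raise ValueError("subject-wise split requires subject_ids")
    subjects = np.unique(dataset.subject_ids.astype(str))
    perm = rng.permutation(len(subjects))
    n_train = int(round(spec.train_frac * len(subjects)))
    train_subjects = set(subjects[perm[:n_train]])
    mask = np.asarray([str(s) in train_subjects for s in dataset.subject_ids])
    return dataset.subset(np.where(mask)[0]), dataset.subset(np.where(~mask)[0])


def build_tcn(config: TcnConfig = TcnConfig(), n_channels: int = 6,
              window_len: int = 100) -> ModelBundle:
    """Construct an untrained bundle from a configuration."""
    model = TCNClassifier(**dataclasses.asdict(config))
    model.build(n_channels=n_channels, window_len=window_len)
    return ModelBundle(model=model)


def train(bundle: ModelBundle, train_set: WindowedDataset,
          validation_set: WindowedDataset | None = None) -> tuple[ModelBundle, dict]:
    """Fit a bundle on a standardized windowed dataset.

    If the training set carries no channel statistics they are fitted here
    and stored on the bundle; validation windows are scaled with the
    training statistics.
    """
    stats = train_set.channel_stats
    if stats is None or not stats._is_fitted():
        stats = ChannelStandardizer().fit(train_set.windows)
    bundle.channel_stats = stats
    x_train = stats.transform(train_set.windows)
    if validation_set is not None:
        bundle.model.fit(x_train, train_set.labels,
                         X_val=stats.transform(validation_set.windows),
                         y_val=validation_set.labels)
    else:
        bundle.model.fit(x_train, train_set.labels)
    return bundle, bundle.model.history_


def predict(bundle: ModelBundle, windows: np.ndarray) -> tuple[np.ndarray,
                                                               np.ndarray]:
    """Classify raw (unstandardized) windows; returns (labels, probs)."""
    windows = np.asarray(windows, dtype=float)
    if windows.ndim == 2:
        windows = windows[None]
    if bundle.channel_stats is not None and bundle.channel_stats._is_fitted():
        windows = bundle.channel_stats.transform(windows)
    probs = bundle.model.predict_proba(windows)
    labels = bundle.model.classes_[probs.argmax(axis=1)]
    return labels, probs


def tune(search_space: Mapping[str, Any], n_trials: int, seed: int,
         train_set: WindowedDataset, validation_set: WindowedDataset,
         base_config: TcnConfig = TcnConfig(),
         log_path: str | pathlib.Path | None = None) -> TcnConfig:
    """Seeded random search over TCN hyperparameters.

    ``search_space`` maps a :class:`TcnConfig` field to either a list of
    candidate values or a (low, high) range (integer ranges sample
    uniformly; positive float ranges spanning >= 2 decades sample
    log-uniformly, otherwise uniformly).  Returns the trialed configuration
    with the highest validation accuracy; the trial log is returned via
    ``log_path`` (JSON) when given.
    """
    if not search_space:
        raise ValueError("search space is empty")
    rng = np.random.default_rng(seed)
    trials = []
    best = None
    for trial in range(n_trials):
        overrides = {}
        for name, space in search_space.items():
            if isinstance(space, tuple) and len(space) == 2 and \
                    all(isinstance(v, (int, float)) and not isinstance(v, bool)
                        for v in space):
                low, high = space
                if isinstance(low, int) and isinstance(high, int):
                    overrides[name] = int(rng.integers(low, high + 1))
                elif low > 0 and high / low >= 100:
                    overrides[name] = float(10 ** rng.uniform(np.log10(low),
                                                              np.log10(high)))
                else:
                    overrides[name] = float(rng.uniform(low, high))
            else:
                values = list(space)
                overrides[name] = values[int(rng.integers(len(values)))]
        cfg = dataclasses.replace(base_config, **overrides)
        bundle = build_tcn(cfg, n_channels=train_set.windows.shape[2],
                           window_len=train_set.windows.shape[1])
        bundle, _ = train(bundle, train_set, validation_set)
        labels, _ = predict(bundle, validation_set.windows)
        acc = float(np.mean(labels == validation_set.labels))
        trials.append({"trial": trial, "overrides": overrides,
                       "val_accuracy": acc})
        if best is None or acc > best[0]:
            best = (acc, cfg)
    if log_path is not None:
        pathlib.Path(log_path).write_text(json.dumps(trials, indent=2))
    return best[1]
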