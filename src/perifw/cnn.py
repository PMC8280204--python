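"""Compact 2D CNN for 16x16 peritumoral patches, with majority voting.

Architecture (defaults): six 3x3 convolutional layers with ReLU, average
pooling after the second and fourth, max pooling after the sixth, global
average pooling of each feature map, and a softmax head over the two classes
(glioblastoma, metastasis). Training minimizes categorical cross-entropy
with RMSprop.

The network is implemented directly on NumPy (im2col convolutions and
explicit backpropagation), so a fixed seed gives bit-reproducible weights,
shuffling, and predictions on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .patches import PatchSet

__all__ = ["ModelConfig", "CnnModel", "TrainHistory", "SubjectPrediction",
           "build_model", "train", "predict_patch_probs", "predict_subject",
           "majority_vote", "balance_patches", "CLASSES"]

CLASSES = ("glioblastoma", "metastasis")   # index 0 = positive class


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters (all config-exposed)."""

    input_shape: tuple[int, int, int] = (16, 16, 1)
    conv_filters: tuple[int, ...] = (16, 16, 32, 32, 64, 64)
    kernel_size: int = 3
    avgpool_after: tuple[int, ...] = (2, 4)   # 1-based conv indices
    maxpool_after: int = 6
    optimizer: str = "rmsprop"
    loss: str = "categorical_crossentropy"
    learning_rate: float = 1e-3
    rho: float = 0.9
    epsilon: float = 1e-8
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_shape[:2] != (16, 16) or self.input_shape[2] not in (1, 2):
            raise ValueError("input shape must be 16x16x1 or 16x16x2")
        if len(self.conv_filters) == 0:
            raise ValueError("at least one convolutional layer is required")
        if self.optimizer != "rmsprop":
            raise ValueError("only the rmsprop optimizer is implemented")


# -- layers ------------------------------------------------------------------

class _Conv:
    """3x3 same-padding convolution via im2col; NHWC layout."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = k * k * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        self._cols = win.reshape(n * h * w, c * k * k)
        self._in_shape = x.shape
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray):
        n, h, w, c = self._in_shape
        k, p = self.k, self.k // 2
        dflat = dout.reshape(n * h * w, -1)
        self.dW = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dcols.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[..., i, j]
        return dxp[:, p:p + h, p:p + w, :]

    def grads(self):
        return [("W", self.dW), ("b", self.db)]


class _ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def grads(self):
        return []


class _AvgPool2:
    def params(self):
        return []

    def forward(self, x):
        n, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dout):
        n, h, w, c = self._shape
        d = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2) / 4.0
        return d

    def grads(self):
        return []


class _MaxPool2:
    def params(self):
        return []

    def forward(self, x):
        n, h, w, c = x.shape
        self._shape = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        # ties share the gradient equally (counts handled in backward)
        self._argmask = (xr == out[:, :, None, :, None, :])
        return out

    def backward(self, dout):
        n, h, w, c = self._shape
        xr_mask = self._argmask
        counts = xr_mask.sum(axis=(2, 4), keepdims=True)
        d = xr_mask * (dout[:, :, None, :, None, :] / counts)
        return d.reshape(n, h, w, c)

    def grads(self):
        return []


class _GAP:
    def params(self):
        return []

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :], self._shape) / (h * w)

    def grads(self):
        return []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in),
                            (d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def grads(self):
        return [("W", self.dW), ("b", self.db)]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainHistory:
    """Per-epoch training loss and accuracy."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(1, len(self.loss) + 1),
                             "loss": self.loss, "accuracy": self.accuracy})


class CnnModel:
    """The patch classifier: layer stack, weights, and provenance."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.map_kind: str | None = None
        self.train_fingerprint: str | None = None
        rng = np.random.default_rng(config.seed)
        layers: list = []
        c_in = config.input_shape[2]
        size = config.input_shape[0]
        for i, c_out in enumerate(config.conv_filters, start=1):
            layers.append(_Conv(c_in, c_out, config.kernel_size, rng))
            layers.append(_ReLU())
            if i in config.avgpool_after and size >= 2:
                layers.append(_AvgPool2())
                size //= 2
            if i == config.maxpool_after and size >= 2:
                layers.append(_MaxPool2())
                size //= 2
            c_in = c_out
        layers.append(_GAP())
        layers.append(_Dense(c_in, 2, rng))
        self.layers = layers
        self._rms_cache: dict[tuple[int, str], np.ndarray] = {}

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for _, p in layer.params())

    # -- checkpointing: npz weights + YAML architecture sidecar --------------

    def save(self, stem: str | Path) -> None:
        import yaml
        stem = Path(stem)
        arrays = {f"{li}_{name}": p for li, layer in enumerate(self.layers)
                  for name, p in layer.params()}
        np.savez(stem.with_suffix(".npz"), **arrays)
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.config.__dict__.items()}
        sidecar = {"config": cfg, "map_kind": self.map_kind,
                   "train_fingerprint": self.train_fingerprint,
                   "n_parameters": int(self.n_parameters)}
        stem.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))

    @classmethod
    def load(cls, stem: str | Path) -> "CnnModel":
        import yaml
        stem = Path(stem)
        sidecar = yaml.safe_load(stem.with_suffix(".yaml").read_text())
        cfg = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in sidecar["config"].items()}
        model = cls(ModelConfig(**cfg))
        arrays = np.load(stem.with_suffix(".npz"))
        for li, layer in enumerate(model.layers):
            for name, p in layer.params():
                p[:] = arrays[f"{li}_{name}"]
        model.map_kind = sidecar.get("map_kind")
        model.train_fingerprint = sidecar.get("train_fingerprint")
        return model

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:] != self.config.input_shape:
            raise ValueError(f"input shape {x.shape[1:]} does not match model "
                             f"input {self.config.input_shape}")
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (N, 2); columns ordered as CLASSES."""
        h = self._check_input(x)
        for layer in self.layers:
            h = layer.forward(h)
        return _softmax(h)

    def _train_step(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        probs = self.forward(x)
        n = x.shape[0]
        loss = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))
        dout = (probs - y_onehot) / n
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        cfg = self.config
        for li, layer in enumerate(self.layers):
            for (name, p), (_, g) in zip(layer.params(), layer.grads()):
                key = (li, name)
                c = self._rms_cache.get(key)
                if c is None:
                    c = np.zeros_like(p)
                c[:] = cfg.rho * c + (1 - cfg.rho) * g * g
                self._rms_cache[key] = c
                p -= cfg.learning_rate * g / (np.sqrt(c) + cfg.epsilon)
        return float(loss)


def build_model(config: ModelConfig = ModelConfig()) -> CnnModel:
    """Instantiate the (untrained) network with seeded weight initialization."""
    return CnnModel(config)


def _labels_to_indices(labels: np.ndarray) -> np.ndarray:
    idx = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in CLASSES:
            raise ValueError(f"unknown class label {lab!r}")
        idx[i] = CLASSES.index(lab)
    return idx


def _patchset_xy(patches: PatchSet) -> tuple[np.ndarray, np.ndarray]:
    x = patches.to_array()
    y = _labels_to_indices(patches.labels)
    return x, y


def train(model: CnnModel, train_patches: PatchSet | tuple[np.ndarray, np.ndarray],
          config: ModelConfig | None = None) -> TrainHistory:
    """Train in place by RMSprop on cross-entropy; returns the history.

    Requires at least two patches of each class. Epoch shuffling is driven
    by the model seed, so identical data and seed give identical weights.
    """
    cfg = config or model.config
    if isinstance(train_patches, PatchSet):
        x, y = _patchset_xy(train_patches)
        model.map_kind = train_patches.map_kind
    else:
        x, y = train_patches
        y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if (counts < 2).any():
        raise ValueError("training needs at least two patches per class; got "
                         f"{dict(zip(CLASSES, counts))}")
    x = model._check_input(x)
    y_onehot = np.eye(2, dtype=np.float32)[y]
    model.train_fingerprint = f"n={len(y)};sum={float(x.sum()):.6g}"
    rng = np.random.default_rng(cfg.seed + 1)
    history = TrainHistory()
    n = len(y)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            losses.append(model._train_step(x[sel], y_onehot[sel]))
        probs = predict_probs_array(model, x)
        acc = float(np.mean(probs.argmax(axis=1) == y))
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(acc)
    return history


def predict_probs_array(model: CnnModel, x: np.ndarray,
                        batch_size: int = 512) -> np.ndarray:
    x = model._check_input(x)
    out = [model.forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(out) if out else np.zeros((0, 2))


def predict_patch_probs(model: CnnModel, patches: PatchSet) -> np.ndarray:
    """Per-patch class probabilities (N, 2), columns ordered as CLASSES.

    Refuses a patch set whose map kind differs from the one the model was
    trained on (prevents silently scoring FA patches with an FW-VF model).
    """
    if model.map_kind is not None and patches.map_kind != model.map_kind:
        raise ValueError(f"model was trained on {model.map_kind!r} patches, "
                         f"got {patches.map_kind!r}")
    return predict_probs_array(model, patches.to_array())


@dataclass
class SubjectPrediction:
    """Patch probabilities aggregated to one subject label by majority vote."""

    subject_id: str
    patch_probs: np.ndarray          # (N, 2)
    patch_labels: np.ndarray         # argmax class name per patch
    votes: dict[str, int]
    final_label: str
    tie_broken: bool = False

    @property
    def gbm_vote_fraction(self) -> float:
        """Fraction of patches voting glioblastoma (the subject-level score)."""
        n = sum(self.votes.values())
        return self.votes[CLASSES[0]] / n if n else np.nan


def majority_vote(patch_probs: np.ndarray, subject_id: str = "sub-000",
                  tie_rule: str = "mean_prob") -> SubjectPrediction:
    """Subject label = modal class over patch argmax labels.

    Ties are broken by the higher mean patch probability (``tie_rule=
    'mean_prob'``), with the tie flagged.
    """
    probs = np.asarray(patch_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 2 or probs.shape[0] == 0:
        raise ValueError("need a non-empty (N, 2) probability array")
    hard = probs.argmax(axis=1)
    votes = {CLASSES[0]: int((hard == 0).sum()), CLASSES[1]: int((hard == 1).sum())}
    tie = votes[CLASSES[0]] == votes[CLASSES[1]]
    if not tie:
        final = CLASSES[0] if votes[CLASSES[0]] > votes[CLASSES[1]] else CLASSES[1]
    elif tie_rule == "mean_prob":
        means = probs.mean(axis=0)
        final = CLASSES[int(means.argmax())]
    else:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    return SubjectPrediction(
        subject_id=subject_id, patch_probs=probs,
        patch_labels=np.array([CLASSES[i] for i in hard]),
        votes=votes, final_label=final, tie_broken=bool(tie))


def predict_subject(model: CnnModel, patches: PatchSet,
                    subject_id: str | None = None) -> SubjectPrediction:
    """Score all of a subject's patches and majority-vote the final label."""
    if len(patches) == 0:
        raise ValueError("subject has no patches; cannot classify")
    probs = predict_patch_probs(model, patches)
    sid = subject_id or patches.patches[0].subject_id
    return majority_vote(probs, subject_id=sid)


class CnnClassifier:
    """fit/predict_proba adapter so the CNN runs through the same
    cross-validation driver as the texture baselines."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        self.config = config
        self.model: CnnModel | None = None
        self.history: TrainHistory | None = None

    def fit(self, patches: PatchSet) -> "CnnClassifier":
        self.model = build_model(self.config)
        self.history = train(self.model, patches)
        return self

    def predict_proba(self, patches: PatchSet) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        return predict_patch_probs(self.model, patches)


def balance_patches(patches: PatchSet, seed: int = 0) -> PatchSet:
    """Balanced patch sample: the majority class is randomly capped to the
    minority class count (the training-set balancing strategy)."""
    labels = patches.labels
    rng = np.random.default_rng(seed)
    idx_by_class = {c: np.flatnonzero(labels == c) for c in CLASSES}
    n_min = min(len(v) for v in idx_by_class.values())
    keep = np.concatenate([
        rng.permutation(v)[:n_min] for v in idx_by_class.values()])
    keep.sort()
    return PatchSet([patches.patches[i] for i in keep], patches.map_kind,
                    {**patches.provenance, "balanced": True, "balance_seed": seed})
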