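"""Per-axis binary slice classifiers (RoiNetX / RoiNetY / RoiNetZ).

All three networks share one architecture — input, [conv(32, 3x3) - BN -
ReLU - maxpool(2x2, stride 2)] x 2, then BN - ReLU before a 2-unit dense
head with softmax — and differ only in input size: X 43x512, Y 43x256,
Z 512x512.  Layer census: 1 input, 2 conv, 3 batch-norm, 3 ReLU, 2 pool,
1 fully connected, softmax.  The input stage zero-centers images by
subtracting the training-set mean image.

Training uses stochastic gradient descent with momentum, minibatch
shuffling every epoch and optional inverse-frequency class weighting
(background points heavily outnumber organ points).  Class order is
(background=0, organ=1) everywhere.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _nn

__all__ = [
    "AXIS_INPUT_SHAPES",
    "NetConfig",
    "AxisClassifier",
    "TrainingError",
    "build_network",
    "train_classifier",
    "predict_axis",
    "save_classifier",
    "load_classifier",
]

#: Canonical input sizes (rows, cols) for a 43x512x512 volume.
AXIS_INPUT_SHAPES = {"X": (43, 512), "Y": (43, 256), "Z": (512, 512)}

BACKGROUND, ORGAN = 0, 1


class TrainingError(ValueError):
    """Raised for unusable training sets (empty, or single-class)."""


@dataclass
class NetConfig:
    """Hyperparameters of one axis classifier.

    Defaults follow the final-system values: 32 filters of size 3,
    learning rate 0.01 with SGDM, minibatch 64, shuffling every epoch,
    40 epochs.  ``fast()`` gives the 4-epoch preset used for quick runs.
    """

    input_shape: tuple[int, int] | None = None  # (rows, cols); None = canonical for axis
    n_filters: int = 32
    filter_size: int = 3
    epochs: int = 40
    learning_rate: float = 0.01
    minibatch: int = 64
    momentum: float = 0.9
    validation_frequency: int = 30
    shuffle: bool = True
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_filters", "filter_size", "epochs", "minibatch", "validation_frequency"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.filter_size != 3:
            raise ValueError("only 3x3 filters are supported")

    @classmethod
    def fast(cls, **kw) -> "NetConfig":
        kw.setdefault("epochs", 4)
        return cls(**kw)


@dataclass
class AxisClassifier:
    """A trained (or trainable) binary classifier for one projection axis."""

    axis: str
    cfg: NetConfig
    net: _nn.Sequential
    mean_image: np.ndarray | None = None
    log: list[dict] = field(default_factory=list)

    @property
    def input_shape(self) -> tuple[int, int]:
        return self.cfg.input_shape

    def layer_census(self) -> dict[str, int]:
        counts: dict[str, int] = {"input": 1, "softmax": 1, "classification": 1}
        names = {
            _nn.Conv3x3: "conv",
            _nn.BatchNorm: "batchnorm",
            _nn.ReLU: "relu",
            _nn.MaxPool2: "maxpool",
            _nn.Dense: "fully_connected",
        }
        for layer in self.net.layers:
            name = names.get(type(layer))
            if name:
                counts[name] = counts.get(name, 0) + 1
        return counts

    def n_params(self) -> int:
        return self.net.n_params()

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        """(n, rows, cols) grayscale -> zero-centered NCHW batch."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 2:
            images = images[None]
        if images.shape[1:3] != tuple(self.cfg.input_shape):
            raise ValueError(
                f"axis {self.axis}: expected images of shape {self.cfg.input_shape}, "
                f"got {images.shape[1:3]}"
            )
        if self.mean_image is not None:
            images = images - self.mean_image
        return images[:, None, :, :]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (n, 2), rows summing to 1."""
        images = np.asarray(images, dtype=np.float32)
        if images.size == 0:
            return np.zeros((0, 2), np.float32)
        x = self._prepare(images)
        probs = np.empty((x.shape[0], 2), np.float32)
        step = _eval_chunk(self.cfg.input_shape, self.cfg.n_filters)
        for i in range(0, x.shape[0], step):
            probs[i : i + step] = _nn.softmax(self.net.forward(x[i : i + step], train=False))
        return probs

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Hard labels: 1 = organ, 0 = background."""
        probs = self.predict_proba(images)
        return probs.argmax(axis=1)


def _eval_chunk(shape: tuple[int, int], n_filters: int) -> int:
    elems = shape[0] * shape[1] * n_filters
    return max(1, int(24e6 // max(elems, 1)))


def build_network(cfg: NetConfig, axis: str = "X") -> AxisClassifier:
    """Build an untrained classifier for one axis.

    If ``cfg.input_shape`` is None the canonical shape for the axis is
    used; an explicit shape may be any (rows >= 5, cols >= 5) geometry,
    which keeps small test volumes usable.
    """
    axis = axis.upper()
    if axis not in AXIS_INPUT_SHAPES:
        raise ValueError(f"axis must be one of X, Y, Z; got {axis!r}")
    if cfg.input_shape is None:
        cfg = replace(cfg, input_shape=AXIS_INPUT_SHAPES[axis])
    h, w = cfg.input_shape
    if h < 5 or w < 5:
        raise ValueError(f"input shape too small: {cfg.input_shape}")
    rng = np.random.default_rng(cfg.seed)
    f = cfg.n_filters
    d_in = (h // 4) * (w // 4) * f
    net = _nn.Sequential(
        [
            _nn.Conv3x3(1, f, rng, first=True),
            _nn.BatchNorm(f),
            _nn.ReLU(),
            _nn.MaxPool2(),
            _nn.Conv3x3(f, f, rng),
            _nn.BatchNorm(f),
            _nn.ReLU(),
            _nn.MaxPool2(),
            _nn.BatchNorm(f),
            _nn.ReLU(),
            _nn.Flatten(),
            _nn.Dense(d_in, 2, rng),
        ]
    )
    return AxisClassifier(axis=axis, cfg=cfg, net=net)


def _micro_batch(shape: tuple[int, int], n_filters: int, minibatch: int) -> int:
    # bound the largest stored activation (conv1 output) to ~128 MB
    elems = shape[0] * shape[1] * n_filters
    return max(1, min(minibatch, int(8e6 // max(elems // 4, 1))))


def train_classifier(
    classifier: AxisClassifier,
    images: np.ndarray,
    labels: np.ndarray,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> AxisClassifier:
    """Train in place with SGDM and return the classifier.

    ``images`` is (n, rows, cols) float in [0, 1]; ``labels`` is (n,) with
    1 = organ, 0 = background.  Fixed config seed implies bit-reproducible
    weights on one platform.
    """
    cfg = classifier.cfg
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    n = images.shape[0]
    if n == 0:
        raise TrainingError("empty training set")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise TrainingError(f"training set contains a single class: {classes.tolist()}")

    classifier.mean_image = images.mean(axis=0, dtype=np.float64).astype(np.float32)
    x = images - classifier.mean_image
    if cfg.class_weighting:
        freq = np.zeros(2, np.float64)
        freq[classes] = counts
        weights = (n / (2.0 * np.maximum(freq, 1))).astype(np.float32)
    else:
        weights = np.ones(2, np.float32)

    rng = np.random.default_rng(cfg.seed + 1)
    micro = _micro_batch(cfg.input_shape, cfg.n_filters, cfg.minibatch)
    it = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        for start in range(0, n, cfg.minibatch):
            idx = order[start : start + cfg.minibatch]
            norm = float(weights[labels[idx]].sum())
            classifier.net.zero_grad()
            loss = 0.0
            correct = 0
            for j in range(0, len(idx), micro):
                sub = idx[j : j + micro]
                logits = classifier.net.forward(x[sub][:, None, :, :], train=True)
                sub_loss, dlogits = _nn.weighted_xent_grad(logits, labels[sub], weights, norm)
                classifier.net.backward(dlogits)
                loss += sub_loss
                correct += int((logits.argmax(axis=1) == labels[sub]).sum())
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at iteration {it}")
            _nn.sgdm_step(classifier.net, cfg.learning_rate, cfg.momentum)
            it += 1
            entry = {"iter": it, "epoch": epoch, "loss": loss, "acc": correct / len(idx)}
            if val_images is not None and it % cfg.validation_frequency == 0:
                pred = classifier.predict(val_images)
                entry["val_acc"] = float((pred == np.asarray(val_labels)).mean())
            classifier.log.append(entry)
    return classifier


def predict_axis(classifier: AxisClassifier, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batch prediction: (labels, organ probabilities), batch order preserved."""
    probs = classifier.predict_proba(images)
    return probs.argmax(axis=1), probs[:, ORGAN]


def save_classifier(classifier: AxisClassifier, path) -> None:
    """Persist weights (.npz) plus a JSON sidecar with axis and config."""
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(classifier.net.layers):
        for name, p in layer.params.items():
            arrays[f"l{i}_{name}"] = p.value
        if isinstance(layer, _nn.BatchNorm):
            arrays[f"l{i}_running_mean"] = layer.running_mean
            arrays[f"l{i}_running_var"] = layer.running_var
    if classifier.mean_image is not None:
        arrays["mean_image"] = classifier.mean_image
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"axis": classifier.axis, "cfg": asdict(classifier.cfg)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_classifier(path) -> AxisClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = sidecar["cfg"]
    cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
    cfg = NetConfig(**cfg_dict)
    classifier = build_network(cfg, axis=sidecar["axis"])
    with np.load(path.with_suffix(".npz")) as data:
        for i, layer in enumerate(classifier.net.layers):
            for name, p in layer.params.items():
                p.value[...] = data[f"l{i}_{name}"]
            if isinstance(layer, _nn.BatchNorm):
                layer.running_mean[...] = data[f"l{i}_running_mean"]
                layer.running_var[...] = data[f"l{i}_running_var"]
                layer._warm = True
        if "mean_image" in data:
            classifier.mean_image = data["mean_image"]
    return classifier
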