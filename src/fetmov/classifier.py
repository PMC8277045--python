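"""The three-class CNN classifier: splitting, building, training, predicting.

The network mirrors the monitoring system's published layer table: three
convolution stages with kernels 5x3, 5x2, 5x2 and 60/50/40 filters, each
followed by ReLU, then a flatten and a dense 3-way softmax head; training
is plain stochastic gradient descent at learning rate 1e-4.  Realizations
enter as small RGB images (64x26x3 for full spectrograms; the NNMF
variants feed the rendered W or H matrix instead, and the input shape —
and, where a factor matrix is thinner than a kernel, the clamped kernel —
adapt accordingly).

Class imbalance is deliberately preserved: the split is stratified per
class at the natural inter-class ratio (80/20 by default, floor rounding
on the train side), with no rebalancing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .segmentation import MovementClass

__all__ = [
    "CNNSpec",
    "SplitIndices",
    "TrainedModel",
    "stratified_split",
    "build_cnn",
    "train_cnn",
    "predict",
]

CLASS_ORDER = (MovementClass.FETAL, MovementClass.LAUGH, MovementClass.RESPIRATORY)


@dataclass(frozen=True)
class CNNSpec:
    """Architecture and training hyper-parameters.

    Defaults follow the published layer table (kernels 5x3/5x2/5x2,
    filters 60/50/40, learning rate 1e-4, 300 end-to-end epochs, SGD).
    ``small()`` returns a reduced configuration for desk-scale corpus
    experiments: same kernel geometry, 8/6/4 filters, 50 epochs at
    learning rate 1e-3 — the epoch count at which the training loss
    plateaus on corpora of ~1500 realizations, keeping runs single-CPU
    friendly.
    """

    conv_kernels: tuple[tuple[int, int], ...] = ((5, 3), (5, 2), (5, 2))
    conv_filters: tuple[int, ...] = (60, 50, 40)
    learning_rate: float = 1e-4
    epochs: int = 300
    batch_size: int = 32
    n_classes: int = 3
    input_shape: tuple[int, int, int] = (64, 26, 3)  # (H, W, C)

    def __post_init__(self) -> None:
        if len(self.conv_kernels) != 3 or len(self.conv_filters) != 3:
            raise ValueError("spec must define exactly 3 conv stages")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @staticmethod
    def small(input_shape: tuple[int, int, int] = (64, 26, 3),
              epochs: int = 50) -> "CNNSpec":
        return CNNSpec(conv_filters=(8, 6, 4), learning_rate=1e-3,
                       epochs=epochs, input_shape=input_shape)

    def with_input_shape(self, shape: tuple[int, int, int]) -> "CNNSpec":
        return replace(self, input_shape=tuple(int(s) for s in shape))


@dataclass
class SplitIndices:
    """Disjoint stratified train/test indices over a labeled dataset."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    train_frac: float

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")


def stratified_split(labels: np.ndarray, train_frac: float = 0.8,
                     seed: int = 0) -> SplitIndices:
    """Per-class random split at ``train_frac`` (floor rule on train side).

    Every class keeps its natural share in both partitions; the per-class
    train count is floor(train_frac * n_class).  Deterministic in ``seed``.
    Accepts a LabeledDataset or a plain label array.
    """
    if hasattr(labels, "labels"):
        labels = labels.labels
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(
                f"class {c} has {idx.size} member(s); need >= 2 to split"
            )
        perm = rng.permutation(idx)
        k = int(np.floor(train_frac * idx.size))
        train.append(perm[:k])
        test.append(perm[k:])
    return SplitIndices(
        train_idx=np.sort(np.concatenate(train)),
        test_idx=np.sort(np.concatenate(test)),
        train_frac=train_frac,
    )


def _clamped_kernel(kernel: tuple[int, int], h: int, w: int) -> tuple[int, int]:
    # factor matrices (64 x r, r x 26) can be thinner than a kernel in one
    # dimension; clamp that dimension so valid convolution stays defined
    return (min(kernel[0], h), min(kernel[1], w))


def build_cnn(spec: CNNSpec, seed: int = 0) -> nn.Sequential:
    """Instantiate the (untrained) network for ``spec.input_shape``.

    Architecture: 3 x [valid conv -> ReLU], flatten, dense -> 3 logits.
    Raises ValueError when the input is too small even for clamped kernels.
    """
    h, w, c = spec.input_shape
    if h < 1 or w < 1 or c < 1:
        raise ValueError(f"invalid input shape {spec.input_shape}")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = c
    for kernel, filters in zip(spec.conv_kernels, spec.conv_filters):
        kh, kw = _clamped_kernel(kernel, h, w)
        conv = nn.Conv2D(in_ch, filters, (kh, kw), rng)
        h, w = conv.out_shape(h, w)
        layers += [conv, nn.ReLU()]
        in_ch = filters
    layers.append(nn.Flatten())
    layers.append(nn.Dense(h * w * in_ch, spec.n_classes, rng))
    return nn.Sequential(layers)


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reproduce it."""

    net: nn.Sequential
    spec: CNNSpec
    class_order: tuple[MovementClass, ...] = CLASS_ORDER
    training_log: list[float] = field(default_factory=list)  # per-epoch mean loss
    seed: int = 0


def _to_nchw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError(f"expected batch of H x W x C images, got shape {x.shape}")
    return x.transpose(0, 3, 1, 2)


def train_cnn(
    features: np.ndarray,
    labels: np.ndarray,
    split: SplitIndices,
    spec: CNNSpec,
    seed: int = 0,
) -> TrainedModel:
    """Train the network with minibatch SGD on the train split.

    ``features`` is (N, H, W, C); ``labels`` holds class indices 0..2.
    The seed fixes both weight init and epoch shuffling, so two runs with
    identical inputs are bit-identical.  A non-finite loss aborts with a
    diagnostic rather than training on.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if np.any((labels < 0) | (labels >= spec.n_classes)):
        raise ValueError("labels must be class indices in [0, n_classes)")
    x = _to_nchw(features)
    if x.shape[1:] != (spec.input_shape[2], spec.input_shape[0], spec.input_shape[1]):
        raise ValueError(
            f"feature shape {features.shape[1:]} does not match spec input "
            f"shape {spec.input_shape}"
        )
    if split.train_idx.size == 0:
        raise ValueError("empty train split")
    net = build_cnn(spec, seed=seed)
    rng = np.random.default_rng(seed + 1)
    xt, yt = x[split.train_idx], labels[split.train_idx]
    log: list[float] = []
    for _ in range(spec.epochs):
        order = rng.permutation(len(yt))
        losses = []
        for s in range(0, len(yt), spec.batch_size):
            b = order[s : s + spec.batch_size]
            try:
                losses.append(net.train_batch(xt[b], yt[b], spec.learning_rate))
            except FloatingPointError as exc:
                raise RuntimeError(
                    f"training aborted at epoch {len(log)}: {exc}"
                ) from exc
        log.append(float(np.mean(losses)))
    return TrainedModel(net=net, spec=spec, training_log=log, seed=seed)


def predict(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and probability rows for a feature batch.

    Probability rows are non-negative and sum to 1; the label is the
    argmax, ties resolved toward the lowest class index (numpy argmax).
    """
    x = _to_nchw(features)
    expect = (model.spec.input_shape[2], model.spec.input_shape[0],
              model.spec.input_shape[1])
    if x.shape[1:] != expect:
        raise ValueError(
            f"feature shape {features.shape[1:]} does not match model input "
            f"shape {model.spec.input_shape}"
        )
    probs = model.net.predict_proba(x)
    return probs.argmax(axis=1), probs
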