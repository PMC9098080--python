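"""CNN classifier: configuration, weighted loss, augmentation and
snapshot-ensemble training with a cosine-annealing learning-rate schedule."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from usvpipe.errors import ConfigError, EmptyInputError, ShapeMismatchError
from usvpipe import nn

_ALLOWED_CONV_LAYERS = (3, 4, 5)
_ALLOWED_FILTERS = (16, 32, 64, 96)
_ALLOWED_FIRST_KERNELS = ((3, 3), (5, 5), (3, 18))
_ALLOWED_DENSE = (32, 64, 128)


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters; defaults follow the published search grid.

    ``first_stride`` is an efficiency extension (time-axis striding in the
    first convolution) used by reduced-scale runs; ``(1, 1)`` reproduces the
    plain architecture.
    """

    n_conv_layers: int = 4
    filters_per_layer: tuple[int, ...] = (32, 32, 64, 64)
    first_kernel: tuple[int, int] = (3, 18)
    later_kernel: tuple[int, int] = (3, 3)
    dense_size: int = 128
    n_dense: int = 2
    dropout_p: float = 0.5
    l2_coeff: float = 1e-4
    lr_max: float = 1e-3
    cycle_len: int = 40
    n_cycles: int = 5
    batch_size: int = 64
    n_classes: int = 12
    momentum: float = 0.9
    seed: int = 0
    first_stride: tuple[int, int] = (1, 1)
    input_shape: tuple[int, int] = (64, 401)
    augment: bool = True

    def __post_init__(self) -> None:
        if self.n_conv_layers not in _ALLOWED_CONV_LAYERS:
            raise ConfigError(f"n_conv_layers must be one of {_ALLOWED_CONV_LAYERS}")
        if len(self.filters_per_layer) != self.n_conv_layers:
            raise ConfigError("filters_per_layer length must equal n_conv_layers")
        for f in self.filters_per_layer:
            if f not in _ALLOWED_FILTERS:
                raise ConfigError(f"filter count {f} not in {_ALLOWED_FILTERS}")
        if tuple(self.first_kernel) not in _ALLOWED_FIRST_KERNELS:
            raise ConfigError(f"first_kernel must be one of {_ALLOWED_FIRST_KERNELS}")
        if self.dense_size not in _ALLOWED_DENSE:
            raise ConfigError(f"dense_size must be one of {_ALLOWED_DENSE}")
        if not 0 <= self.dropout_p < 1:
            raise ConfigError("dropout_p must lie in [0, 1)")
        if self.cycle_len < 1 or self.n_cycles < 1:
            raise ConfigError("cycle_len and n_cycles must be positive")

    @property
    def total_epochs(self) -> int:
        return self.n_cycles * self.cycle_len


def class_weights(class_counts) -> np.ndarray:
    """Inverse-frequency class weights ``cw_i = N / (c * n_i)``.

    ``class_counts`` is a sequence of per-class sample counts.  The weighted
    mean of the weights under the empirical class distribution is exactly 1.
    """
    counts = np.asarray(class_counts, dtype=float)
    if counts.size == 0:
        raise EmptyInputError("no class counts given")
    if np.any(counts <= 0):
        raise ValueError("all class counts must be positive; drop empty classes upstream")
    n_total = counts.sum()
    c = len(counts)
    return n_total / (c * counts)


def wcce_loss(y_onehot: np.ndarray, p: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Class-weighted categorical cross-entropy (natural log), batch mean."""
    y = np.atleast_2d(np.asarray(y_onehot, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if y.shape != p.shape:
        raise ShapeMismatchError(f"y {y.shape} vs p {p.shape}")
    if weights is None:
        weights = np.ones(y.shape[1])
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (y.shape[1],):
        raise ShapeMismatchError("weights length must equal the class count")
    per_sample = -(weights * y * np.log(p)).sum(axis=1)
    return float(per_sample.mean())


def cosine_annealing_lr(epoch: int, cycle_len: int = 40, lr_max: float = 1e-3) -> float:
    """Cosine-annealed learning rate with warm restarts (0-based epoch)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    phase = (epoch % cycle_len) / cycle_len
    return (lr_max / 2.0) * (np.cos(np.pi * phase) + 1.0)


def augment_batch(images: np.ndarray, seed: int | np.random.Generator,
                  max_frac: float = 0.1, fill: float | None = None) -> np.ndarray:
    """Random per-image height/width shifts of up to 10% of each dimension.

    Vacated pixels are filled with ``fill`` (default: each image's minimum,
    i.e. the log-floor for unnormalized, 0 for min-max normalized images).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    imgs = np.asarray(images)
    squeeze = imgs.ndim == 3
    x = imgs[:, None] if squeeze else imgs
    n, c, h, w = x.shape
    max_dh = int(np.ceil(max_frac * h))
    max_dw = int(np.ceil(max_frac * w))
    out = np.empty_like(x)
    dhs = rng.integers(-max_dh, max_dh + 1, size=n)
    dws = rng.integers(-max_dw, max_dw + 1, size=n)
    for i in range(n):
        fv = float(x[i].min()) if fill is None else fill
        shifted = np.full_like(x[i], fv)
        dh, dw = int(dhs[i]), int(dws[i])
        src_h = slice(max(0, -dh), min(h, h - dh))
        dst_h = slice(max(0, dh), min(h, h + dh))
        src_w = slice(max(0, -dw), min(w, w - dw))
        dst_w = slice(max(0, dw), min(w, w + dw))
        shifted[:, dst_h, dst_w] = x[i][:, src_h, src_w]
        out[i] = shifted
    return out[:, 0] if squeeze else out


def build_classifier(config: ClassifierConfig,
                     rng: np.random.Generator | None = None) -> nn.Network:
    """Assemble the CNN.

    First convolution uses ``first_kernel``; every convolution except the
    last is followed by Module 1 (batch norm + ELU + 2x2 max pool), the last
    by Module 2 (batch norm + ELU).  Two dense layers, dropout, softmax head.
    """
    rng = rng or np.random.default_rng(config.seed)
    h, w = config.input_shape
    layers: list[nn.Layer] = []
    in_ch = 1
    for i in range(config.n_conv_layers):
        kernel = tuple(config.first_kernel) if i == 0 else tuple(config.later_kernel)
        stride = tuple(config.first_stride) if i == 0 else (1, 1)
        layers.append(nn.Conv2D(in_ch, config.filters_per_layer[i], kernel,
                                stride=stride, rng=rng))
        h = (h + stride[0] - 1) // stride[0]
        w = (w + stride[1] - 1) // stride[1]
        layers.append(nn.BatchNorm(config.filters_per_layer[i]))
        layers.append(nn.ELU())
        if i < config.n_conv_layers - 1:  # Module 1 pools, Module 2 does not
            layers.append(nn.MaxPool2D((2, 2)))
            h //= 2
            w //= 2
        in_ch = config.filters_per_layer[i]
    layers.append(nn.Flatten())
    dim = in_ch * h * w
    for _ in range(config.n_dense):
        layers.append(nn.Dense(dim, config.dense_size, rng=rng))
        layers.append(nn.ELU())
        dim = config.dense_size
    layers.append(nn.Dropout(config.dropout_p))
    layers.append(nn.Dense(dim, config.n_classes, rng=rng))
    return nn.Network(layers)


@dataclass
class SnapshotSet:
    """Checkpoints harvested at the learning-rate minima of one training run."""

    config: ClassifierConfig
    class_names: list[str]
    checkpoints: list[list[np.ndarray]]
    history: list[dict]
    _network: nn.Network | None = None

    def network_at(self, checkpoint: int = -1) -> nn.Network:
        if self._network is None:
            self._network = build_classifier(self.config)
        self._network.set_state(self.checkpoints[checkpoint])
        return self._network

    def predict_proba(self, x: np.ndarray, checkpoint: int = -1,
                      batch_size: int = 128) -> np.ndarray:
        return self.network_at(checkpoint).predict_proba(x, batch_size)


def _as_images(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    return x


def train_snapshots(train_set: tuple[np.ndarray, np.ndarray],
                    val_set: tuple[np.ndarray, np.ndarray] | None,
                    config: ClassifierConfig,
                    weights: np.ndarray | None = None,
                    class_names: list[str] | None = None,
                    verbose: bool = False) -> SnapshotSet:
    """Run ``n_cycles * cycle_len`` epochs, snapshotting at each cycle end.

    ``train_set`` is ``(images, integer_labels)``; images may be
    ``(n, 64, 401)`` or ``(n, 1, 64, 401)``, already normalized to [0, 1].
    """
    x_train, y_train = train_set
    if len(x_train) == 0:
        raise EmptyInputError("empty training set")
    x_train = _as_images(x_train)
    y_train = np.asarray(y_train, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    network = build_classifier(config, rng=rng)
    optimizer = nn.NesterovSGD(network, momentum=config.momentum,
                               l2_coeff=config.l2_coeff)
    cw = None if weights is None else np.asarray(weights, dtype=np.float32)
    n = len(x_train)
    checkpoints = []
    history = []
    for epoch in range(config.total_epochs):
        lr = cosine_annealing_lr(epoch, config.cycle_len, config.lr_max)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for b0 in range(0, n, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            xb = x_train[idx]
            if config.augment:
                xb = augment_batch(xb, rng)
            epoch_loss += network.loss_and_grad(xb, y_train[idx], cw, rng)
            optimizer.step(lr)
            n_batches += 1
        record = {"epoch": epoch + 1, "lr": lr, "loss": epoch_loss / max(n_batches, 1)}
        if (epoch + 1) % config.cycle_len == 0:
            checkpoints.append(network.get_state())
            record["snapshot"] = len(checkpoints)
        if val_set is not None and (epoch + 1) % config.cycle_len == 0:
            xv, yv = _as_images(val_set[0]), np.asarray(val_set[1])
            pv = network.predict_proba(xv, config.batch_size)
            record["val_accuracy"] = float(np.mean(pv.argmax(axis=1) == yv))
        history.append(record)
        if verbose:
            print(f"epoch {epoch + 1}/{config.total_epochs} "
                  f"lr={lr:.2e} loss={record['loss']:.4f}")
    if class_names is None:
        class_names = [str(i) for i in range(config.n_classes)]
    return SnapshotSet(config=config, class_names=list(class_names),
                       checkpoints=checkpoints, history=history)


def grid_search(train_set, val_set, configs: list[ClassifierConfig],
                weights: np.ndarray | None = None) -> tuple[ClassifierConfig, list[dict]]:
    """Optional architecture search: train each candidate, rank by validation
    accuracy of its last snapshot.  Returns (best config, per-config records)."""
    if not configs:
        raise EmptyInputError("no candidate configurations")
    xv = _as_images(np.asarray(val_set[0]))
    yv = np.asarray(val_set[1])
    records = []
    for config in configs:
        snapshots = train_snapshots(train_set, None, config, weights=weights)
        probs = snapshots.predict_proba(xv, batch_size=config.batch_size)
        records.append({"config": config,
                        "val_accuracy": float(np.mean(probs.argmax(1) == yv))})
    best = max(records, key=lambda r: r["val_accuracy"])
    return best["config"], records
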