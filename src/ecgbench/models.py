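"""The four 1-D neural architectures, the majority-class baseline, and the
training loop.

Each architecture is tied to an input sampling frequency (CNN 360 Hz,
ResNet 250 Hz, GRUAttNet 500 Hz, RTA-CNN 300 Hz by default) and consumes
fixed-length single-lead segments shaped ``(batch, 1, input_len)``:

* **CNN** — three conv/max-pool blocks with (5, 10, 20) filters of sizes
  (3, 4, 4), then dense layers of 30, 20 and C units; leaky-ReLU throughout,
  softmax output.
* **ResNet** — a stem convolution plus four residual blocks of two size-3
  convolutions each with (64, 128, 256, 256) filters, batch-norm and dropout
  between the convolutions, a projection shortcut around every block
  (9 convolutions in the counted depth), global average pooling, softmax.
* **GRUAttNet** — five blocks of three 12-filter convolutions with lengths
  (3, 3, 24), a bidirectional GRU of 12 units per direction and an additive
  attention pooling over time.
* **RTA-CNN** — six residual temporal-attention blocks: a trunk conv stack
  modulated as ``trunk * (1 + attention)`` where the attention branch
  (downsample - conv - upsample - sigmoid) emits per-time-step weights in
  [0, 1]; per-block filter lengths (32, 16, 9, 9, 3, 3) and counts
  (16, 32, 64, 64, 64, 128); a 100-unit dense layer before the output.

Training uses Adam with early stopping on a validation metric, restoring the
best-validation parameters.  Everything runs on the in-package NumPy
autodiff engine and is bit-deterministic under a fixed seed.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nn.autodiff import (
    Tensor,
    global_avg_pool,
    fit_len,
    softmax,
    softmax_cross_entropy,
    upsample_nearest,
)
from .nn.layers import (
    AttentionPool,
    BatchNorm1d,
    BiGRU,
    Conv1d,
    Dense,
    Dropout,
    Layer,
    LeakyReLU,
    MaxPool,
)
from .nn.optim import Adam

logger = logging.getLogger(__name__)

ARCHITECTURES = ("cnn", "resnet", "gruattnet", "rtacnn", "dummy_mv")

#: Default input frequency (Hz) each architecture is tied to.
DEFAULT_INPUT_FS: dict[str, float] = {
    "cnn": 360.0,
    "resnet": 250.0,
    "gruattnet": 500.0,
    "rtacnn": 300.0,
}


@dataclass
class ModelSpec:
    architecture: str
    input_fs: float
    input_len: int
    n_classes: int
    loss: str = "cross_entropy"  # or "en_loss"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.input_len < 1 or self.n_classes < 2:
            raise ValueError("input_len >= 1 and n_classes >= 2 required")
        if self.loss not in ("cross_entropy", "en_loss"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainConfig:
    max_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_patience: int = 10
    early_stop_metric: str = "val_loss"  # or "val_macro_f1"

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("training hyperparameters must be positive")
        if self.early_stop_patience < 0:
            raise ValueError("patience must be >= 0")
        if self.early_stop_metric not in ("val_loss", "val_macro_f1"):
            raise ValueError(f"unknown metric {self.early_stop_metric!r}")


class Network:
    """Base for the architecture objects: a layer list plus forward wiring."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.layers: list[Layer] = []

    def register(self, *layers: Layer):
        self.layers.extend(layers)
        return layers if len(layers) > 1 else layers[0]

    def parameters(self) -> list[Tensor]:
        return [p for l in self.layers for p in l.params()]

    def set_train(self, mode: bool) -> None:
        for l in self.layers:
            l.set_train(mode)

    def forward(self, x: Tensor) -> Tensor:  # logits (N, C)
        raise NotImplementedError


@dataclass
class TrainedModel:
    spec: ModelSpec
    net: Optional[Network]  # None for the dummy baseline
    majority_class: Optional[int] = None
    training_history: dict[str, list[float]] = field(default_factory=dict)


def _check_pools(input_len: int, n_pools: int) -> None:
    if input_len < 2**n_pools:
        raise ValueError(
            f"input_len {input_len} too short for {n_pools} stride-2 pooling stages"
        )


# ---------------------------------------------------------------------------
# CNN
# ---------------------------------------------------------------------------


class _CNN(Network):
    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        _check_pools(spec.input_len, 3)
        rng = np.random.default_rng(spec.seed)
        self.blocks = []
        cin = 1
        for f, k in ((5, 3), (10, 4), (20, 4)):
            conv = self.register(Conv1d(cin, f, k, rng))
            self.blocks.append(conv)
            cin = f
        self.act = self.register(LeakyReLU())
        self.pool = self.register(MaxPool(2, 2))
        L = spec.input_len
        for _ in range(3):
            L = (L - 2) // 2 + 1
        self.fc1 = self.register(Dense(20 * L, 30, rng))
        self.fc2 = self.register(Dense(30, 20, rng))
        self.out = self.register(Dense(20, spec.n_classes, rng))

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.blocks:
            x = self.pool(self.act(conv(x)))
        n = x.data.shape[0]
        x = x.reshape(n, -1)
        x = self.act(self.fc1(x))
        x = self.act(self.fc2(x))
        return self.out(x)


def build_cnn(spec: ModelSpec) -> TrainedModel:
    assert spec.architecture == "cnn"
    return TrainedModel(spec, _CNN(spec))


# ---------------------------------------------------------------------------
# ResNet
# ---------------------------------------------------------------------------


class _ResBlock(Layer):
    """conv-BN-act-dropout-conv-BN with a projection shortcut (1-size conv)
    bridging any channel mismatch, then a final activation."""

    def __init__(self, cin: int, cout: int, rng, dropout: float, drop_rng):
        self.c1 = Conv1d(cin, cout, 3, rng)
        self.bn1 = BatchNorm1d(cout)
        self.drop = Dropout(dropout, drop_rng)
        self.c2 = Conv1d(cout, cout, 3, rng)
        self.bn2 = BatchNorm1d(cout)
        self.proj = Conv1d(cin, cout, 1, rng)
        self.act = LeakyReLU()

    def params(self):
        return [p for l in (self.c1, self.bn1, self.c2, self.bn2, self.proj)
                for p in l.params()]

    def set_train(self, mode: bool):
        for l in (self.bn1, self.bn2, self.drop):
            l.set_train(mode)

    def __call__(self, x: Tensor) -> Tensor:
        y = self.drop(self.act(self.bn1(self.c1(x))))
        y = self.bn2(self.c2(y))
        return self.act(y + self.proj(x))


class _ResNet(Network):
    def __init__(self, spec: ModelSpec, filters: Sequence[int], dropout: float):
        super().__init__(spec)
        _check_pools(spec.input_len, 3)
        rng = np.random.default_rng(spec.seed)
        drop_rng = np.random.default_rng(spec.seed + 1)
        self.stem = self.register(Conv1d(1, filters[0], 3, rng))
        self.blocks = []
        cin = filters[0]
        for f in filters:
            blk = _ResBlock(cin, f, rng, dropout, drop_rng)
            self.register(blk)
            self.blocks.append(blk)
            cin = f
        self.pool = self.register(MaxPool(2, 2))
        self.out = self.register(Dense(filters[-1], spec.n_classes, rng))

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem(x)
        for i, blk in enumerate(self.blocks):
            x = blk(x)
            if i < 3:  # downsample after the first three blocks
                x = self.pool(x)
        return self.out(global_avg_pool(x))

    def conv_depth(self) -> int:
        """Counted convolution depth: the stem plus two per block (the
        1-size projection shortcuts are not counted)."""
        return 1 + 2 * len(self.blocks)


def build_resnet(
    spec: ModelSpec,
    filters: Sequence[int] = (64, 128, 256, 256),
    dropout: float = 0.2,
) -> TrainedModel:
    assert spec.architecture == "resnet"
    if len(filters) != 4:
        raise ValueError("resnet takes exactly 4 per-block filter counts")
    return TrainedModel(spec, _ResNet(spec, filters, dropout))


# ---------------------------------------------------------------------------
# GRUAttNet
# ---------------------------------------------------------------------------


class _GRUAttNet(Network):
    def __init__(self, spec: ModelSpec, dropout: float):
        super().__init__(spec)
        rng = np.random.default_rng(spec.seed)
        drop_rng = np.random.default_rng(spec.seed + 1)
        self.convs: list[list[Conv1d]] = []
        cin = 1
        for _ in range(5):
            block = [
                Conv1d(cin, 12, 3, rng),
                Conv1d(12, 12, 3, rng),
                Conv1d(12, 12, 24, rng),
            ]
            for c in block:
                self.register(c)
            self.convs.append(block)
            cin = 12
        self.act = self.register(LeakyReLU())
        self.drop = self.register(Dropout(dropout, drop_rng))
        self.gru = self.register(BiGRU(12, 12, rng))
        self.attn = self.register(AttentionPool(24, 24, rng))
        self.out = self.register(Dense(24, spec.n_classes, rng))

    def forward(self, x: Tensor) -> Tensor:
        for block in self.convs:
            for conv in block:
                x = self.act(conv(x))
            x = self.drop(x)
        x = x.transpose(0, 2, 1)  # (N, T, 12)
        h = self.gru(x)
        return self.out(self.attn(h))


def build_gruattnet(spec: ModelSpec, dropout: float = 0.2) -> TrainedModel:
    assert spec.architecture == "gruattnet"
    return TrainedModel(spec, _GRUAttNet(spec, dropout))


# ---------------------------------------------------------------------------
# RTA-CNN
# ---------------------------------------------------------------------------


class _RTABlock(Layer):
    """Residual temporal-attention block.

    Trunk: two convolutions with batch-norm.  Attention branch: max-pool
    downsampling, two convolutions, nearest-neighbour upsampling back to the
    trunk length, a 1-size convolution and a sigmoid, giving per-time-step
    weights in [0, 1].  Combined as ``trunk * (1 + attention)`` so that
    zeroed attention leaves the trunk output unchanged.
    """

    def __init__(self, cin: int, f: int, k: int, rng, dropout: float, drop_rng):
        self.t1 = Conv1d(cin, f, k, rng)
        self.tb1 = BatchNorm1d(f)
        self.t2 = Conv1d(f, f, k, rng)
        self.tb2 = BatchNorm1d(f)
        self.a1 = Conv1d(cin, f, k, rng)
        self.ab1 = BatchNorm1d(f)
        self.a2 = Conv1d(f, f, k, rng)
        self.ab2 = BatchNorm1d(f)
        self.a3 = Conv1d(f, f, 1, rng)
        self.pool = MaxPool(2, 2)
        self.act = LeakyReLU()

    def _sub(self):
        return (self.t1, self.tb1, self.t2, self.tb2,
                self.a1, self.ab1, self.a2, self.ab2, self.a3)

    def params(self):
        return [p for l in self._sub() for p in l.params()]

    def set_train(self, mode: bool):
        for l in self._sub():
            l.set_train(mode)

    def attention(self, x: Tensor, target_len: int) -> Tensor:
        a = self.pool(x)
        a = self.act(self.ab1(self.a1(a)))
        a = self.act(self.ab2(self.a2(a)))
        a = fit_len(upsample_nearest(a, 2), target_len)
        return self.a3(a).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        t = self.act(self.tb1(self.t1(x)))
        t = self.tb2(self.t2(t))
        att = self.attention(x, t.data.shape[2])
        return self.act(t * (att + 1.0))


class _RTACNN(Network):
    FILTERS = (16, 32, 64, 64, 64, 128)
    KLENS = (32, 16, 9, 9, 3, 3)

    def __init__(self, spec: ModelSpec, dropout: float,
                 filters: Sequence[int], klens: Sequence[int]):
        super().__init__(spec)
        _check_pools(spec.input_len, len(filters) + 1)
        rng = np.random.default_rng(spec.seed)
        drop_rng = np.random.default_rng(spec.seed + 1)
        self.blocks: list[_RTABlock] = []
        cin = 1
        for f, k in zip(filters, klens):
            blk = _RTABlock(cin, f, k, rng, dropout, drop_rng)
            self.register(blk)
            self.blocks.append(blk)
            cin = f
        self.pool = self.register(MaxPool(2, 2))
        self.drop = self.register(Dropout(dropout, drop_rng))
        L = spec.input_len
        for _ in range(len(filters)):
            L = (L - 2) // 2 + 1
        self.fc = self.register(Dense(filters[-1] * L, 100, rng))
        self.act = self.register(LeakyReLU())
        self.out = self.register(Dense(100, spec.n_classes, rng))

    def forward(self, x: Tensor) -> Tensor:
        for blk in self.blocks:
            x = self.drop(self.pool(blk(x)))
        n = x.data.shape[0]
        x = self.act(self.fc(x.reshape(n, -1)))
        return self.out(x)


def build_rtacnn(
    spec: ModelSpec,
    dropout: float = 0.2,
    filters: Sequence[int] = _RTACNN.FILTERS,
    klens: Sequence[int] = _RTACNN.KLENS,
) -> TrainedModel:
    assert spec.architecture == "rtacnn"
    return TrainedModel(spec, _RTACNN(spec, dropout, filters, klens))


def build_model(spec: ModelSpec, **kwargs) -> TrainedModel:
    builder = {
        "cnn": build_cnn, "resnet": build_resnet,
        "gruattnet": build_gruattnet, "rtacnn": build_rtacnn,
    }[spec.architecture]
    return builder(spec, **kwargs)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def en_loss(probabilities: Tensor, labels: np.ndarray, beta: float = 1.0) -> Tensor:
    """Exponential-nonlinearity loss on probability rows.

    A monotone transform of -log p_true that up-weights hard examples:
    ``mean(exp(beta * (1 - p_true)) * (-log p_true))``.  Zero when every
    true-class probability is 1; the true-class probability is clamped at
    1e-7 before the log.
    """
    n, C = probabilities.data.shape
    onehot = np.zeros((n, C))
    onehot[np.arange(n), labels] = 1.0
    p_true = (probabilities * Tensor(onehot)).sum(axis=1).clip_min(1e-7)
    weight = (Tensor(np.full(n, beta)) * (1.0 - p_true)).exp()
    return (weight * (-p_true.log())).mean()


def _loss(net_logits: Tensor, labels: np.ndarray, kind: str) -> Tensor:
    if kind == "cross_entropy":
        return softmax_cross_entropy(net_logits, labels)
    return en_loss(softmax(net_logits, axis=1), labels)


# ---------------------------------------------------------------------------
# Baseline, training, prediction
# ---------------------------------------------------------------------------


def dummy_majority(train_labels: Sequence[int], n_classes: Optional[int] = None) -> TrainedModel:
    """Baseline that always predicts the majority training class (ties go to
    the lowest class index)."""
    y = np.asarray(train_labels, dtype=int)
    if y.size == 0:
        raise ValueError("empty training labels")
    C = n_classes or int(y.max()) + 1
    counts = np.bincount(y, minlength=C)
    maj = int(np.flatnonzero(counts == counts.max()).min())
    spec = ModelSpec("dummy_mv", input_fs=1.0, input_len=1, n_classes=C)
    return TrainedModel(spec, net=None, majority_class=maj)


def _to_xy(segments, input_len: Optional[int] = None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(segments, tuple):
        X, y = segments
        return np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    X = np.stack([s.samples for s in segments])
    y = np.array([s.label for s in segments], dtype=int)
    return X, y


def _forward_logits(net: Network, X: np.ndarray) -> np.ndarray:
    return net.forward(Tensor(X[:, None, :])).data


def _batched_eval_loss(net: Network, X, y, kind: str, batch: int = 256) -> float:
    tot, n = 0.0, X.shape[0]
    for i in range(0, n, batch):
        xb, yb = X[i : i + batch], y[i : i + batch]
        loss = _loss(net.forward(Tensor(xb[:, None, :])), yb, kind)
        tot += float(loss.data) * xb.shape[0]
    return tot / n


def train(
    model: TrainedModel,
    train_segments,
    val_segments,
    cfg: TrainConfig,
) -> TrainedModel:
    """Minimize the spec loss with Adam; early-stop when the validation
    metric fails to improve for ``early_stop_patience`` epochs and restore
    the best-validation parameters.  Segments must already be resampled and
    length-fitted to the model's input contract.
    """
    from .metrics import compute_metrics  # local import to avoid a cycle

    net = model.net
    if net is None:
        raise ValueError("the dummy baseline has no training phase")
    Xtr, ytr = _to_xy(train_segments)
    Xva, yva = _to_xy(val_segments)
    if Xtr.shape[0] == 0:
        raise ValueError("empty training set")
    present = np.unique(ytr)
    if present.size < model.spec.n_classes:
        logger.warning(
            "classes %s absent from the training set",
            sorted(set(range(model.spec.n_classes)) - set(present.tolist())),
        )
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(model.spec.seed + 12345)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "val_macro_f1": []}
    maximize = cfg.early_stop_metric == "val_macro_f1"
    best = -np.inf if maximize else np.inf
    best_params = None
    bad_epochs = 0
    for epoch in range(cfg.max_epochs):
        net.set_train(True)
        perm = rng.permutation(Xtr.shape[0])
        ep_loss, nb = 0.0, 0
        for i in range(0, perm.size, cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            opt.zero_grad()
            loss = _loss(net.forward(Tensor(Xtr[idx][:, None, :])), ytr[idx],
                         model.spec.loss)
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            nb += 1
        net.set_train(False)
        val_loss = _batched_eval_loss(net, Xva, yva, model.spec.loss)
        probs = _predict_probs(model, Xva)
        f1 = compute_metrics(yva, probs.argmax(axis=1), model.spec.n_classes).macro_f1
        history["train_loss"].append(ep_loss / max(nb, 1))
        history["val_loss"].append(val_loss)
        history["val_macro_f1"].append(f1)
        current = f1 if maximize else val_loss
        improved = current > best if maximize else current < best
        logger.info("epoch %d: train_loss=%.4f val_loss=%.4f val_macro_f1=%.4f",
                    epoch, history["train_loss"][-1], val_loss, f1)
        if improved:
            best = current
            best_params = [p.data.copy() for p in net.parameters()]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.early_stop_patience:
                break
    if best_params is not None:
        for p, d in zip(net.parameters(), best_params):
            p.data = d
    model.training_history = history
    return model


def _predict_probs(model: TrainedModel, X: np.ndarray, batch: int = 256) -> np.ndarray:
    if model.net is None:
        probs = np.zeros((X.shape[0], model.spec.n_classes))
        probs[:, model.majority_class] = 1.0
        return probs
    if X.shape[1] != model.spec.input_len:
        raise ValueError(
            f"segment length {X.shape[1]} != model input_len {model.spec.input_len}"
        )
    model.net.set_train(False)
    out = []
    for i in range(0, X.shape[0], batch):
        logits = _forward_logits(model.net, X[i : i + batch])
        out.append(softmax(Tensor(logits), axis=1).data)
    return np.concatenate(out, axis=0)


def predict(model: TrainedModel, segments) -> tuple[np.ndarray, np.ndarray]:
    """Probability rows on the class simplex plus argmax labels (ties to the
    lowest index)."""
    X, _ = _to_xy(segments)
    probs = _predict_probs(model, X)
    return probs, probs.argmax(axis=1)
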