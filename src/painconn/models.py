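"""Connectome convolutional classifiers in plain numpy.

Three binary classifiers over N x N connectivity matrices:

``ann4brains``
    The connectome-CNN filter stack: an edge-to-edge (E2E) bank whose filters
    have cross-shaped support (one row plus one column of the adjacency
    matrix), an edge-to-node (E2N) bank reducing each node's row of edges to
    a scalar per filter, a node-to-graph (N2G) bank reducing the node vector
    to graph-level units, and three fully connected layers ending in a
    2-class softmax.  Dropout sits between the fully connected layers.

``ann4brains_batch``
    The same stack with batch-normalization layers inserted after each
    connectome filter bank.

``conv1d_net``
    Two one-dimensional convolutional layers over the row-stacked matrix
    (each of the N rows is a length-N channel; the first layer's kernels span
    the full row length), followed by one fully connected layer and a 2-way
    softmax head.

Forward *and* backward passes are written out explicitly (einsum), which
keeps every filter's semantics inspectable and makes the small problem sizes
here train in seconds on one CPU.  Training is plain SGD with momentum,
cross-entropy loss plus optional L1/L2 weight penalties (a zero coefficient
deactivates the penalty), and early stopping on validation loss.

The functional primitives :func:`e2e_forward`, :func:`e2n_forward` and
:func:`n2g_forward` expose the single-filter math directly; the layer classes
apply the same formulas over filter banks and batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARCHITECTURES = ("ann4brains", "ann4brains_batch", "conv1d_net")


# ---------------------------------------------------------------------------
# Single-filter functional primitives


def e2e_forward(a: np.ndarray, row_weights: np.ndarray,
                col_weights: np.ndarray) -> np.ndarray:
    """Edge-to-edge response: out(i,j) = sum_k r(k) a(i,k) + sum_k c(k) a(k,j)."""
    a = np.asarray(a, dtype=float)
    r = np.asarray(row_weights, dtype=float)
    c = np.asarray(col_weights, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n) or r.shape != (n,) or c.shape != (n,):
        raise ValueError("e2e: need square a and length-N row/col weights")
    u = a @ r  # row responses, constant along j
    v = a.T @ c  # column responses, constant along i
    return u[:, None] + v[None, :]


def e2n_forward(a: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Edge-to-node response: out(i) = sum_k w(k) a(i,k)."""
    a = np.asarray(a, dtype=float)
    w = np.asarray(weights, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or w.shape != (a.shape[0],):
        raise ValueError("e2n: need square a and length-N weights")
    return a @ w


def n2g_forward(v: np.ndarray, weights: np.ndarray) -> float:
    """Node-to-graph response: a weighted combination of the node vector."""
    v = np.asarray(v, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("n2g: need equal-length vectors")
    return float(v @ w)


# ---------------------------------------------------------------------------
# Layers


class Param:
    __slots__ = ("value", "grad", "penalize")

    def __init__(self, value: np.ndarray, penalize: bool):
        self.value = value
        self.grad = np.zeros_like(value)
        self.penalize = penalize  # weight penalties never touch biases/BN


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class E2EBank(Layer):
    """F edge-to-edge filters over a single-channel N x N input."""

    def __init__(self, n: int, filters: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(2 * n)
        self.R = Param(rng.normal(0, s, (filters, n)), True)
        self.C = Param(rng.normal(0, s, (filters, n)), True)
        self.b = Param(np.zeros(filters), False)

    def params(self):
        return [self.R, self.C, self.b]

    def forward(self, x, training):
        self.x = x  # (B, N, N)
        u = np.einsum("bik,fk->bfi", x, self.R.value, optimize=True)
        v = np.einsum("bkj,fk->bfj", x, self.C.value, optimize=True)
        return u[:, :, :, None] + v[:, :, None, :] + self.b.value[None, :, None, None]

    def backward(self, g):
        du = g.sum(axis=3)
        dv = g.sum(axis=2)
        self.R.grad = np.einsum("bfi,bik->fk", du, self.x, optimize=True)
        self.C.grad = np.einsum("bfj,bkj->fk", dv, self.x, optimize=True)
        self.b.grad = g.sum(axis=(0, 2, 3))
        return (np.einsum("bfi,fk->bik", du, self.R.value, optimize=True)
                + np.einsum("bfj,fk->bkj", dv, self.C.value, optimize=True))


class E2NBank(Layer):
    """F edge-to-node filters over C channels of N x N maps -> (B, F, N)."""

    def __init__(self, n: int, in_channels: int, filters: int,
                 rng: np.random.Generator):
        s = 1.0 / np.sqrt(in_channels * n)
        self.W = Param(rng.normal(0, s, (filters, in_channels, n)), True)
        self.b = Param(np.zeros(filters), False)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self.x = x  # (B, C, N, N)
        return (np.einsum("bcik,fck->bfi", x, self.W.value, optimize=True)
                + self.b.value[None, :, None])

    def backward(self, g):
        self.W.grad = np.einsum("bfi,bcik->fck", g, self.x, optimize=True)
        self.b.grad = g.sum(axis=(0, 2))
        return np.einsum("bfi,fck->bcik", g, self.W.value, optimize=True)


class FullKernelConv(Layer):
    """Kernels spanning the whole spatial extent: (B, C, L) -> (B, F).

    Used both as the node-to-graph bank (nodes -> graph units) and as the
    first full-row 1-D convolution of ``conv1d_net``.
    """

    def __init__(self, length: int, in_channels: int, filters: int,
                 rng: np.random.Generator):
        s = 1.0 / np.sqrt(in_channels * length)
        self.W = Param(rng.normal(0, s, (filters, in_channels, length)), True)
        self.b = Param(np.zeros(filters), False)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self.x = x
        return np.einsum("bcl,fcl->bf", x, self.W.value, optimize=True) + self.b.value[None, :]

    def backward(self, g):
        self.W.grad = np.einsum("bf,bcl->fcl", g, self.x, optimize=True)
        self.b.grad = g.sum(axis=0)
        return np.einsum("bf,fcl->bcl", g, self.W.value, optimize=True)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        s = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0, s, (n_out, n_in)), True)
        self.b = Param(np.zeros(n_out), False)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self.x = x
        return x @ self.W.value.T + self.b.value[None, :]

    def backward(self, g):
        self.W.grad = g.T @ self.x
        self.b.grad = g.sum(axis=0)
        return g @ self.W.value


class LeakyReLU(Layer):
    """Leaky rectifier; negative slope 1/3 follows the connectome-CNN habit."""

    def __init__(self, slope: float = 1.0 / 3.0):
        self.slope = slope

    def forward(self, x, training):
        self.mask = x >= 0
        return np.where(self.mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self.mask, g, self.slope * g)


class Dropout(Layer):
    """Inverted dropout; a no-op at rate 0 and in inference mode."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, training):
        if not training or self.rate == 0:
            self.mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without an rng")
        self.mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self.mask

    def backward(self, g):
        return g if self.mask is None else g * self.mask


class BatchNorm(Layer):
    """Per-channel batch normalization (channel axis 1), running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels), False)
        self.beta = Param(np.zeros(channels), False)
        self.momentum = momentum
        self.eps = eps
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        shape = [1] * x.ndim
        shape[1] = -1
        return shape

    def forward(self, x, training):
        axes = tuple(i for i in range(x.ndim) if i != 1)
        shp = self._shape(x)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mu
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mu, var = self.run_mean, self.run_var
        self.axes, self.n = axes, x.size // x.shape[1]
        self.istd = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mu.reshape(shp)) * self.istd.reshape(shp)
        return self.gamma.value.reshape(shp) * self.xhat + self.beta.value.reshape(shp)

    def backward(self, g):
        shp = self._shape(g)
        self.gamma.grad = (g * self.xhat).sum(axis=self.axes)
        self.beta.grad = g.sum(axis=self.axes)
        gg = g * self.gamma.value.reshape(shp)
        mean_gg = gg.mean(axis=self.axes).reshape(shp)
        mean_ggx = (gg * self.xhat).mean(axis=self.axes).reshape(shp)
        return self.istd.reshape(shp) * (gg - mean_gg - self.xhat * mean_ggx)


class Identity2D(Layer):
    """Pass-through marking (B, N, N) input as N channels of length N."""

    def forward(self, x, training):
        return x

    def backward(self, g):
        return g


# ---------------------------------------------------------------------------
# Architecture specification and assembly


@dataclass(frozen=True)
class ArchitectureSpec:
    """One architecture plus its regularization/optimization hyper-parameters.

    The standard grid draws dropout in {0, 0.3, 0.5, 0.8}, L1/L2 lambda in
    {0, 0.1, 0.01} and learning rate in {0.1, 0.01, 0.001}; other values are
    accepted for exploration.
    """

    name: str
    n_regions: int
    e2e_filters: int = 32
    e2n_filters: int = 64
    n2g_units: int = 128
    fc_sizes: tuple = (128, 30, 2)
    conv1d_filters: tuple = (64, 64)
    conv1d_fc: int = 96
    dropout: float = 0.0
    l1_lambda: float = 0.0
    l2_lambda: float = 0.0
    learning_rate: float = 0.01
    batch_norm: bool = False
    leaky_slope: float = 1.0 / 3.0

    def validate(self) -> None:
        if self.name not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.name!r}")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.l1_lambda < 0 or self.l2_lambda < 0 or self.learning_rate <= 0:
            raise ValueError("invalid regularization or learning rate")
        if len(self.fc_sizes) != 3 or self.fc_sizes[-1] != 2:
            raise ValueError("fc_sizes must be three sizes ending in the 2-way head")


class Network:
    """A feed-forward stack with a softmax cross-entropy head."""

    def __init__(self, layers: list, spec: ArchitectureSpec):
        self.layers = layers
        self.spec = spec

    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params()]

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class logits for a batch of N x N matrices."""
        h = np.asarray(x, dtype=float)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None, :, :]
        logits = self.forward(x, training=False)
        return _softmax(logits)

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on the batch; fills every parameter's grad."""
        logits = self.forward(x, training=True)
        probs = _softmax(logits)
        n = len(y)
        ce = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
        g = probs.copy()
        g[np.arange(n), y] -= 1.0
        g /= n
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return float(ce)

    def penalty(self) -> float:
        l1, l2 = self.spec.l1_lambda, self.spec.l2_lambda
        total = 0.0
        for p in self.params():
            if p.penalize:
                if l1:
                    total += l1 * np.abs(p.value).sum()
                if l2:
                    total += l2 * np.square(p.value).sum()
        return float(total)

    def weight_l1(self) -> float:
        return float(sum(np.abs(p.value).sum() for p in self.params() if p.penalize))

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_state(self) -> list:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_architecture(spec: ArchitectureSpec, seed: int = 0) -> Network:
    """Assemble an untrained network for ``spec`` with seeded initialization."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = spec.n_regions
    act = lambda: LeakyReLU(spec.leaky_slope)  # noqa: E731
    layers: list[Layer] = []
    if spec.name in ("ann4brains", "ann4brains_batch"):
        bn = spec.name == "ann4brains_batch"
        # E2EBank consumes the single-channel (B, N, N) input directly
        layers.append(E2EBank(n, spec.e2e_filters, rng))
        if bn:
            layers.append(BatchNorm(spec.e2e_filters))
        layers.append(act())
        layers.append(E2NBank(n, spec.e2e_filters, spec.e2n_filters, rng))
        if bn:
            layers.append(BatchNorm(spec.e2n_filters))
        layers.append(act())
        layers.append(FullKernelConv(n, spec.e2n_filters, spec.n2g_units, rng))
        if bn:
            layers.append(BatchNorm(spec.n2g_units))
        layers.append(act())
        sizes = (spec.n2g_units,) + tuple(spec.fc_sizes)
        for k in range(3):
            layers.append(Dropout(spec.dropout))
            layers.append(Dense(sizes[k], sizes[k + 1], rng))
            if k < 2:
                layers.append(act())
    else:  # conv1d_net
        layers.append(Identity2D())  # rows of the matrix are the N channels
        layers.append(FullKernelConv(n, n, spec.conv1d_filters[0], rng))
        layers.append(act())
        layers.append(Dense(spec.conv1d_filters[0], spec.conv1d_filters[1], rng))
        layers.append(act())
        layers.append(Dense(spec.conv1d_filters[1], spec.conv1d_fc, rng))
        layers.append(act())
        layers.append(Dropout(spec.dropout))
        layers.append(Dense(spec.conv1d_fc, 2, rng))
    return Network(layers, spec)


def expected_parameter_count(spec: ArchitectureSpec) -> int:
    """Closed-form parameter count for a given spec (weights + biases + BN)."""
    n = spec.n_regions
    if spec.name in ("ann4brains", "ann4brains_batch"):
        total = spec.e2e_filters * (2 * n + 1)
        total += spec.e2n_filters * (spec.e2e_filters * n + 1)
        total += spec.n2g_units * (spec.e2n_filters * n + 1)
        sizes = (spec.n2g_units,) + tuple(spec.fc_sizes)
        for k in range(3):
            total += sizes[k + 1] * (sizes[k] + 1)
        if spec.name == "ann4brains_batch":
            total += 2 * (spec.e2e_filters + spec.e2n_filters + spec.n2g_units)
        return total
    f1, f2 = spec.conv1d_filters
    total = f1 * (n * n + 1)
    total += f2 * (f1 + 1)
    total += spec.conv1d_fc * (f2 + 1)
    total += 2 * (spec.conv1d_fc + 1)
    return total


# ---------------------------------------------------------------------------
# Training


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    momentum: float = 0.9
    patience: int = 10


@dataclass
class TrainedModel:
    network: Network
    spec: ArchitectureSpec
    history: list = field(default_factory=list)
    seed: int = 0

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return predict_proba(self, features)


def train_model(model: Network, train_x, train_y, val_x, val_y,
                spec: ArchitectureSpec | None = None,
                train_cfg: TrainConfig | None = None,
                seed: int = 0) -> TrainedModel:
    """SGD-with-momentum training with early stopping on validation loss.

    The objective is mean cross-entropy plus ``l1 * sum|w| + l2 * sum w^2``
    over the weight matrices (biases and normalization parameters are not
    penalized; a zero lambda deactivates its penalty).  Per-epoch training
    objective and validation cross-entropy are recorded; the parameters of
    the best validation epoch are restored at the end.
    """
    spec = spec or model.spec
    cfg = train_cfg or TrainConfig()
    train_x = np.asarray(train_x, dtype=float)
    val_x = np.asarray(val_x, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    val_y = np.asarray(val_y, dtype=int)
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("train and validation sets must be non-empty")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    model.set_dropout_rng(rng)
    params = model.params()
    velocity = [np.zeros_like(p.value) for p in params]
    l1, l2, lr = spec.l1_lambda, spec.l2_lambda, spec.learning_rate

    history: list[dict] = []
    best_val = np.inf
    best_state = model.get_state()
    stale = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_x))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            with np.errstate(over="ignore", invalid="ignore"):
                ce = model.loss_and_backward(train_x[idx], train_y[idx])
            if not np.isfinite(ce):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {ce!r} "
                    f"(learning rate {lr}, spec {spec.name})"
                )
            for p, v in zip(params, velocity):
                g = p.grad
                if p.penalize and (l1 or l2):
                    g = g + l1 * np.sign(p.value) + 2.0 * l2 * p.value
                v *= cfg.momentum
                v -= lr * g
                p.value += v
            epoch_loss += ce
            n_batches += 1
        val_loss = _mean_ce(model, val_x, val_y)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1) + model.penalty(),
            "val_loss": val_loss,
        })
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = model.get_state()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.set_state(best_state)
    return TrainedModel(network=model, spec=spec, history=history, seed=seed)


def _mean_ce(model: Network, x: np.ndarray, y: np.ndarray,
             batch: int = 256) -> float:
    total = 0.0
    for start in range(0, len(x), batch):
        probs = _softmax(model.forward(x[start:start + batch], training=False))
        sel = probs[np.arange(len(probs)), y[start:start + batch]]
        total += -np.log(np.clip(sel, 1e-12, None)).sum()
    return float(total / len(x))


def predict_proba(model: TrainedModel | Network, features: np.ndarray) -> np.ndarray:
    """Per-instance class probabilities (rows sum to 1; dropout off)."""
    net = model.network if isinstance(model, TrainedModel) else model
    x = np.asarray(features, dtype=float)
    if x.ndim == 2:
        x = x[None, :, :]
    n = net.spec.n_regions
    if x.shape[1:] != (n, n):
        raise ValueError(f"expected inputs of shape (*, {n}, {n}), got {x.shape}")
    return net.predict_proba(x)
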