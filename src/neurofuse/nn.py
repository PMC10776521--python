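"""Minimal dense neural-network core with manual backpropagation.

Implements exactly the pieces the joint-fusion classifier needs — fully
connected layers, batch normalization, ReLU, inverted dropout, SGD with
momentum, binary cross-entropy on a single logistic output and an L1 penalty
on designated weight matrices — plus gradients of the model output with
respect to its inputs, which drive the expected-gradients attribution.
Everything is NumPy; training is deterministic given the generator passed in.
"""

from __future__ import annotations

import numpy as np

#: single precision throughout the network: ample for SGD training and
#: roughly twice the matmul throughput of float64 on one CPU core
DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "vel")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.vel = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He initialization for ReLU stacks
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy, accumulate=True):
        if accumulate:
            self.W.grad += self._x.T @ dy
            self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class BatchNorm(Layer):
    """Batch normalization with running statistics for inference."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train, rng):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            inv_sd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * inv_sd
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._cache = ("train", xhat, inv_sd)
        else:
            inv_sd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_sd
            self._cache = ("eval", xhat, inv_sd)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy, accumulate=True):
        mode, xhat, inv_sd = self._cache
        if accumulate:
            self.gamma.grad += (dy * xhat).sum(axis=0)
            self.beta.grad += dy.sum(axis=0)
        dxhat = dy * self.gamma.value
        if mode == "eval":
            return dxhat * inv_sd
        n = dy.shape[0]
        return (inv_sd / n) * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy, accumulate=True):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout: identity at inference."""

    def __init__(self, p: float):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, train, rng):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy, accumulate=True):
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train, rng):
        for l in self.layers:
            x = l.forward(x, train, rng)
        return x

    def backward(self, dy, accumulate=True):
        for l in reversed(self.layers):
            dy = l.backward(dy, accumulate)
        return dy


# ---------------------------------------------------------------------------
# the joint-fusion network


def _mlp_block(n_in: int, widths: list[int], rng) -> Sequential:
    layers: list[Layer] = []
    for w in widths:
        layers += [Dense(n_in, w, rng), BatchNorm(w), ReLU()]
        n_in = w
    return Sequential(layers)


class JointFusionNet:
    """Per-modality feature-reduction subnetworks feeding a fused classifier.

    Each modality block passes through its own reduction network (FR-NN) to a
    fixed-length embedding; embeddings are concatenated and classified by a
    shared head (C-NN) ending in a single logistic unit.  With one modality
    the same architecture degrades gracefully to a single-input model.
    Training backpropagates the classification loss through the reduction
    networks, so the embeddings are learned jointly with the classifier.
    """

    def __init__(
        self,
        input_dims: list[int],
        frnn_widths: list[list[int]],
        cnn_widths: list[int],
        dropout: tuple[float, float] = (0.5, 0.2),
        seed: int = 0,
    ):
        if len(input_dims) != len(frnn_widths) or not input_dims:
            raise ValueError("need one FR-NN width list per modality")
        rng = np.random.default_rng(seed)
        self.frnns = [_mlp_block(d, w, rng) for d, w in zip(input_dims, frnn_widths)]
        merged = sum(w[-1] for w in frnn_widths)
        head: list[Layer] = []
        n_in = merged
        for k, w in enumerate(cnn_widths):
            head += [Dense(n_in, w, rng), BatchNorm(w), ReLU()]
            if k < len(dropout):
                head.append(Dropout(dropout[k]))
            n_in = w
        head.append(Dense(n_in, 1, rng))
        self.head = Sequential(head)
        self._embed_dims = [w[-1] for w in frnn_widths]
        self.input_dims = list(input_dims)

    # --- parameter plumbing

    def params(self) -> list[Param]:
        return [p for f in self.frnns for p in f.params()] + self.head.params()

    def l1_params(self) -> list[Param]:
        """Weight matrices of each FR-NN's first layer (sparsity target)."""
        out = []
        for f in self.frnns:
            first = f.layers[0]
            assert isinstance(first, Dense)
            out.append(first.W)
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[:] = 0

    # --- forward / backward

    def forward(self, blocks: list[np.ndarray], train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if len(blocks) != len(self.frnns):
            raise ValueError("wrong number of modality blocks")
        blocks = [np.asarray(x, dtype=DTYPE) for x in blocks]
        embeds = [f.forward(x, train, rng) for f, x in zip(self.frnns, blocks)]
        z = np.concatenate(embeds, axis=1)
        return self.head.forward(z, train, rng)[:, 0]  # logits

    def backward(self, dlogit: np.ndarray, accumulate: bool = True) -> list[np.ndarray]:
        dz = self.head.backward(dlogit[:, None], accumulate)
        dxs = []
        lo = 0
        for f, w in zip(self.frnns, self._embed_dims):
            dxs.append(f.backward(dz[:, lo:lo + w], accumulate))
            lo += w
        return dxs

    def predict_proba(self, blocks: list[np.ndarray]) -> np.ndarray:
        return sigmoid(self.forward(blocks, train=False))

    def input_gradients(self, blocks: list[np.ndarray]) -> list[np.ndarray]:
        """d p / d x at inference (running-statistics) mode, per modality."""
        logits = self.forward(blocks, train=False)
        p = sigmoid(logits)
        return self.backward((p * (1 - p)).astype(DTYPE), accumulate=False)


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    n = len(y)
    loss = np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits))))
    grad = (sigmoid(logits) - y) / n
    return float(loss), grad


def train(
    net: JointFusionNet,
    blocks: list[np.ndarray],
    y: np.ndarray,
    epochs: int = 150,
    batch_size: int = 64,
    lr: float = 0.001,
    momentum: float = 0.9,
    l1: float = 0.01,
    seed: int = 0,
    freeze_frnn: bool = False,
) -> list[float]:
    """SGD-with-momentum training loop; returns the per-epoch mean loss.

    ``freeze_frnn`` stops parameter updates in the reduction networks (an
    ablation that removes the joint co-learning of the embeddings).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if any(b.shape[0] != n for b in blocks):
        raise ValueError("blocks and labels are not row-aligned")
    rng = np.random.default_rng(seed)
    frozen = set(map(id, [p for f in net.frnns for p in f.params()])) if freeze_frnn else set()
    l1_ids = set(map(id, net.l1_params()))
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if len(idx) < 2:  # batch norm needs batch statistics
                continue
            net.zero_grad()
            logits = net.forward([b[idx] for b in blocks], train=True, rng=rng)
            loss, dlogit = bce_with_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    "NaN/inf training loss; check feature scaling and learning rate "
                    f"(lr={lr}, input scale max={max(np.abs(b).max() for b in blocks):.3g})"
                )
            net.backward(dlogit.astype(DTYPE))
            for p in net.params():
                if id(p) in frozen:
                    continue
                g = p.grad
                if l1 and id(p) in l1_ids:
                    g = g + l1 * np.sign(p.value)
                p.vel = momentum * p.vel - lr * g
                p.value += p.vel
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    return history
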