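"""Weighted convolutional neural network for two-class expression profiles.

The classifier prepends a learnable per-gene weight vector (a 1x1 "weighted
convolution") to a small conv/pool/dense/softmax stack. The gene vector is
multiplied entrywise by the weights, embedded row-major into a near-square 2D
grid (zero-padded), and passed through:

    5x5 conv -> ReLU -> 2x2 max pool -> 5x5 conv -> ReLU -> 2x2 max pool
    -> 1x1 conv -> ReLU -> (1x1 pool = identity) -> dense hidden (ReLU)
    -> dense 2 -> softmax

All forward and backward passes are exact analytic numpy implementations
(verified against central finite differences in the test suite); training is
plain mini-batch SGD on mean cross-entropy. Max pooling keeps a trailing
partial block (ceil division), which makes a 13x13 grid — 169 genes — the
smallest input the two 5x5 stages accept.

The per-gene weights start at 1 so the weighted stage is initially the
identity and the network is a strict generalization of a plain CNN; they are
trained jointly with every other parameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import ExpressionDataset
from .errors import ValidationError

__all__ = [
    "GeneGrid",
    "WCNNConfig",
    "WCNNModel",
    "grid_embed",
    "grid_unembed",
    "weighted_input_forward",
    "weighted_input_backward",
    "conv_forward",
    "conv_backward",
    "maxpool_forward",
    "maxpool_backward",
    "dense_softmax_forward",
    "softmax",
    "train",
    "predict",
]

MIN_GENES = 169  # 13x13 grid: smallest input for two 5x5 convs with 2x2 ceil-pooling


# ---------------------------------------------------------------------------
# Grid embedding
# ---------------------------------------------------------------------------

@dataclass
class GeneGrid:
    """Row-major embedding of a length-G gene vector into a near-square grid."""

    n_genes: int
    height: int
    width: int

    @classmethod
    def for_genes(cls, n_genes: int) -> "GeneGrid":
        if n_genes < 1:
            raise ValidationError("need at least one gene")
        height = math.ceil(math.sqrt(n_genes))
        width = math.ceil(n_genes / height)
        return cls(n_genes=n_genes, height=height, width=width)

    @property
    def pad_count(self) -> int:
        return self.height * self.width - self.n_genes


def grid_embed(x: np.ndarray, grid: GeneGrid) -> np.ndarray:
    """Embed vectors (..., G) as (..., 1, H, W) maps; padded cells are 0."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != grid.n_genes:
        raise ValidationError(
            f"vector length {x.shape[-1]} does not match grid gene count {grid.n_genes}"
        )
    pad = [(0, 0)] * (x.ndim - 1) + [(0, grid.pad_count)]
    padded = np.pad(x, pad)
    return padded.reshape(*x.shape[:-1], 1, grid.height, grid.width)


def grid_unembed(maps: np.ndarray, grid: GeneGrid) -> np.ndarray:
    """Inverse of :func:`grid_embed`: recover the (..., G) gene vectors."""
    flat = np.asarray(maps).reshape(*maps.shape[:-3], grid.height * grid.width)
    return flat[..., : grid.n_genes]


# ---------------------------------------------------------------------------
# Layer primitives (forward + backward)
# ---------------------------------------------------------------------------

def weighted_input_forward(x: np.ndarray, gene_weights: np.ndarray) -> np.ndarray:
    """Entrywise product of the gene vector(s) with the learnable weights."""
    x = np.asarray(x, dtype=float)
    gene_weights = np.asarray(gene_weights, dtype=float)
    if x.shape[-1] != gene_weights.shape[0]:
        raise ValidationError("gene_weights length does not match input length")
    return x * gene_weights


def weighted_input_backward(
    x: np.ndarray, gene_weights: np.ndarray, upstream: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the weighted stage: (d/dx, d/dweights)."""
    x = np.asarray(x, dtype=float)
    upstream = np.asarray(upstream, dtype=float)
    if upstream.shape != x.shape:
        raise ValidationError("upstream gradient shape does not match input")
    grad_x = upstream * gene_weights
    grad_w = (upstream * x).reshape(-1, x.shape[-1]).sum(axis=0)
    return grad_x, grad_w


def conv_forward(inputs: np.ndarray, kernels: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Valid (no-padding) cross-correlation over channel stacks.

    inputs: (B, C_in, H, W); kernels: (C_out, C_in, kh, kw); biases: (C_out,).
    Returns pre-activation maps (B, C_out, H-kh+1, W-kw+1).
    """
    b, c_in, h, w = inputs.shape
    c_out, c_in_k, kh, kw = kernels.shape
    if c_in_k != c_in:
        raise ValidationError("kernel channel count does not match input")
    if kh > h or kw > w:
        raise ValidationError(f"kernel {kh}x{kw} larger than input {h}x{w}")
    ho, wo = h - kh + 1, w - kw + 1
    out = np.zeros((b, c_out, ho, wo))
    for dy in range(kh):
        for dx in range(kw):
            patch = inputs[:, :, dy : dy + ho, dx : dx + wo]
            out += np.einsum("bchw,oc->bohw", patch, kernels[:, :, dy, dx])
    return out + biases[None, :, None, None]


def conv_backward(
    inputs: np.ndarray, kernels: np.ndarray, upstream: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of :func:`conv_forward` w.r.t. (inputs, kernels, biases)."""
    _, _, kh, kw = kernels.shape
    ho, wo = upstream.shape[2], upstream.shape[3]
    grad_in = np.zeros_like(inputs)
    grad_k = np.zeros_like(kernels)
    for dy in range(kh):
        for dx in range(kw):
            patch = inputs[:, :, dy : dy + ho, dx : dx + wo]
            grad_k[:, :, dy, dx] = np.einsum("bohw,bchw->oc", upstream, patch)
            grad_in[:, :, dy : dy + ho, dx : dx + wo] += np.einsum(
                "bohw,oc->bchw", upstream, kernels[:, :, dy, dx]
            )
    grad_b = upstream.sum(axis=(0, 2, 3))
    return grad_in, grad_k, grad_b


def _pool_blocks(maps: np.ndarray, pool: int) -> np.ndarray:
    """Stack each pool x pool block (padding partial blocks with -inf) on a new axis."""
    b, c, h, w = maps.shape
    ho, wo = math.ceil(h / pool), math.ceil(w / pool)
    padded = np.full((b, c, ho * pool, wo * pool), -np.inf)
    padded[:, :, :h, :w] = maps
    blocks = padded.reshape(b, c, ho, pool, wo, pool)
    return blocks.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, pool * pool)


def maxpool_forward(maps: np.ndarray, pool: int) -> tuple[np.ndarray, np.ndarray]:
    """Blockwise maximum with ceil division (partial trailing blocks kept).

    Returns (pooled maps, argmax indices for gradient routing). A 1x1 pool is
    the identity.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.size == 0:
        raise ValidationError("cannot pool an empty map")
    if pool == 1:
        return maps, np.zeros(maps.shape, dtype=np.int64)
    blocks = _pool_blocks(maps, pool)
    arg = blocks.argmax(axis=-1)  # first maximum wins on ties
    out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
    return out, arg


def maxpool_backward(
    upstream: np.ndarray, arg: np.ndarray, in_shape: tuple[int, ...], pool: int
) -> np.ndarray:
    """Route each pooled gradient back to the block cell that attained the max."""
    if pool == 1:
        return upstream
    b, c, h, w = in_shape
    ho, wo = upstream.shape[2], upstream.shape[3]
    grad_pad = np.zeros((b, c, ho, wo, pool * pool))
    np.put_along_axis(grad_pad, arg[..., None], upstream[..., None], axis=-1)
    grad_pad = grad_pad.reshape(b, c, ho, wo, pool, pool).transpose(0, 1, 2, 4, 3, 5)
    grad_pad = grad_pad.reshape(b, c, ho * pool, wo * pool)
    return grad_pad[:, :, :h, :w]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stabilized softmax over the last axis."""
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def dense_softmax_forward(
    features: np.ndarray, weights: np.ndarray, bias: np.ndarray
) -> np.ndarray:
    """Class probabilities from a linear layer followed by stabilized softmax."""
    features = np.asarray(features, dtype=float)
    if features.shape[-1] != weights.shape[1]:
        raise ValidationError("feature length does not match dense weight shape")
    logits = features @ weights.T + bias
    return softmax(logits)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class WCNNConfig:
    """Architecture and training hyperparameters.

    ``filters`` are the kernel counts of the three conv layers (5x5, 5x5,
    1x1). Kernel and pool sizes are fixed by the architecture. Training is
    mini-batch SGD on cross-entropy.
    """

    filters: tuple[int, int, int] = (8, 16, 16)
    hidden_units: int = 32
    learning_rate: float = 0.05
    epochs: int = 100
    batch_size: int = 16
    init_scale: float | None = None  # None -> Glorot-uniform per layer; float -> fixed uniform(-s, s)
    relu_conv: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.filters = tuple(int(f) for f in self.filters)
        if len(self.filters) != 3 or min(self.filters) < 1:
            raise ValidationError("filters must be three positive integers")
        if self.hidden_units < 1 or self.batch_size < 1 or self.epochs < 0:
            raise ValidationError("invalid hidden_units/batch_size/epochs")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")

    def to_dict(self) -> dict:
        return {
            "filters": list(self.filters),
            "hidden_units": self.hidden_units,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "init_scale": self.init_scale,
            "relu_conv": self.relu_conv,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WCNNConfig":
        d = dict(d)
        if "filters" in d:
            d["filters"] = tuple(d["filters"])
        return cls(**d)


def _spatial_chain(height: int, width: int) -> list[tuple[int, int]]:
    """Spatial extents after each (conv, pool) stage; raises if a conv cannot fit."""
    sizes = []
    h, w = height, width
    for kernel, pool in ((5, 2), (5, 2), (1, 1)):
        if kernel > h or kernel > w:
            raise ValidationError(
                f"grid {height}x{width} too small for the conv stack: stage kernel "
                f"{kernel}x{kernel} does not fit {h}x{w}; at least {MIN_GENES} genes "
                f"(13x13 grid) are required"
            )
        h, w = h - kernel + 1, w - kernel + 1
        h, w = math.ceil(h / pool), math.ceil(w / pool)
        sizes.append((h, w))
    return sizes


class WCNNModel:
    """All trainable parameters plus the gene grid and configuration."""

    def __init__(self, gene_ids: list[str], config: WCNNConfig):
        self.gene_ids = list(gene_ids)
        self.config = config
        g = len(gene_ids)
        if g < MIN_GENES:
            raise ValidationError(
                f"the architecture needs at least {MIN_GENES} genes (13x13 grid), got {g}"
            )
        self.grid = GeneGrid.for_genes(g)
        self.spatial = _spatial_chain(self.grid.height, self.grid.width)
        f1, f2, f3 = config.filters
        h3, w3 = self.spatial[2]
        self.flat_dim = f3 * h3 * w3

        rng = np.random.default_rng(config.seed)

        def limit(fan_in: int, fan_out: int) -> float:
            # Glorot-uniform keeps signal magnitude roughly constant through
            # depth; a fixed init_scale collapses activations in deep stacks.
            if config.init_scale is not None:
                return float(config.init_scale)
            return math.sqrt(6.0 / (fan_in + fan_out))

        def uniform(shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
            s = limit(fan_in, fan_out)
            return rng.uniform(-s, s, size=shape)

        def bias(size: int) -> np.ndarray:
            # small random values keep pre-activations off the exact ReLU kink
            return rng.uniform(-0.01, 0.01, size=size)

        self.gene_weights = np.ones(g)  # identity start: a strict plain-CNN superset
        self.K1 = uniform((f1, 1, 5, 5), 25, f1 * 25)
        self.b1 = bias(f1)
        self.K2 = uniform((f2, f1, 5, 5), f1 * 25, f2 * 25)
        self.b2 = bias(f2)
        self.K3 = uniform((f3, f2, 1, 1), f2, f3)
        self.b3 = bias(f3)
        self.Wh = uniform((config.hidden_units, self.flat_dim), self.flat_dim, config.hidden_units)
        self.bh = bias(config.hidden_units)
        self.Wo = uniform((2, config.hidden_units), config.hidden_units, 2)
        self.bo = bias(2)
        self.loss_trace: list[float] = []
        self.acc_trace: list[float] = []

    PARAM_NAMES = ("gene_weights", "K1", "b1", "K2", "b2", "K3", "b3", "Wh", "bh", "Wo", "bo")

    # -- forward ------------------------------------------------------------
    def _act(self, pre: np.ndarray) -> np.ndarray:
        return np.maximum(pre, 0.0) if self.config.relu_conv else pre

    def forward(self, X: np.ndarray, cache: bool = False):
        """Class probabilities (B, 2); with ``cache`` also the intermediates."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.grid.n_genes:
            raise ValidationError(
                f"input has {X.shape[1]} genes, model expects {self.grid.n_genes}"
            )
        xw = weighted_input_forward(X, self.gene_weights)
        m0 = grid_embed(xw, self.grid)
        c1 = conv_forward(m0, self.K1, self.b1)
        a1 = self._act(c1)
        p1, arg1 = maxpool_forward(a1, 2)
        c2 = conv_forward(p1, self.K2, self.b2)
        a2 = self._act(c2)
        p2, arg2 = maxpool_forward(a2, 2)
        c3 = conv_forward(p2, self.K3, self.b3)
        a3 = self._act(c3)
        p3, _ = maxpool_forward(a3, 1)
        flat = p3.reshape(p3.shape[0], -1)
        h_pre = flat @ self.Wh.T + self.bh
        h = np.maximum(h_pre, 0.0)
        probs = dense_softmax_forward(h, self.Wo, self.bo)
        if not cache:
            return probs
        return probs, {
            "X": X, "xw": xw, "m0": m0,
            "c1": c1, "a1": a1, "p1": p1, "arg1": arg1,
            "c2": c2, "a2": a2, "p2": p2, "arg2": arg2,
            "c3": c3, "a3": a3, "flat": flat,
            "h_pre": h_pre, "h": h, "probs": probs,
        }

    # -- loss and gradients -------------------------------------------------
    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and its gradient for every parameter group."""
        y = np.asarray(y, dtype=int)
        probs, c = self.forward(X, cache=True)
        b = probs.shape[0]
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(b), y] + eps)))

        onehot = np.zeros_like(probs)
        onehot[np.arange(b), y] = 1.0
        d_logits = (probs - onehot) / b  # softmax + CE fused gradient

        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = d_logits.T @ c["h"]
        grads["bo"] = d_logits.sum(axis=0)
        d_h = d_logits @ self.Wo
        d_hpre = d_h * (c["h_pre"] > 0)
        grads["Wh"] = d_hpre.T @ c["flat"]
        grads["bh"] = d_hpre.sum(axis=0)
        d_flat = d_hpre @ self.Wh

        f3 = self.config.filters[2]
        h3, w3 = self.spatial[2]
        d_p3 = d_flat.reshape(b, f3, h3, w3)
        d_a3 = d_p3  # 1x1 pool is the identity
        d_c3 = d_a3 * (c["c3"] > 0) if self.config.relu_conv else d_a3
        d_p2, gK3, gb3 = conv_backward(c["p2"], self.K3, d_c3)
        grads["K3"], grads["b3"] = gK3, gb3

        d_a2 = maxpool_backward(d_p2, c["arg2"], c["a2"].shape, 2)
        d_c2 = d_a2 * (c["c2"] > 0) if self.config.relu_conv else d_a2
        d_p1, gK2, gb2 = conv_backward(c["p1"], self.K2, d_c2)
        grads["K2"], grads["b2"] = gK2, gb2

        d_a1 = maxpool_backward(d_p1, c["arg1"], c["a1"].shape, 2)
        d_c1 = d_a1 * (c["c1"] > 0) if self.config.relu_conv else d_a1
        d_m0, gK1, gb1 = conv_backward(c["m0"], self.K1, d_c1)
        grads["K1"], grads["b1"] = gK1, gb1

        d_xw = grid_unembed(d_m0, self.grid)
        _, grads["gene_weights"] = weighted_input_backward(c["X"], self.gene_weights, d_xw)
        return loss, grads

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "gene_ids": self.gene_ids,
            "config": self.config.to_dict(),
            "params": {name: getattr(self, name).tolist() for name in self.PARAM_NAMES},
            "loss_trace": [float(v) for v in self.loss_trace],
            "acc_trace": [float(v) for v in self.acc_trace],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "WCNNModel":
        payload = json.loads(text)
        model = cls(payload["gene_ids"], WCNNConfig.from_dict(payload["config"]))
        for name in cls.PARAM_NAMES:
            setattr(model, name, np.asarray(payload["params"][name], dtype=float))
        model.loss_trace = list(payload.get("loss_trace", []))
        model.acc_trace = list(payload.get("acc_trace", []))
        return model

    @classmethod
    def load(cls, path: str | Path) -> "WCNNModel":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def train(train_ds: ExpressionDataset, config: WCNNConfig) -> WCNNModel:
    """Mini-batch SGD on mean cross-entropy; deterministic given ``config.seed``.

    The per-epoch loss is the mean of batch losses; the per-epoch accuracy is
    a full forward pass over the training set with the updated parameters.
    With ``epochs = 0`` the freshly initialized model is returned unchanged.
    """
    train_ds.validate(require_two_classes=config.epochs > 0)
    model = WCNNModel(train_ds.gene_ids, config)
    X, y = train_ds.values, train_ds.labels
    rng = np.random.default_rng(config.seed + 1)  # data order stream, distinct from init
    for _ in range(config.epochs):
        order = rng.permutation(X.shape[0])
        batch_losses = []
        for start in range(0, X.shape[0], config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = model.loss_and_grads(X[idx], y[idx])
            batch_losses.append(loss)
            for name, g in grads.items():
                param = getattr(model, name)
                param -= config.learning_rate * g
        model.loss_trace.append(float(np.mean(batch_losses)))
        preds, _ = predict(model, train_ds)
        model.acc_trace.append(float((preds == y).mean()))
    return model


def predict(model: WCNNModel, ds: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (ties broken toward class 0) and class-probability scores."""
    if list(ds.gene_ids) != list(model.gene_ids):
        raise ValidationError("dataset gene_ids do not match the model")
    probs = model.forward(ds.values)
    labels = (probs[:, 1] > probs[:, 0]).astype(int)
    return labels, probs
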