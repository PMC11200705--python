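"""Transformer encoder classifier for fixed-length gait-cycle matrices.

Forward path: learned linear embedding (channels -> d_model), additive
sinusoidal positional encoding, ``n_blocks`` post-norm encoder blocks
(multi-head self-attention and position-wise feed-forward, each wrapped in
residual + layer normalization), flatten over time and model dimensions,
and a fully connected softmax head.

Implemented directly on NumPy with hand-written backpropagation and an Adam
optimizer, so training runs anywhere the scientific stack is installed; the
network is small enough (d_model 48, 5 blocks) for CPU training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import LABELS, N_CHANNELS


@dataclass
class ModelConfig:
    seq_len: int = 276
    n_channels: int = N_CHANNELS
    d_model: int = 48
    n_blocks: int = 5
    n_heads: int = 4
    ff_dim: int = 128
    dropout: float = 0.1
    n_classes: int = 2

    def validate(self) -> "ModelConfig":
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model {self.d_model} not divisible by n_heads {self.n_heads}"
            )
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        return self

    @property
    def flatten_width(self) -> int:
        """Width of the flattened vector entering the final FC layer."""
        return self.seq_len * self.d_model


@dataclass
class TrainConfig:
    epochs: int = 130
    batch_size: int = 64
    learning_rate: float = 1e-5
    seed: int = 0


def sinusoidal_positional_encoding(seq_len: int, d_model: int, dtype=np.float32) -> np.ndarray:
    pos = np.arange(seq_len)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe.astype(dtype)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _layernorm_fwd(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    inv = 1.0 / np.sqrt((xc ** 2).mean(-1, keepdims=True) + eps)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


class TransformerClassifier:
    """Trainable encoder classifier; see module docstring for the layout."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config.validate()
        self.dtype = dtype
        self.params: dict[str, np.ndarray] = {}
        self.history: dict[str, list[float]] = {
            "train_loss": [], "train_accuracy": [], "val_accuracy": []
        }
        rng = np.random.default_rng(seed)
        c = config

        def xavier(shape):
            bound = math.sqrt(6.0 / (shape[0] + shape[-1]))
            return rng.uniform(-bound, bound, shape).astype(dtype)

        p = self.params
        p["emb_W"] = xavier((c.n_channels, c.d_model))
        p["emb_b"] = np.zeros(c.d_model, dtype)
        for i in range(c.n_blocks):
            for name in ("q", "k", "v", "o"):
                p[f"b{i}_W{name}"] = xavier((c.d_model, c.d_model))
                p[f"b{i}_b{name}"] = np.zeros(c.d_model, dtype)
            p[f"b{i}_ln1_g"] = np.ones(c.d_model, dtype)
            p[f"b{i}_ln1_b"] = np.zeros(c.d_model, dtype)
            p[f"b{i}_W1"] = xavier((c.d_model, c.ff_dim))
            p[f"b{i}_b1"] = np.zeros(c.ff_dim, dtype)
            p[f"b{i}_W2"] = xavier((c.ff_dim, c.d_model))
            p[f"b{i}_b2"] = np.zeros(c.d_model, dtype)
            p[f"b{i}_ln2_g"] = np.ones(c.d_model, dtype)
            p[f"b{i}_ln2_b"] = np.zeros(c.d_model, dtype)
        p["fc_W"] = xavier((c.flatten_width, c.n_classes))
        p["fc_b"] = np.zeros(c.n_classes, dtype)
        self.pos_encoding = sinusoidal_positional_encoding(c.seq_len, c.d_model, dtype)

    # ---------------------------------------------------------------- forward

    def _split_heads(self, x):
        b, t, d = x.shape
        nh = self.config.n_heads
        return x.reshape(b, t, nh, d // nh).transpose(0, 2, 1, 3)

    def _merge_heads(self, x):
        b, nh, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, nh * dh)

    def _attention_fwd(self, x, i):
        p = self.params
        q = x @ p[f"b{i}_Wq"] + p[f"b{i}_bq"]
        k = x @ p[f"b{i}_Wk"] + p[f"b{i}_bk"]
        v = x @ p[f"b{i}_Wv"] + p[f"b{i}_bv"]
        qh, kh, vh = map(self._split_heads, (q, k, v))
        scale = 1.0 / math.sqrt(qh.shape[-1])
        scores = (qh @ kh.transpose(0, 1, 3, 2)) * scale
        attn = _softmax(scores)
        ctx = attn @ vh
        merged = self._merge_heads(ctx)
        out = merged @ p[f"b{i}_Wo"] + p[f"b{i}_bo"]
        cache = (x, qh, kh, vh, attn, merged, scale)
        return out, cache

    def _attention_bwd(self, dout, i, cache, grads):
        p = self.params
        x, qh, kh, vh, attn, merged, scale = cache
        b, t, d = x.shape
        grads[f"b{i}_Wo"] += merged.reshape(-1, d).T @ dout.reshape(-1, d)
        grads[f"b{i}_bo"] += dout.sum(axis=(0, 1))
        dmerged = dout @ p[f"b{i}_Wo"].T
        dctx = self._split_heads(dmerged)
        dattn = dctx @ vh.transpose(0, 1, 3, 2)
        dvh = attn.transpose(0, 1, 3, 2) @ dctx
        dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
        dqh = (dscores @ kh) * scale
        dkh = (dscores.transpose(0, 1, 3, 2) @ qh) * scale
        dq, dk, dv = map(self._merge_heads, (dqh, dkh, dvh))
        dx = np.zeros_like(x)
        xf = x.reshape(-1, d)
        for name, dy in (("q", dq), ("k", dk), ("v", dv)):
            grads[f"b{i}_W{name}"] += xf.T @ dy.reshape(-1, d)
            grads[f"b{i}_b{name}"] += dy.sum(axis=(0, 1))
            dx += dy @ p[f"b{i}_W{name}"].T
        return dx

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Class probabilities for ``x`` of shape (batch, seq_len, n_channels).

        Returns ``(probs, caches)``; caches feed :meth:`backward` when
        training.
        """
        c = self.config
        if x.ndim != 3 or x.shape[1] != c.seq_len or x.shape[2] != c.n_channels:
            raise ValueError(
                f"expected input (batch, {c.seq_len}, {c.n_channels}), got {x.shape}"
            )
        p = self.params
        x = x.astype(self.dtype, copy=False)
        drop = c.dropout if train else 0.0
        if drop > 0.0 and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")

        def dropout_mask(shape):
            if drop == 0.0:
                return None
            return (rng.random(shape) >= drop).astype(self.dtype) / (1.0 - drop)

        caches: dict = {"x_in": x}
        h = x @ p["emb_W"] + p["emb_b"]
        h = h + self.pos_encoding[None, :, :]
        block_caches = []
        for i in range(c.n_blocks):
            a, attn_cache = self._attention_fwd(h, i)
            mask_a = dropout_mask(a.shape)
            if mask_a is not None:
                a = a * mask_a
            h1, ln1_cache = _layernorm_fwd(h + a, p[f"b{i}_ln1_g"], p[f"b{i}_ln1_b"])
            z1 = h1 @ p[f"b{i}_W1"] + p[f"b{i}_b1"]
            r1 = np.maximum(z1, 0.0)
            f = r1 @ p[f"b{i}_W2"] + p[f"b{i}_b2"]
            mask_f = dropout_mask(f.shape)
            if mask_f is not None:
                f = f * mask_f
            h2, ln2_cache = _layernorm_fwd(h1 + f, p[f"b{i}_ln2_g"], p[f"b{i}_ln2_b"])
            block_caches.append(
                (attn_cache, mask_a, ln1_cache, h1, z1, r1, mask_f, ln2_cache)
            )
            h = h2
        caches["blocks"] = block_caches
        flat = h.reshape(h.shape[0], -1)
        caches["flat"] = flat
        logits = flat @ p["fc_W"] + p["fc_b"]
        probs = _softmax(logits)
        return probs, caches

    def backward(self, probs, y_idx, caches) -> dict[str, np.ndarray]:
        """Cross-entropy gradients for one batch (mean reduction)."""
        c = self.config
        p = self.params
        b = probs.shape[0]
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = probs.copy()
        dlogits[np.arange(b), y_idx] -= 1.0
        dlogits /= b
        flat = caches["flat"]
        grads["fc_W"] += flat.T @ dlogits
        grads["fc_b"] += dlogits.sum(axis=0)
        dh = (dlogits @ p["fc_W"].T).reshape(b, c.seq_len, c.d_model)

        for i in reversed(range(c.n_blocks)):
            attn_cache, mask_a, ln1_cache, h1, z1, r1, mask_f, ln2_cache = \
                caches["blocks"][i]
            dsum2, dg2, db2 = _layernorm_bwd(dh, ln2_cache)
            grads[f"b{i}_ln2_g"] += dg2
            grads[f"b{i}_ln2_b"] += db2
            df = dsum2 if mask_f is None else dsum2 * mask_f
            grads[f"b{i}_W2"] += r1.reshape(-1, c.ff_dim).T @ df.reshape(-1, c.d_model)
            grads[f"b{i}_b2"] += df.sum(axis=(0, 1))
            dr1 = df @ p[f"b{i}_W2"].T
            dz1 = dr1 * (z1 > 0)
            grads[f"b{i}_W1"] += h1.reshape(-1, c.d_model).T @ dz1.reshape(-1, c.ff_dim)
            grads[f"b{i}_b1"] += dz1.sum(axis=(0, 1))
            dh1 = dsum2 + dz1 @ p[f"b{i}_W1"].T
            dsum1, dg1, db1 = _layernorm_bwd(dh1, ln1_cache)
            grads[f"b{i}_ln1_g"] += dg1
            grads[f"b{i}_ln1_b"] += db1
            da = dsum1 if mask_a is None else dsum1 * mask_a
            dh = dsum1 + self._attention_bwd(da, i, attn_cache, grads)

        demb = dh
        x_in = caches["x_in"]
        grads["emb_W"] += x_in.reshape(-1, c.n_channels).T @ demb.reshape(-1, c.d_model)
        grads["emb_b"] += demb.sum(axis=(0, 1))
        return grads

    # -------------------------------------------------------------- inference

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for lo in range(0, x.shape[0], batch_size):
            probs, _ = self.forward(x[lo:lo + batch_size], train=False)
            out.append(probs)
        return np.vstack(out)


def cross_entropy(probs: np.ndarray, y_idx: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y_idx)), y_idx] + eps)))


def build_model(config: ModelConfig | None = None, seed: int = 0,
                dtype=np.float32) -> TransformerClassifier:
    """Construct an untrained classifier with deterministic initialization."""
    return TransformerClassifier(config or ModelConfig(), seed=seed, dtype=dtype)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def train(
    model: TransformerClassifier,
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TransformerClassifier:
    """Minimize cross-entropy with Adam; history records per-epoch stats.

    ``epochs == 0`` returns the model untouched with empty history.
    """
    if config.epochs == 0:
        return model
    if x_train.shape[0] == 0 or len(np.unique(y_train)) < 2:
        raise ValueError("training set must be non-empty and two-class")
    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    n = x_train.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            probs, caches = model.forward(xb, train=True, rng=rng)
            losses.append(cross_entropy(probs, yb) * len(idx))
            correct += int((probs.argmax(1) == yb).sum())
            grads = model.backward(probs, yb, caches)
            opt.step(model.params, grads)
        model.history["train_loss"].append(sum(losses) / n)
        model.history["train_accuracy"].append(correct / n)
        if x_val is not None and x_val.shape[0] > 0:
            val_pred = model.predict_proba(x_val).argmax(1)
            model.history["val_accuracy"].append(float((val_pred == y_val).mean()))
    return model


def predict(model: TransformerClassifier, x: np.ndarray):
    """Per-sample class probabilities and string labels (deterministic)."""
    probs = model.predict_proba(x)
    labels = [LABELS[i] for i in probs.argmax(1)]
    return probs, labels
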