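"""A small Llama-style decoder in NumPy, with hand-written gradients.

The building blocks — rotary positional embeddings, grouped multi-query
attention, the SiLU-gated MLP, RMS-normalized pre-norm residual blocks,
LoRA low-rank adapters, and the causal-LM / 2-class classification losses
— are exposed both as pure functions (unit-testable math) and as layer
classes carrying forward caches and a ``backward`` pass, so the whole
model trains on a CPU without an autodiff framework.

Conventions: hidden states are float64 arrays shaped (batch, time, d);
padding sits at the *end* of a sequence and is masked out of the attention
keys; the classifier reads the hidden state of the last non-padding
position.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelConfig",
    "RopeCache",
    "AttentionWeights",
    "MlpWeights",
    "LoraLinear",
    "LlamaModel",
    "rope_angles",
    "apply_rope",
    "attention",
    "llama_mlp",
    "lora_forward",
    "lora_init",
    "lora_merge",
    "causal_lm_loss",
    "classification_loss",
    "softmax",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The desk-scale defaults (d_model 64, 2 layers, 2 heads) train in
    seconds on a CPU; ``paper_scale()`` returns the full-scale preset
    (50,254-token vocabulary, d_model 256, 4 heads, 4 layers).
    """

    vocab_size: int = 512
    d_model: int = 64
    n_heads: int = 2
    n_kv_groups: int = 2
    n_layers: int = 2
    d_ff: int = 0  # 0 -> 4 * d_model
    rope_base: float = 10_000.0
    max_positions: int = 2048
    rms_eps: float = 1e-6
    n_classes: int = 2
    #: classifier pooling: "last" non-padding position (decoder-only
    #: convention; forces attention to route discriminative tokens, which
    #: the attention-motif pipeline relies on), "mean", or "max" (the
    #: occurrence-detection bias; learns faster but leaves attention maps
    #: uninformative for motif discovery)
    pooling: str = "last"

    def __post_init__(self):
        if self.d_ff == 0:
            self.d_ff = 4 * self.d_model
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.n_heads % self.n_kv_groups != 0:
            raise ValueError("n_heads must be divisible by n_kv_groups")
        if self.head_dim % 2 != 0:
            raise ValueError("head dimension must be even (RoPE rotates pairs)")
        if self.pooling not in ("max", "mean", "last"):
            raise ValueError("pooling must be 'max', 'mean' or 'last'")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    @classmethod
    def paper_scale(cls) -> "ModelConfig":
        return cls(
            vocab_size=50_254, d_model=256, n_heads=4, n_kv_groups=4, n_layers=4
        )

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "vocab_size d_model n_heads n_kv_groups n_layers d_ff "
                "rope_base max_positions rms_eps n_classes pooling".split()
            )
        }


# ---------------------------------------------------------------------------
# rotary positional embeddings


@dataclass
class RopeCache:
    """theta_i = base^(-2i/d) and per-position cos/sin tables."""

    theta: np.ndarray  # (d/2,)
    cos: np.ndarray  # (max_positions, d/2)
    sin: np.ndarray  # (max_positions, d/2)


def rope_angles(config: ModelConfig) -> RopeCache:
    """Angle table for the per-head dimension; theta_0 = 1, decreasing."""
    d = config.head_dim
    if d % 2 != 0:
        raise ValueError("head dimension must be even")
    i = np.arange(d // 2, dtype=np.float64)
    theta = config.rope_base ** (-2.0 * i / d)
    p = np.arange(config.max_positions, dtype=np.float64)[:, None]
    angles = p * theta[None, :]
    return RopeCache(theta=theta, cos=np.cos(angles), sin=np.sin(angles))


def apply_rope(vector: np.ndarray, position: int, cache: RopeCache) -> np.ndarray:
    """Rotate coordinate pairs (2i, 2i+1) of one head vector by p*theta_i."""
    v = np.asarray(vector, dtype=np.float64)
    if v.shape[-1] != 2 * cache.theta.shape[0]:
        raise ValueError(
            f"vector length {v.shape[-1]} != head dim {2 * cache.theta.shape[0]}"
        )
    cos, sin = cache.cos[position], cache.sin[position]
    out = np.empty_like(v)
    out[..., 0::2] = v[..., 0::2] * cos - v[..., 1::2] * sin
    out[..., 1::2] = v[..., 0::2] * sin + v[..., 1::2] * cos
    return out


def _rope_rotate(x: np.ndarray, cache: RopeCache, sign: float = 1.0) -> np.ndarray:
    """Rotate (B, H, T, d) by position-indexed angles; sign=-1 inverts."""
    T = x.shape[-2]
    cos = cache.cos[:T][None, None]
    sin = sign * cache.sin[:T][None, None]
    out = np.empty_like(x)
    even, odd = x[..., 0::2], x[..., 1::2]
    out[..., 0::2] = even * cos - odd * sin
    out[..., 1::2] = even * sin + odd * cos
    return out


# ---------------------------------------------------------------------------
# small numerics


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _silu(z: np.ndarray) -> np.ndarray:
    return z / (1.0 + np.exp(-z))


def _dsilu(z: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-z))
    return s * (1.0 + z * (1.0 - s))


# ---------------------------------------------------------------------------
# parameters and layers


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "trainable")

    def __init__(self, data: np.ndarray, trainable: bool = True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.trainable = trainable

    def zero_grad(self):
        self.grad[...] = 0.0


def _kaiming(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))


class LoraLinear:
    """A linear map with an optional rank-r LoRA update W + s*A@B.

    Three regimes: full-rank (adapters off, W trains), adapter mode (W
    frozen, A and B train), frozen.  A fresh adapter pair has B = 0, so
    enabling adapters never changes the layer's function.
    """

    def __init__(
        self,
        d_in: int,
        d_out: int,
        rng: np.random.Generator,
        init_std: float | None = None,
    ):
        self.d_in, self.d_out = d_in, d_out
        std = 1.0 / np.sqrt(d_in) if init_std is None else init_std
        self.W = Param(rng.normal(0.0, std, size=(d_in, d_out)))
        self.A: Param | None = None
        self.B: Param | None = None
        self.scale = 0.0
        self._x: np.ndarray | None = None
        self._xA: np.ndarray | None = None

    # -- adapter management -------------------------------------------------

    @property
    def adapters_enabled(self) -> bool:
        return self.A is not None

    def enable_lora(self, rank: int, alpha: float, rng: np.random.Generator):
        if rank >= min(self.d_in, self.d_out):
            import warnings

            warnings.warn(
                f"LoRA rank {rank} >= min(d_in, d_out) = "
                f"{min(self.d_in, self.d_out)}: no longer low-rank"
            )
        self.scale = alpha / rank
        self.A = Param(np.empty((self.d_in, rank)))
        self.B = Param(np.empty((rank, self.d_out)))
        self.reinit_adapters(rng)
        self.W.trainable = False

    def reinit_adapters(self, rng: np.random.Generator):
        """Kaiming-init A, zero B: the layer's function equals its base."""
        self.A.data[...] = _kaiming(rng, self.d_in, self.A.data.shape[1])
        self.A.zero_grad()
        self.B.data[...] = 0.0
        self.B.zero_grad()

    def merge_adapters(self) -> np.ndarray:
        """Fold s*A@B into W and return the merged matrix."""
        merged = self.effective_weight()
        self.W.data = merged
        return merged

    def effective_weight(self) -> np.ndarray:
        if self.adapters_enabled:
            return self.W.data + self.scale * (self.A.data @ self.B.data)
        return self.W.data.copy()

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        x2 = x.reshape(-1, self.d_in)
        self._x = x2
        y = x2 @ self.W.data
        if self.adapters_enabled:
            self._xA = x2 @ self.A.data
            y = y + self.scale * (self._xA @ self.B.data)
        return y.reshape(*x.shape[:-1], self.d_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy2 = dy.reshape(-1, self.d_out)
        x2 = self._x
        if self.W.trainable:
            self.W.grad += x2.T @ dy2
        dx = dy2 @ self.W.data.T
        if self.adapters_enabled:
            dyB = dy2 @ self.B.data.T
            if self.A.trainable:
                self.A.grad += self.scale * (x2.T @ dyB)
            if self.B.trainable:
                self.B.grad += self.scale * (self._xA.T @ dy2)
            dx += self.scale * (dyB @ self.A.data.T)
        return dx.reshape(*dy.shape[:-1], self.d_in)

    def params(self) -> list[tuple[str, Param]]:
        out = [("W", self.W)]
        if self.adapters_enabled:
            out += [("A", self.A), ("B", self.B)]
        return out


def lora_forward(x: np.ndarray, layer: LoraLinear) -> np.ndarray:
    """y = x W + s (x A) B — the adapter update never materialized in W."""
    return layer.forward(np.asarray(x, dtype=np.float64))


def lora_init(layer: LoraLinear, rng: np.random.Generator) -> LoraLinear:
    """(Re-)initialize adapters: Kaiming A, zero B."""
    if not layer.adapters_enabled:
        raise ValueError("layer has no adapters; call enable_lora first")
    layer.reinit_adapters(rng)
    return layer


def lora_merge(layer: LoraLinear) -> np.ndarray:
    """Return W + s A B without mutating the layer."""
    return layer.effective_weight()


class RMSNorm:
    def __init__(self, d: int, eps: float = 1e-6):
        self.g = Param(np.ones(d))
        self.eps = eps
        self._x = None
        self._inv = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        ms = np.mean(x * x, axis=-1, keepdims=True)
        self._x = x
        self._inv = 1.0 / np.sqrt(ms + self.eps)
        return x * self._inv * self.g.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, inv = self._x, self._inv
        xhat = x * inv
        if self.g.trainable:
            self.g.grad += np.sum(dy * xhat, axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.g.data
        d = x.shape[-1]
        dot = np.sum(dxhat * x, axis=-1, keepdims=True)
        return inv * dxhat - (inv**3 / d) * x * dot

    def params(self):
        return [("g", self.g)]


class Embedding:
    def __init__(self, vocab_size: int, d: int, rng: np.random.Generator):
        self.table = Param(rng.normal(0.0, 0.02, size=(vocab_size, d)))
        self._ids = None

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.table.data[ids]

    def backward(self, dy: np.ndarray):
        if self.table.trainable:
            np.add.at(
                self.table.grad,
                self._ids.reshape(-1),
                dy.reshape(-1, dy.shape[-1]),
            )

    def params(self):
        return [("table", self.table)]


# ---------------------------------------------------------------------------
# attention


@dataclass
class AttentionWeights:
    """Raw projection matrices plus the head->kv-group structure."""

    W_q: np.ndarray  # (d, H*hd)
    W_k: np.ndarray  # (d, G*hd)
    W_v: np.ndarray  # (d, G*hd)
    W_o: np.ndarray  # (H*hd, d)
    n_heads: int
    n_kv_groups: int


@dataclass
class MlpWeights:
    W_gate: np.ndarray
    W_up: np.ndarray
    W_down: np.ndarray


def _score_mask(T: int, valid_len: np.ndarray | None, B: int) -> np.ndarray:
    """(B, 1, T, T) additive mask: causal, plus padded keys disallowed."""
    mask = np.zeros((B, 1, T, T))
    future = np.triu(np.ones((T, T), dtype=bool), k=1)
    mask[:, :, future] = -np.inf
    if valid_len is not None:
        key_pad = np.arange(T)[None, :] >= np.asarray(valid_len)[:, None]  # (B,T)
        mask[:, 0, :, :][key_pad[:, None, :].repeat(T, axis=1)] = -np.inf
    return mask


def attention(
    hidden_states: np.ndarray,
    weights: AttentionWeights,
    cache: RopeCache,
    causal_mask: bool = True,
    valid_len: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Grouped multi-query attention: softmax(RoPE(Q) RoPE(K)^T / sqrt(d_k)) V.

    Heads within one kv-group share the K and V projections.  Returns the
    output hidden states and the attention probabilities (B, H, T, T); each
    query row sums to one.
    """
    x = np.asarray(hidden_states, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    B, T, d = x.shape
    H, G = weights.n_heads, weights.n_kv_groups
    hd = weights.W_q.shape[1] // H
    rep = H // G

    q = (x @ weights.W_q).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
    k = (x @ weights.W_k).reshape(B, T, G, hd).transpose(0, 2, 1, 3)
    v = (x @ weights.W_v).reshape(B, T, G, hd).transpose(0, 2, 1, 3)
    q = _rope_rotate(q, cache)
    k = _rope_rotate(k, cache)
    k_h = np.repeat(k, rep, axis=1)
    v_h = np.repeat(v, rep, axis=1)
    scores = q @ k_h.transpose(0, 1, 3, 2) / np.sqrt(hd)
    if causal_mask:
        scores = scores + _score_mask(T, valid_len, B)
    probs = softmax(scores, axis=-1)
    ctx = (probs @ v_h).transpose(0, 2, 1, 3).reshape(B, T, H * hd)
    out = ctx @ weights.W_o
    if squeeze:
        return out[0], probs[0]
    return out, probs


def llama_mlp(x: np.ndarray, weights: MlpWeights) -> np.ndarray:
    """Gated MLP: W_down( SiLU(x W_gate) * (x W_up) )."""
    x = np.asarray(x, dtype=np.float64)
    return (_silu(x @ weights.W_gate) * (x @ weights.W_up)) @ weights.W_down


class AttentionLayer:
    """Trainable grouped multi-query attention with RoPE and causal mask."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        d, hd = config.d_model, config.head_dim
        self.H, self.G = config.n_heads, config.n_kv_groups
        self.hd = hd
        self.Wq = LoraLinear(d, self.H * hd, rng)
        self.Wk = LoraLinear(d, self.G * hd, rng)
        self.Wv = LoraLinear(d, self.G * hd, rng)
        self.Wo = LoraLinear(self.H * hd, d, rng)
        self.last_probs: np.ndarray | None = None
        self._cache = None

    def forward(
        self,
        x: np.ndarray,
        rope: RopeCache,
        valid_len: np.ndarray | None = None,
    ) -> np.ndarray:
        B, T, d = x.shape
        H, G, hd, rep = self.H, self.G, self.hd, self.H // self.G
        q = self.Wq.forward(x).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
        k = self.Wk.forward(x).reshape(B, T, G, hd).transpose(0, 2, 1, 3)
        v = self.Wv.forward(x).reshape(B, T, G, hd).transpose(0, 2, 1, 3)
        q_r = _rope_rotate(q, rope)
        k_r = _rope_rotate(k, rope)
        k_h = np.repeat(k_r, rep, axis=1)
        v_h = np.repeat(v, rep, axis=1)
        scores = q_r @ k_h.transpose(0, 1, 3, 2) / np.sqrt(hd)
        scores += _score_mask(T, valid_len, B)
        probs = softmax(scores, axis=-1)
        ctx = (probs @ v_h).transpose(0, 2, 1, 3).reshape(B, T, H * hd)
        out = self.Wo.forward(ctx)
        self.last_probs = probs
        self._cache = (q_r, k_h, v_h, probs, rope, (B, T, d))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q_r, k_h, v_h, probs, rope, (B, T, d) = self._cache
        H, G, hd, rep = self.H, self.G, self.hd, self.H // self.G
        dctx = self.Wo.backward(dout).reshape(B, T, H, hd).transpose(0, 2, 1, 3)
        dprobs = dctx @ v_h.transpose(0, 1, 3, 2)
        dv_h = probs.transpose(0, 1, 3, 2) @ dctx
        dscores = probs * (dprobs - np.sum(dprobs * probs, axis=-1, keepdims=True))
        dscores /= np.sqrt(hd)
        dq_r = dscores @ k_h
        dk_h = dscores.transpose(0, 1, 3, 2) @ q_r
        dk_r = dk_h.reshape(B, G, rep, T, hd).sum(axis=2)
        dv = dv_h.reshape(B, G, rep, T, hd).sum(axis=2)
        dq = _rope_rotate(dq_r, rope, sign=-1.0)
        dk = _rope_rotate(dk_r, rope, sign=-1.0)
        dx = self.Wq.backward(dq.transpose(0, 2, 1, 3).reshape(B, T, H * hd))
        dx += self.Wk.backward(dk.transpose(0, 2, 1, 3).reshape(B, T, G * hd))
        dx += self.Wv.backward(dv.transpose(0, 2, 1, 3).reshape(B, T, G * hd))
        return dx

    def lora_linears(self):
        return [self.Wq, self.Wk, self.Wv, self.Wo]

    def params(self):
        return [
            (f"{n}.{pn}", p)
            for n, lin in zip("Wq Wk Wv Wo".split(), self.lora_linears())
            for pn, p in lin.params()
        ]


class GatedMlp:
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        d, h = config.d_model, config.d_ff
        self.gate = LoraLinear(d, h, rng)
        self.up = LoraLinear(d, h, rng)
        self.down = LoraLinear(h, d, rng)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        g = self.gate.forward(x)
        u = self.up.forward(x)
        sg = _silu(g)
        self._cache = (g, u, sg)
        return self.down.forward(sg * u)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g, u, sg = self._cache
        dh = self.down.backward(dy)
        du = dh * sg
        dg = dh * u * _dsilu(g)
        return self.gate.backward(dg) + self.up.backward(du)

    def lora_linears(self):
        return [self.gate, self.up, self.down]

    def params(self):
        return [
            (f"{n}.{pn}", p)
            for n, lin in zip("gate up down".split(), self.lora_linears())
            for pn, p in lin.params()
        ]


class Block:
    """Pre-norm residual block: x + Attn(RMS(x)), then x + MLP(RMS(x))."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.norm1 = RMSNorm(config.d_model, config.rms_eps)
        self.attn = AttentionLayer(config, rng)
        self.norm2 = RMSNorm(config.d_model, config.rms_eps)
        self.mlp = GatedMlp(config, rng)

    def forward(self, x, rope, valid_len=None):
        x = x + self.attn.forward(self.norm1.forward(x), rope, valid_len)
        x = x + self.mlp.forward(self.norm2.forward(x))
        return x

    def backward(self, dy):
        dy = dy + self.norm2.backward(self.mlp.backward(dy))
        dy = dy + self.norm1.backward(self.attn.backward(dy))
        return dy

    def lora_linears(self):
        return self.attn.lora_linears() + self.mlp.lora_linears()

    def params(self):
        return (
            [("norm1.g", self.norm1.g)]
            + [(f"attn.{n}", p) for n, p in self.attn.params()]
            + [("norm2.g", self.norm2.g)]
            + [(f"mlp.{n}", p) for n, p in self.mlp.params()]
        )


class LlamaModel:
    """Decoder-only transformer with a causal-LM head and a 2-class head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.rope = rope_angles(config)
        self.embedding = Embedding(config.vocab_size, config.d_model, rng)
        self.blocks = [Block(config, rng) for _ in range(config.n_layers)]
        self.final_norm = RMSNorm(config.d_model, config.rms_eps)
        self.lm_head = LoraLinear(config.d_model, config.vocab_size, rng)
        self.cls_head = LoraLinear(config.d_model, config.n_classes, rng)
        self._cls_cache = None

    # -- forward ------------------------------------------------------------

    def forward_hidden(
        self, ids: np.ndarray, valid_len: np.ndarray | None = None
    ) -> np.ndarray:
        x = self.embedding.forward(ids)
        for blk in self.blocks:
            x = blk.forward(x, self.rope, valid_len)
        return self.final_norm.forward(x)

    def forward_lm(self, ids: np.ndarray) -> np.ndarray:
        """Per-position vocabulary logits (B, T, V)."""
        return self.lm_head.forward(self.forward_hidden(ids))

    def forward_cls(
        self, ids: np.ndarray, valid_len: np.ndarray | None = None
    ) -> np.ndarray:
        """2-class logits (B, 2) pooled over the non-padding positions."""
        B, T = ids.shape
        if valid_len is None:
            valid_len = np.full(B, T, dtype=int)
        valid_len = np.asarray(valid_len)
        h = self.forward_hidden(ids, valid_len)
        if self.config.pooling == "last":
            pos = valid_len - 1
            pooled = h[np.arange(B), pos]
            self._cls_cache = ("last", h.shape, pos)
        elif self.config.pooling == "mean":
            mask = (np.arange(T)[None, :] < valid_len[:, None]).astype(float)
            pooled = (h * mask[:, :, None]).sum(axis=1) / valid_len[:, None]
            self._cls_cache = ("mean", h.shape, mask, valid_len)
        else:  # per-dimension max over valid positions
            pad = np.arange(T)[None, :] >= valid_len[:, None]
            hm = np.where(pad[:, :, None], -np.inf, h)
            argmax = hm.argmax(axis=1)  # (B, d)
            pooled = np.take_along_axis(h, argmax[:, None, :], axis=1)[:, 0, :]
            self._cls_cache = ("max", h.shape, argmax)
        return self.cls_head.forward(pooled)

    # -- backward -----------------------------------------------------------

    def backward_lm(self, dlogits: np.ndarray) -> None:
        dh = self.lm_head.backward(dlogits)
        self._backward_hidden(dh)

    def backward_cls(self, dlogits: np.ndarray) -> None:
        dpooled = self.cls_head.backward(dlogits)
        cache = self._cls_cache
        if cache[0] == "last":
            _, shape, pos = cache
            dh = np.zeros(shape)
            dh[np.arange(shape[0]), pos] = dpooled
        elif cache[0] == "mean":
            _, shape, mask, valid_len = cache
            dh = (
                mask[:, :, None]
                * dpooled[:, None, :]
                / valid_len[:, None, None]
            )
        else:  # max: gradient routes to the argmax position per dimension
            _, shape, argmax = cache
            dh = np.zeros(shape)
            np.put_along_axis(
                dh, argmax[:, None, :], dpooled[:, None, :], axis=1
            )
        self._backward_hidden(dh)

    def _backward_hidden(self, dh: np.ndarray) -> None:
        dx = self.final_norm.backward(dh)
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)
        self.embedding.backward(dx)

    # -- parameter / adapter management --------------------------------------

    def lora_linears(self) -> list[LoraLinear]:
        """The seven projection matrices per block (q, k, v, o, gate, up, down)."""
        out: list[LoraLinear] = []
        for blk in self.blocks:
            out.extend(blk.lora_linears())
        return out

    def enable_lora(self, rank: int, alpha: float, rng: np.random.Generator):
        for lin in self.lora_linears():
            lin.enable_lora(rank, alpha, rng)

    def params(self) -> list[tuple[str, Param]]:
        named = [("embedding.table", self.embedding.table)]
        for i, blk in enumerate(self.blocks):
            named += [(f"blocks.{i}.{n}", p) for n, p in blk.params()]
        named += [("final_norm.g", self.final_norm.g)]
        named += [(f"lm_head.{n}", p) for n, p in self.lm_head.params()]
        named += [(f"cls_head.{n}", p) for n, p in self.cls_head.params()]
        return named

    def zero_grad(self):
        for _, p in self.params():
            p.zero_grad()

    def set_trainable(self, names_predicate) -> None:
        for name, p in self.params():
            p.trainable = bool(names_predicate(name))

    def attention_probs(self) -> list[np.ndarray]:
        """Last forward pass's attention matrices, one (B, H, T, T) per layer."""
        return [blk.attn.last_probs for blk in self.blocks]

    # -- persistence ----------------------------------------------------------

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        payload = {"config": self.config.to_dict()}
        lins = self.lora_linears()
        if lins and lins[0].adapters_enabled:
            rank = lins[0].A.data.shape[1]
            payload["lora"] = {"rank": rank, "alpha": lins[0].scale * rank}
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(payload, fh)
        arrays = {name: p.data for name, p in self.params()}
        np.savez(os.path.join(directory, "weights.npz"), **arrays)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "LlamaModel":
        with open(os.path.join(directory, "config.json")) as fh:
            payload = json.load(fh)
        model = cls(ModelConfig(**payload["config"]), seed=0)
        if "lora" in payload:
            model.enable_lora(
                int(payload["lora"]["rank"]),
                float(payload["lora"]["alpha"]),
                rng=np.random.default_rng(0),
            )
        with np.load(os.path.join(directory, "weights.npz")) as arch:
            for name, p in model.params():
                p.data[...] = arch[name]
        return model


# ---------------------------------------------------------------------------
# losses


def causal_lm_loss(logits: np.ndarray, input_ids: np.ndarray) -> float:
    """Mean next-token cross-entropy: labels are inputs shifted left by one."""
    loss, _ = causal_lm_loss_and_grad(logits, input_ids)
    return loss


def causal_lm_loss_and_grad(
    logits: np.ndarray, input_ids: np.ndarray
) -> tuple[float, np.ndarray]:
    logits = np.asarray(logits, dtype=np.float64)
    B, T, V = logits.shape
    if T < 2:
        raise ValueError("causal LM loss needs sequences of length >= 2")
    z = logits[:, :-1, :]  # predictions for positions 1..T-1
    y = np.asarray(input_ids)[:, 1:]
    p = softmax(z, axis=-1)
    n = B * (T - 1)
    idx = (np.arange(B)[:, None], np.arange(T - 1)[None, :], y)
    loss = -np.mean(np.log(p[idx]))
    dz = p.copy()
    dz[idx] -= 1.0
    dlogits = np.zeros_like(logits)
    dlogits[:, :-1, :] = dz / n
    return float(loss), dlogits


def classification_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy from 2-class softmax logits."""
    loss, _ = classification_loss_and_grad(logits, labels)
    return loss


def classification_loss_and_grad(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if logits.ndim != 2 or logits.shape[1] != 2:
        raise ValueError("expected (N, 2) logits")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    p = softmax(logits, axis=-1)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels]))
    dz = p.copy()
    dz[np.arange(n), labels] -= 1.0
    return float(loss), dz / n
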