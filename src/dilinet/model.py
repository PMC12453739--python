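"""The DILI classification network.

Architecture, front to back:

1. Feature expansion: two fully connected blocks, each
   ``affine -> BatchNorm -> LeakyReLU(0.01) -> Dropout(0.2)``, taking the
   128-dimensional fingerprint-derived input to 256 dimensions.
2. Token bridge: the 256-vector is reshaped row-major into 8 tokens of 32
   dimensions; fixed sinusoidal positional encodings are added (toggleable).
3. One post-norm Transformer encoder layer: multi-head scaled-dot-product
   self-attention (4 heads by default), residual + LayerNorm, a 32->2048->32
   position-wise feed-forward network with ReLU, residual + LayerNorm;
   dropout 0.1 around both sub-layers.
4. Mean pooling over the 8 tokens, then an affine 32->128 block with
   BatchNorm, LeakyReLU and dropout — the "main branch" output ``m``.
5. A squeeze-and-excitation (SE) gate over the 128 channels
   (``s = sigmoid(W2 relu(W1 m))``, bottleneck 128/r) whose output is added
   back as a residue, plus a dedicated linear skip from the 128-dim network
   input: the head consumes ``m + SE(m) + skip(x)``.
6. A final affine 128->1 producing the classification logit.

Every stochastic element (weight init, dropout masks) draws from
explicitly passed NumPy generators, so eval-mode inference is a pure
function of (weights, input).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, softmax

__all__ = [
    "ModelConfig",
    "MHAParams",
    "SEParams",
    "DiliClassifier",
    "multi_head_attention",
    "se_recalibrate",
    "pool_tokens",
    "to_tokens",
    "sinusoidal_encoding",
]


# --------------------------------------------------------------------- config
@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the printed architecture where it is explicit and the
    documented design choices where it is not (head count, SE ratio,
    positional encoding, pooling, fingerprint folding mode).
    """

    input_dim: int = 128
    fingerprint_bits: int = 2048
    expansion_dim: int = 256
    d_model: int = 32
    n_tokens: int = 8
    n_heads: int = 4
    ffn_dim: int = 2048
    post_dim: int = 128
    leaky_slope: float = 0.01
    dropout_expansion: float = 0.2
    dropout_transformer: float = 0.1
    se_ratio: int = 16
    positional_encoding: bool = True
    pooling: str = "mean"
    input_mode: str = "fold"  # "fold": OR-folded 128-bit input; "project": learned 2048->128

    def __post_init__(self):
        if self.n_tokens * self.d_model != self.expansion_dim:
            raise ValueError("n_tokens * d_model must equal expansion_dim")
        if self.d_model % self.n_heads != 0:
            raise ValueError("n_heads must divide d_model")
        if self.post_dim % self.se_ratio != 0 or self.post_dim // self.se_ratio < 1:
            raise ValueError("se_ratio must divide post_dim with bottleneck >= 1")
        for rate in (self.dropout_expansion, self.dropout_transformer):
            if not 0.0 <= rate < 1.0:
                raise ValueError("dropout rates must lie in [0, 1)")
        if self.pooling != "mean":
            raise ValueError("only mean token pooling is implemented")
        if self.input_mode not in ("fold", "project"):
            raise ValueError("input_mode must be 'fold' or 'project'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MHAParams:
    """Stacked multi-head attention projections.

    ``w_q``, ``w_k``, ``w_v`` are (d_model, h*d_k) with head ``i`` occupying
    columns ``i*d_k:(i+1)*d_k`` (equivalent to per-head d_model x d_k
    matrices); ``w_o`` is (h*d_k, d_model).
    """

    h: int
    d_k: int
    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    w_o: np.ndarray

    def __post_init__(self):
        d_model = self.w_q.shape[0]
        if self.h * self.d_k != self.w_q.shape[1]:
            raise ValueError("h * d_k must match projection width")
        for w in (self.w_q, self.w_k, self.w_v, self.w_o):
            if not np.all(np.isfinite(w)):
                raise ValueError("attention parameters must be finite")
        if self.w_o.shape != (self.h * self.d_k, d_model):
            raise ValueError("w_o has inconsistent shape")


@dataclass
class SEParams:
    """Squeeze-and-excitation bottleneck weights: w1 is (C/r, C), w2 is (C, C/r)."""

    c: int
    r: int
    w1: np.ndarray
    w2: np.ndarray

    def __post_init__(self):
        if self.c % self.r != 0 or self.c // self.r < 1:
            raise ValueError("reduction ratio must divide channel count")
        if self.w1.shape != (self.c // self.r, self.c) or self.w2.shape != (self.c, self.c // self.r):
            raise ValueError("SE weight shapes inconsistent with (C, r)")


# ------------------------------------------------------------------ functional
def sinusoidal_encoding(n_tokens: int, d_model: int) -> np.ndarray:
    """Fixed sine/cosine positional encodings, one row per token position."""
    position = np.arange(n_tokens, dtype=np.float64)[:, None]
    div = np.exp(np.arange(0, d_model, 2, dtype=np.float64) * (-math.log(10000.0) / d_model))
    pe = np.zeros((n_tokens, d_model))
    pe[:, 0::2] = np.sin(position * div)
    pe[:, 1::2] = np.cos(position * div)
    return pe


def to_tokens(v: np.ndarray, n_tokens: int = 8, d_model: int = 32,
              positional_encoding: bool = False) -> np.ndarray:
    """Row-major reshape of a flat feature vector into a token matrix."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] != n_tokens * d_model:
        raise ValueError(f"expected last dimension {n_tokens * d_model}, got {v.shape[-1]}")
    x = v.reshape(*v.shape[:-1], n_tokens, d_model)
    if positional_encoding:
        x = x + sinusoidal_encoding(n_tokens, d_model)
    return x


def pool_tokens(x: np.ndarray) -> np.ndarray:
    """Mean over the token axis (second-to-last)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-2] == 0:
        raise ValueError("cannot pool an empty token set")
    return x.mean(axis=-2)


def _mha_graph(x: Tensor, w_q: Tensor, w_k: Tensor, w_v: Tensor, w_o: Tensor,
               h: int, d_k: int, dropout_rate: float = 0.0,
               rng: np.random.Generator | None = None):
    """Attention on a batched token tensor (B, n, d). Returns (out, weights)."""
    b, n, d = x.shape

    def split_heads(t: Tensor) -> Tensor:
        return t.reshape(b, n, h, d_k).transpose((0, 2, 1, 3))

    q = split_heads(x @ w_q)
    k = split_heads(x @ w_k)
    v = split_heads(x @ w_v)
    scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(d_k))
    attn = softmax(scores, axis=-1)
    weights = attn.data.copy()
    if dropout_rate > 0.0:
        if rng is None:
            raise ValueError("dropout requires a random generator")
        mask = (rng.random(attn.shape) >= dropout_rate) / (1.0 - dropout_rate)
        attn = attn * Tensor(mask)
    heads = attn @ v  # (B, h, n, d_k)
    concat = heads.transpose((0, 2, 1, 3)).reshape(b, n, h * d_k)
    return concat @ w_o, weights


def multi_head_attention(x: np.ndarray, params: MHAParams) -> np.ndarray:
    """Deterministic multi-head self-attention on a single (n, d_model) matrix.

    Per head: ``softmax((X Wq)(X Wk)^T / sqrt(d_k)) (X Wv)``; head outputs are
    concatenated and projected by ``w_o``. Use
    :func:`multi_head_attention_with_weights` to also retrieve the attention
    maps.
    """
    return multi_head_attention_with_weights(x, params)[0]


def multi_head_attention_with_weights(x: np.ndarray, params: MHAParams):
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != params.w_q.shape[0]:
        raise ValueError("token matrix incompatible with attention parameters")
    out, w = _mha_graph(Tensor(x[None]), Tensor(params.w_q), Tensor(params.w_k),
                        Tensor(params.w_v), Tensor(params.w_o), params.h, params.d_k)
    return out.data[0], w[0]


def se_recalibrate(f: np.ndarray, params: SEParams):
    """Channel-wise recalibration of a C-vector (or batch of them).

    The squeeze step is the identity here because each channel holds a single
    scalar (H = W = 1). Returns ``(f_tilde, gates)`` with
    ``gates = sigmoid(W2 relu(W1 f))`` and ``f_tilde = gates * f``.
    """
    f = np.asarray(f, dtype=np.float64)
    if f.shape[-1] != params.c:
        raise ValueError(f"expected {params.c} channels, got {f.shape[-1]}")
    hidden = np.maximum(f @ params.w1.T, 0.0)
    gates = 1.0 / (1.0 + np.exp(-(hidden @ params.w2.T)))
    return gates * f, gates


# --------------------------------------------------------------------- layers
def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.w = Tensor(_uniform_fan_in(rng, d_in, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(_uniform_fan_in(rng, d_in, (d_out,)), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.w
        return out + self.b if self.b is not None else out

    def parameters(self):
        return [self.w] if self.b is None else [self.w, self.b]


class BatchNorm:
    """1-d batch normalization with running statistics (momentum 0.1, eps 1e-5)."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered ** 2.0).mean(axis=0, keepdims=True)
            x_hat = centered * ((var + self.eps) ** -0.5)
            n = x.shape[0]
            unbiased = var.data[0] * (n / max(n - 1, 1))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * x.data.mean(axis=0)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            x_hat = (x + Tensor(-self.running_mean)) * Tensor((self.running_var + self.eps) ** -0.5)
        return x_hat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2.0).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


def _dropout(x: Tensor, rate: float, train: bool, rng: np.random.Generator | None) -> Tensor:
    if not train or rate <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout requires a random generator")
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


# -------------------------------------------------------------------- network
class DiliClassifier:
    """Full network; weights live in autodiff tensors.

    The forward pass is exposed both whole (:meth:`forward_logit`,
    :meth:`predict_proba`) and stage by stage (:meth:`expand_features`,
    :meth:`encode_tokens`, ...) so each published block can be inspected and
    tested in isolation. After any forward pass the attention maps and SE
    gates of that pass are available as ``last_attention`` (B, h, n, n) and
    ``last_gates`` (B, C).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        rng = rng if rng is not None else np.random.default_rng(0)
        c = cfg
        self.proj = Linear(c.fingerprint_bits, c.input_dim, rng) if c.input_mode == "project" else None
        self.fc1 = Linear(c.input_dim, c.expansion_dim, rng)
        self.bn1 = BatchNorm(c.expansion_dim)
        self.fc2 = Linear(c.expansion_dim, c.expansion_dim, rng)
        self.bn2 = BatchNorm(c.expansion_dim)
        d_k = c.d_model // c.n_heads
        self.w_q = Tensor(_uniform_fan_in(rng, c.d_model, (c.d_model, c.d_model)), requires_grad=True)
        self.w_k = Tensor(_uniform_fan_in(rng, c.d_model, (c.d_model, c.d_model)), requires_grad=True)
        self.w_v = Tensor(_uniform_fan_in(rng, c.d_model, (c.d_model, c.d_model)), requires_grad=True)
        self.w_o = Tensor(_uniform_fan_in(rng, c.d_model, (c.d_model, c.d_model)), requires_grad=True)
        self.d_k = d_k
        self.ln1 = LayerNorm(c.d_model)
        self.ffn1 = Linear(c.d_model, c.ffn_dim, rng)
        self.ffn2 = Linear(c.ffn_dim, c.d_model, rng)
        self.ln2 = LayerNorm(c.d_model)
        self.post = Linear(c.d_model, c.post_dim, rng)
        self.bn3 = BatchNorm(c.post_dim)
        bottleneck = c.post_dim // c.se_ratio
        self.se_w1 = Tensor(_uniform_fan_in(rng, c.post_dim, (bottleneck, c.post_dim)), requires_grad=True)
        self.se_w2 = Tensor(_uniform_fan_in(rng, bottleneck, (c.post_dim, bottleneck)), requires_grad=True)
        self.skip = Linear(c.input_dim, c.post_dim, rng)
        self.out = Linear(c.post_dim, 1, rng)
        self.pe = sinusoidal_encoding(c.n_tokens, c.d_model) if c.positional_encoding else None
        self.last_attention: np.ndarray | None = None
        self.last_gates: np.ndarray | None = None

    # ------------------------------------------------------------- parameters
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in (self.proj, self.fc1, self.bn1, self.fc2, self.bn2, self.ln1,
                      self.ffn1, self.ffn2, self.ln2, self.post, self.bn3,
                      self.skip, self.out):
            if layer is not None:
                params.extend(layer.parameters())
        params.extend([self.w_q, self.w_k, self.w_v, self.w_o, self.se_w1, self.se_w2])
        return params

    def mha_params(self) -> MHAParams:
        return MHAParams(self.cfg.n_heads, self.d_k, self.w_q.data, self.w_k.data,
                         self.w_v.data, self.w_o.data)

    def se_params(self) -> SEParams:
        return SEParams(self.cfg.post_dim, self.cfg.se_ratio, self.se_w1.data, self.se_w2.data)

    # ----------------------------------------------------------- graph stages
    def _expand(self, x: Tensor, train: bool, rng) -> Tensor:
        c = self.cfg
        h = _dropout(self.bn1(self.fc1(x), train).leaky_relu(c.leaky_slope),
                     c.dropout_expansion, train, rng)
        return _dropout(self.bn2(self.fc2(h), train).leaky_relu(c.leaky_slope),
                        c.dropout_expansion, train, rng)

    def _encoder_layer(self, x: Tensor, train: bool, rng) -> Tensor:
        c = self.cfg
        attn, weights = _mha_graph(x, self.w_q, self.w_k, self.w_v, self.w_o,
                                   c.n_heads, self.d_k,
                                   c.dropout_transformer if train else 0.0, rng)
        self.last_attention = weights
        x1 = self.ln1(x + _dropout(attn, c.dropout_transformer, train, rng))
        ffn = self.ffn2(self.ffn1(x1).relu())
        return self.ln2(x1 + _dropout(ffn, c.dropout_transformer, train, rng))

    def _forward_graph(self, x: np.ndarray, train: bool, rng=None) -> Tensor:
        c = self.cfg
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        expected = c.fingerprint_bits if c.input_mode == "project" else c.input_dim
        if x.shape[1] != expected:
            raise ValueError(f"expected input width {expected}, got {x.shape[1]}")
        xt = Tensor(x)
        if self.proj is not None:
            xt = self.proj(xt)
        v = self._expand(xt, train, rng)
        tokens = v.reshape(x.shape[0], c.n_tokens, c.d_model)
        if self.pe is not None:
            tokens = tokens + Tensor(self.pe)
        enc = self._encoder_layer(tokens, train, rng)
        pooled = enc.mean(axis=1)
        m = _dropout(self.bn3(self.post(pooled), train).leaky_relu(c.leaky_slope),
                     c.dropout_expansion, train, rng)
        hidden = (m @ self.se_w1.transpose((1, 0))).relu()
        gates = (hidden @ self.se_w2.transpose((1, 0))).sigmoid()
        self.last_gates = gates.data.copy()
        head = m + gates * m + self.skip(xt)
        return self.out(head).reshape(x.shape[0])

    # -------------------------------------------------------------- inference
    def expand_features(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """The two-block 128->256 expansion on its own (numpy in, numpy out)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.cfg.input_dim:
            raise ValueError(f"expected input width {self.cfg.input_dim}")
        out = self._expand(Tensor(x), train, rng).data
        return out

    def encode_tokens(self, tokens: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """The Transformer encoder layer on an (..., n_tokens, d_model) array."""
        t = np.asarray(tokens, dtype=np.float64)
        squeeze = t.ndim == 2
        if squeeze:
            t = t[None]
        if t.shape[-2:] != (self.cfg.n_tokens, self.cfg.d_model):
            raise ValueError("token matrix shape mismatch")
        out = self._encoder_layer(Tensor(t), train, rng).data
        return out[0] if squeeze else out

    def forward_logit(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        logits = self._forward_graph(x, train, rng).data
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode DILI probability per row; class 1 iff >= 0.5."""
        return 1.0 / (1.0 + np.exp(-self.forward_logit(x, train=False)))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x) >= 0.5).astype(int)

    # ------------------------------------------------------------------ state
    def state_dict(self) -> dict[str, np.ndarray]:
        named = self._named_tensors()
        state = {k: t.data.copy() for k, t in named.items()}
        for bn_name, bn in (("bn1", self.bn1), ("bn2", self.bn2), ("bn3", self.bn3)):
            state[f"{bn_name}.running_mean"] = bn.running_mean.copy()
            state[f"{bn_name}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = self._named_tensors()
        expected = set(named) | {f"bn{i}.running_{s}" for i in (1, 2, 3) for s in ("mean", "var")}
        if set(state) != expected:
            missing = expected ^ set(state)
            raise ValueError(f"checkpoint does not match this configuration: {sorted(missing)[:4]}")
        for key, tensor in named.items():
            arr = np.asarray(state[key], dtype=np.float64)
            if arr.shape != tensor.data.shape:
                raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {tensor.data.shape}")
            tensor.data = arr.copy()
        for bn_name, bn in (("bn1", self.bn1), ("bn2", self.bn2), ("bn3", self.bn3)):
            bn.running_mean = np.asarray(state[f"{bn_name}.running_mean"], dtype=np.float64).copy()
            bn.running_var = np.asarray(state[f"{bn_name}.running_var"], dtype=np.float64).copy()

    def _named_tensors(self) -> dict[str, Tensor]:
        named: dict[str, Tensor] = {}
        layers = {"fc1": self.fc1, "fc2": self.fc2, "ffn1": self.ffn1, "ffn2": self.ffn2,
                  "post": self.post, "skip": self.skip, "out": self.out}
        if self.proj is not None:
            layers["proj"] = self.proj
        for name, lin in layers.items():
            named[f"{name}.w"] = lin.w
            named[f"{name}.b"] = lin.b
        for name, norm in (("bn1", self.bn1), ("bn2", self.bn2), ("bn3", self.bn3),
                           ("ln1", self.ln1), ("ln2", self.ln2)):
            named[f"{name}.gamma"] = norm.gamma
            named[f"{name}.beta"] = norm.beta
        named.update({"w_q": self.w_q, "w_k": self.w_k, "w_v": self.w_v, "w_o": self.w_o,
                      "se_w1": self.se_w1, "se_w2": self.se_w2})
        return named
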