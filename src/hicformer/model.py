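"""Graph autoencoder: edge-aware graph-transformer encoder + attention UNet.

The encoder stacks graph-transformer convolutions in which each node
aggregates its neighbours' features weighted by scaled-dot-product attention
that incorporates the Hi-C edge weight:

    x'_i = W1 x_i + sum_{j != i} a_ij (W2 x_j + W5 e_ij)
    a_ij = softmax_j( (W3 x_i)^T (W4 x_j + W5 e_ij) / sqrt(d) )

with W5 shared between the attention coefficients and the messages.  The
softmax runs over the node's observed neighbour set by default (matching the
sparse-input motivation); a dense variant attending over all other nodes is
available behind ``dense_attention``.

The decoder forms the inner-product contact-probability map P = X' X'^T and
translates it into a dense contact window with a UNet: three Down blocks
(stride-2 convolutions), a Middle block with token self-attention

    F_M = softmax( (Wq F)(Wk F)^T / sqrt(d_k) ) Wv F

three Up blocks (nearest-neighbour upsample + convolution) that fuse the
same-level Down features through cross-attention (token counts permitting,
otherwise concatenation), and a group-norm / swish / conv head.  The output
window is symmetrized as (O + O^T) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .graphs import HiCGraph
from .nn import Linear, Module, Tensor

__all__ = [
    "ModelConfig",
    "GraphTransformerLayer",
    "GraphEncoder",
    "contact_probability",
    "self_attention",
    "AttentionUNet",
    "HiCAutoencoder",
]


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    Channel widths and layer counts are configurable; the defaults target a
    256-bin window.  ``max_attn_tokens`` bounds the token count at which Up
    blocks use cross-attention (quadratic cost); coarser levels fall back to
    concatenated skip connections.
    """

    in_features: int = 13
    hidden: int = 32
    n_heads: int = 4
    n_layers: int = 2
    unet_channels: tuple[int, int, int] = (64, 128, 256)
    window_size: int = 256
    max_attn_tokens: int = 1024
    dense_attention: bool = False
    residual: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["unet_channels"] = list(self.unet_channels)
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        d["unet_channels"] = tuple(d["unet_channels"])
        return ModelConfig(**d)


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------

class GraphTransformerLayer(Module):
    """One edge-aware graph-transformer convolution (multi-head)."""

    def __init__(self, in_dim: int, hidden: int, n_heads: int,
                 rng: np.random.Generator):
        if hidden % n_heads:
            raise ValueError("hidden width must divide into heads")
        self.n_heads = n_heads
        self.head_dim = hidden // n_heads
        self.hidden = hidden
        self.w1 = Linear(in_dim, hidden, rng)           # self term
        self.w2 = Linear(in_dim, hidden, rng)           # neighbour message
        self.w3 = Linear(in_dim, hidden, rng)           # query
        self.w4 = Linear(in_dim, hidden, rng)           # key
        self.w5 = Linear(1, hidden, rng, bias=False)    # edge weight (shared)

    def __call__(self, X: Tensor, edge_index: np.ndarray,
                 edge_weight: np.ndarray, dense: bool = False) -> Tensor:
        if X.shape[1] != self.w1.weight.shape[0]:
            raise ValueError(
                f"feature width {X.shape[1]} does not match layer input "
                f"width {self.w1.weight.shape[0]}")
        if dense:
            return self._dense(X, edge_index, edge_weight)
        return self._sparse(X, edge_index, edge_weight)

    def _sparse(self, X: Tensor, edge_index: np.ndarray,
                edge_weight: np.ndarray) -> Tensor:
        n = X.shape[0]
        h, dh = self.n_heads, self.head_dim
        mask = edge_index[0] != edge_index[1]      # self-loops feed degree,
        tgt = edge_index[0][mask]                  # not attention
        src = edge_index[1][mask]
        out = self.w1(X)
        if tgt.size == 0:
            return out
        e_emb = self.w5(Tensor(edge_weight[mask][:, None]))
        q_e = nn.take(self.w3(X), tgt)
        k_e = nn.take(self.w4(X), src) + e_emb
        score = (q_e * k_e).reshape(-1, h, dh).sum(axis=2) / math.sqrt(dh)
        # numerically stable segment softmax over each node's neighbour set
        seg_max = np.full((n, h), -np.inf)
        np.maximum.at(seg_max, tgt, score.data)
        s = (score - Tensor(seg_max[tgt])).exp()
        denom = nn.segment_sum(s, tgt, n)
        a = s / nn.take(denom, tgt)
        v_e = (nn.take(self.w2(X), src) + e_emb).reshape(-1, h, dh)
        msg = (a.reshape(-1, h, 1) * v_e).reshape(-1, self.hidden)
        return out + nn.segment_sum(msg, tgt, n)

    def _dense(self, X: Tensor, edge_index: np.ndarray,
               edge_weight: np.ndarray) -> Tensor:
        n = X.shape[0]
        h, dh = self.n_heads, self.head_dim
        W = np.zeros((n, n))
        W[edge_index[0], edge_index[1]] = edge_weight
        e_emb = self.w5(Tensor(W.reshape(-1, 1))).reshape(n, n, h, dh)
        q = self.w3(X).reshape(n, 1, h, dh)
        k = self.w4(X).reshape(1, n, h, dh) + e_emb
        score = (q * k).sum(axis=3) / math.sqrt(dh)        # (n, n, h)
        diag_mask = np.where(np.eye(n, dtype=bool), -1e30, 0.0)
        score = score + Tensor(diag_mask[:, :, None])
        a = nn.softmax(score, axis=1)
        v = self.w2(X).reshape(1, n, h, dh) + e_emb
        msg = (a.reshape(n, n, h, 1) * v).sum(axis=1).reshape(n, self.hidden)
        return self.w1(X) + msg


class GraphEncoder(Module):
    """Stack of graph-transformer layers with residual connections."""

    def __init__(self, in_features: int, hidden: int, n_layers: int,
                 n_heads: int, rng: np.random.Generator,
                 residual: bool = True):
        self.input_proj = Linear(in_features, hidden, rng)
        self.layers = [GraphTransformerLayer(hidden, hidden, n_heads, rng)
                       for _ in range(n_layers)]
        self.residual = residual

    def __call__(self, graph: HiCGraph, dense: bool = False) -> Tensor:
        X = self.input_proj(Tensor(graph.node_features))
        for layer in self.layers:
            update = nn.relu(layer(X, graph.edge_index, graph.edge_weight,
                                   dense=dense))
            X = X + update if self.residual else update
        return X


def contact_probability(latent: Tensor) -> Tensor:
    """Inner-product contact-probability map ``P = X' X'^T`` (symmetric PSD)."""
    return latent @ latent.T


# ---------------------------------------------------------------------------
# Decoder
# ---------------------------------------------------------------------------

def self_attention(tokens: Tensor, wq: Linear, wk: Linear,
                   wv: Linear) -> Tensor:
    """Scaled dot-product self-attention over a (T, C) token matrix."""
    q = wq(tokens)
    k = wk(tokens)
    v = wv(tokens)
    dk = k.shape[1]
    scores = (q @ k.T) / math.sqrt(dk)
    return nn.softmax(scores, axis=1) @ v


def cross_attention(queries: Tensor, context: Tensor, wq: Linear,
                    wk: Linear, wv: Linear) -> Tensor:
    """Attention with queries from one token set and keys/values from another."""
    q = wq(queries)
    k = wk(context)
    v = wv(context)
    dk = k.shape[1]
    scores = (q @ k.T) / math.sqrt(dk)
    return nn.softmax(scores, axis=1) @ v


def _norm_groups(channels: int) -> int:
    for g in (8, 4, 2):
        if channels % g == 0:
            return g
    return 1


class _ConvBlock(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / ((cin + cout) * 9))
        self.weight = Tensor(rng.uniform(-limit, limit, (cout, cin, 3, 3)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.norm = nn.GroupNorm(_norm_groups(cout), cout)

    def __call__(self, x: Tensor) -> Tensor:
        return nn.swish(self.norm(nn.conv2d(x, self.weight, self.bias,
                                            stride=1, padding=1)))


class _Conv(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1):
        limit = math.sqrt(6.0 / ((cin + cout) * 9))
        self.weight = Tensor(rng.uniform(-limit, limit, (cout, cin, 3, 3)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return nn.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=1)


class _AttnProj(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.wq = Linear(channels, channels, rng, bias=False)
        self.wk = Linear(channels, channels, rng, bias=False)
        self.wv = Linear(channels, channels, rng, bias=False)


def _to_tokens(x: Tensor) -> tuple[Tensor, tuple[int, int, int]]:
    c, hh, ww = x.shape
    return x.reshape(c, hh * ww).T, (c, hh, ww)


def _from_tokens(t: Tensor, shape: tuple[int, int, int]) -> Tensor:
    c, hh, ww = shape
    return t.T.reshape(c, hh, ww)


class AttentionUNet(Module):
    """UNet over the contact-probability map with attention blocks.

    Three Down levels halve the spatial size (256 -> 32 at defaults); the
    Middle block applies token self-attention; Up levels double the size
    and fuse same-level Down features via cross-attention where the level's
    token count (at the configured ``window_size``) is at most
    ``max_attn_tokens``, and via concatenation + convolution otherwise.
    The fusion mode per level is fixed at construction so every allocated
    parameter participates in the forward pass.
    """

    def __init__(self, channels: tuple[int, int, int],
                 rng: np.random.Generator, max_attn_tokens: int = 1024,
                 window_size: int = 256):
        c1, c2, c3 = channels
        self.channels = channels
        self.max_attn_tokens = max_attn_tokens
        self.stem = _Conv(1, c1, rng)
        self.down_convs = [_ConvBlock(c1, c1, rng), _ConvBlock(c2, c2, rng),
                           _ConvBlock(c3, c3, rng)]
        self.down_samplers = [_Conv(c1, c2, rng, stride=2),
                              _Conv(c2, c3, rng, stride=2),
                              _Conv(c3, c3, rng, stride=2)]
        self.mid_conv1 = _ConvBlock(c3, c3, rng)
        self.mid_attn = _AttnProj(c3, rng)
        self.mid_conv2 = _ConvBlock(c3, c3, rng)
        # up level l receives the skip of down level l (channels c1,c2,c3)
        self.up_convs = [_Conv(c2, c1, rng), _Conv(c3, c2, rng),
                         _Conv(c3, c3, rng)]
        self.attn_at_level = [
            (window_size // 2 ** level) ** 2 <= max_attn_tokens
            for level in range(3)]
        self.up_fusions = [
            _AttnProj(c, rng) if self.attn_at_level[level]
            else _Conv(2 * c, c, rng)
            for level, c in enumerate((c1, c2, c3))]
        self.up_norms = [nn.GroupNorm(_norm_groups(c1), c1),
                         nn.GroupNorm(_norm_groups(c2), c2),
                         nn.GroupNorm(_norm_groups(c3), c3)]
        self.head_norm = nn.GroupNorm(_norm_groups(c1), c1)
        self.head_conv = _Conv(c1, 1, rng)

    def __call__(self, P: Tensor) -> Tensor:
        size = P.shape[0]
        if P.shape != (size, size):
            raise ValueError("P must be square")
        if size % 8:
            raise ValueError(f"window size {size} must be divisible by 8")
        x = self.stem(P.reshape(1, size, size))
        skips: list[Tensor] = []
        for conv, down in zip(self.down_convs, self.down_samplers):
            x = conv(x)
            skips.append(x)
            x = down(x)
        # middle block: conv, token self-attention (residual), conv
        x = self.mid_conv1(x)
        tokens, shape = _to_tokens(x)
        attn = self_attention(tokens, self.mid_attn.wq, self.mid_attn.wk,
                              self.mid_attn.wv)
        x = x + _from_tokens(attn, shape)
        x = self.mid_conv2(x)
        for level in (2, 1, 0):
            x = nn.upsample_nearest2d(x, 2)
            x = self.up_convs[level](x)
            skip = skips[level]
            fusion = self.up_fusions[level]
            if self.attn_at_level[level]:
                q_tok, shape = _to_tokens(x)
                kv_tok, _ = _to_tokens(skip)
                fused = cross_attention(q_tok, kv_tok, fusion.wq, fusion.wk,
                                        fusion.wv)
                x = x + _from_tokens(fused, shape)
            else:
                x = fusion(nn.concat([x, skip], axis=0))
            x = nn.swish(self.up_norms[level](x))
        out = self.head_conv(nn.swish(self.head_norm(x)))
        out = out.reshape(size, size)
        return (out + out.T) * 0.5


# ---------------------------------------------------------------------------
# Full autoencoder
# ---------------------------------------------------------------------------

class HiCAutoencoder(Module):
    """Encoder + inner product + UNet decoder, trained jointly."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = GraphEncoder(config.in_features, config.hidden,
                                    config.n_layers, config.n_heads, rng,
                                    residual=config.residual)
        self.decoder = AttentionUNet(config.unet_channels, rng,
                                     max_attn_tokens=config.max_attn_tokens,
                                     window_size=config.window_size)

    def __call__(self, graph: HiCGraph) -> Tensor:
        latent = self.encoder(graph, dense=self.config.dense_attention)
        P = contact_probability(latent)
        return self.decoder(P)

    def predict(self, graph: HiCGraph) -> np.ndarray:
        """Forward pass returning a plain array (no gradient tape)."""
        return self(graph).data
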