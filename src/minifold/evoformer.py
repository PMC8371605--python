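"""The Evoformer trunk.

Iterated blocks exchange information between the MSA representation
(N_seq × N_res × c_m) and the pair representation (N_res × N_res × c_z):
the outer-product mean pushes MSA covariation into the pair stack in every
block; pair-biased row attention closes the loop back into the MSA; and the
two triangle updates (multiplicative and attention) propagate information
around triangles of residues so the pair representation can move towards
geometric consistency.

Every branch is pre-layer-normalized, gated where the architecture calls
for it, and added residually. Final output projections are zero-initialized
so a freshly initialized block is the identity map.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import ParamStore, Tensor

__all__ = [
    "outer_product_mean", "msa_row_attention_with_pair_bias",
    "msa_column_attention", "triangle_multiplicative_update",
    "triangle_self_attention", "transition", "evoformer_block",
    "evoformer_stack",
]

_NEG_INF = -1e9


def _ln(store: ParamStore, name: str, x: Tensor, width: int) -> Tensor:
    gamma = store.get(f"{name}.scale", (width,), "ones")
    beta = store.get(f"{name}.offset", (width,), "zeros")
    return nn.layer_norm(x, gamma, beta)


def outer_product_mean(store: ParamStore, p: str, m: Tensor, cfg: ModelConfig,
                       seq_mask: np.ndarray | None = None) -> Tensor:
    """Pair update from the MSA: mean over sequences of the outer product of
    two per-residue linear projections, flattened and mapped to c_z."""
    s, r, c = m.shape
    hid = min(16, cfg.c_m)
    mn = _ln(store, f"{p}.ln", m, c)
    a = nn.linear(store, f"{p}.a", mn, c, hid)
    b = nn.linear(store, f"{p}.b", mn, c, hid)
    if seq_mask is not None:
        w = np.asarray(seq_mask, float)[:, None, None]
        a = a * w
        b = b * w
        denom = max(float(w.sum()), 1.0)
    else:
        denom = float(s)
    outer = (
        a.reshape(s, r * hid).swapaxes(0, 1) @ b.reshape(s, r * hid)
    )  # (r*hid, r*hid) with index (i,p),(j,q)
    outer = outer.reshape(r, hid, r, hid).transpose((0, 2, 1, 3)).reshape(r, r, hid * hid)
    outer = outer / denom
    return nn.linear(store, f"{p}.out", outer, hid * hid, cfg.c_z, init="zeros")


def _heads(x: Tensor, n_heads: int, d: int):
    """(..., R, h*d) -> (..., h, R, d)"""
    *lead, r, _ = x.shape
    return x.reshape(*lead, r, n_heads, d).swapaxes(-2, -3)


def msa_row_attention_with_pair_bias(
    store: ParamStore, p: str, m: Tensor, z: Tensor, cfg: ModelConfig,
    res_mask: np.ndarray | None = None, return_weights: bool = False,
):
    """Per-sequence (row) attention over residues, with per-head scalar
    logits projected from the pair representation added before softmax."""
    s, r, c = m.shape
    h = cfg.msa_heads
    d = c // h
    mn = _ln(store, f"{p}.ln", m, c)
    q = _heads(nn.linear(store, f"{p}.q", mn, c, h * d, bias=False), h, d)
    k = _heads(nn.linear(store, f"{p}.k", mn, c, h * d, bias=False), h, d)
    v = _heads(nn.linear(store, f"{p}.v", mn, c, h * d, bias=False), h, d)
    zn = _ln(store, f"{p}.ln_z", z, cfg.c_z)
    bias = nn.linear(store, f"{p}.pair_bias", zn, cfg.c_z, h, bias=False)  # (r,r,h)
    logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))  # (s,h,r,r)
    logits = logits + bias.transpose((2, 0, 1))
    if res_mask is not None:
        logits = logits + _NEG_INF * (1.0 - np.asarray(res_mask, float))[None, None, None, :]
    attn = nn.softmax(logits, axis=-1)
    o = (attn @ v).swapaxes(-2, -3).reshape(s, r, h * d)
    gate = nn.sigmoid(nn.linear(store, f"{p}.gate", mn, c, h * d, bias_init="ones"))
    update = nn.linear(store, f"{p}.out", o * gate, h * d, c, init="zeros")
    if return_weights:
        return update, attn.data
    return update


def msa_column_attention(
    store: ParamStore, p: str, m: Tensor, cfg: ModelConfig,
    seq_mask: np.ndarray | None = None, return_weights: bool = False,
):
    """Attention along the sequence axis within each alignment column."""
    s, r, c = m.shape
    h = cfg.msa_heads
    d = c // h
    mn = _ln(store, f"{p}.ln", m, c)
    mt = mn.swapaxes(0, 1)  # (r, s, c)
    q = _heads(nn.linear(store, f"{p}.q", mt, c, h * d, bias=False), h, d)
    k = _heads(nn.linear(store, f"{p}.k", mt, c, h * d, bias=False), h, d)
    v = _heads(nn.linear(store, f"{p}.v", mt, c, h * d, bias=False), h, d)
    logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))  # (r,h,s,s)
    if seq_mask is not None:
        logits = logits + _NEG_INF * (1.0 - np.asarray(seq_mask, float))[None, None, None, :]
    attn = nn.softmax(logits, axis=-1)
    o = (attn @ v).swapaxes(-2, -3).reshape(r, s, h * d)
    gate = nn.sigmoid(nn.linear(store, f"{p}.gate", mt, c, h * d, bias_init="ones"))
    update = nn.linear(store, f"{p}.out", o * gate, h * d, c, init="zeros").swapaxes(0, 1)
    if return_weights:
        return update, attn.data
    return update


def triangle_multiplicative_update(
    store: ParamStore, p: str, z: Tensor, cfg: ModelConfig, mode: str,
    res_mask: np.ndarray | None = None,
) -> Tensor:
    """Update edge (i,j) from the two edges completing a triangle through
    every third residue k: (i,k),(j,k) for ``outgoing`` or (k,i),(k,j) for
    ``incoming``. Gated linear projections, combined per channel, then
    normalized, gated and projected back."""
    if mode not in ("outgoing", "incoming"):
        raise ValueError(f"invalid mode {mode!r}")
    r, _, c = z.shape
    hid = c  # hidden channel width equals c_z
    zn = _ln(store, f"{p}.ln", z, c)
    a = nn.sigmoid(nn.linear(store, f"{p}.a_gate", zn, c, hid, bias_init="ones")) * \
        nn.linear(store, f"{p}.a", zn, c, hid)
    b = nn.sigmoid(nn.linear(store, f"{p}.b_gate", zn, c, hid, bias_init="ones")) * \
        nn.linear(store, f"{p}.b", zn, c, hid)
    if res_mask is not None:
        w = np.asarray(res_mask, float)
        a = a * (w[:, None, None] * w[None, :, None])
        b = b * (w[:, None, None] * w[None, :, None])
    at = a.transpose((2, 0, 1))  # (c, i, k)
    bt = b.transpose((2, 0, 1))  # (c, j, k)
    if mode == "outgoing":
        prod = at @ bt.swapaxes(-1, -2)       # sum_k a[i,k] b[j,k]
    else:
        prod = at.swapaxes(-1, -2) @ bt       # sum_k a[k,i] b[k,j]
    prod = prod.transpose((1, 2, 0))           # (i, j, c)
    gate = nn.sigmoid(nn.linear(store, f"{p}.gate", zn, c, c, bias_init="ones"))
    hidden = _ln(store, f"{p}.ln_out", prod, hid)
    return gate * nn.linear(store, f"{p}.out", hidden, hid, c, init="zeros")


def triangle_self_attention(
    store: ParamStore, p: str, z: Tensor, cfg: ModelConfig, mode: str,
    res_mask: np.ndarray | None = None, return_weights: bool = False,
):
    """Axial attention on the pair representation with an extra logit bias
    projected from the triangle's third edge.

    ``starting``: edge (i,j) attends over k to edges (i,k), biased by the
    edge (j,k). ``ending``: edge (i,j) attends over k to edges (k,j),
    biased by the edge (k,i) — implemented as the starting-node update on
    the transposed pair representation.
    """
    if mode not in ("starting", "ending"):
        raise ValueError(f"invalid mode {mode!r}")
    if mode == "ending":
        out = triangle_self_attention(
            store, p, z.swapaxes(0, 1), cfg, "starting", res_mask, return_weights
        )
        if return_weights:
            return out[0].swapaxes(0, 1), out[1]
        return out.swapaxes(0, 1)

    r, _, c = z.shape
    h = cfg.pair_heads
    d = max(c // h, 1)
    zn = _ln(store, f"{p}.ln", z, c)
    q = _heads(nn.linear(store, f"{p}.q", zn, c, h * d, bias=False), h, d)  # (i,h,j,d)
    k = _heads(nn.linear(store, f"{p}.k", zn, c, h * d, bias=False), h, d)
    v = _heads(nn.linear(store, f"{p}.v", zn, c, h * d, bias=False), h, d)
    bias = nn.linear(store, f"{p}.edge_bias", zn, c, h, bias=False)  # (j,k,h)
    logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))  # (i,h,j,k)
    logits = logits + bias.transpose((2, 0, 1))             # broadcast over i
    if res_mask is not None:
        logits = logits + _NEG_INF * (1.0 - np.asarray(res_mask, float))[None, None, None, :]
    attn = nn.softmax(logits, axis=-1)
    o = (attn @ v).swapaxes(-2, -3).reshape(r, r, h * d)
    gate = nn.sigmoid(nn.linear(store, f"{p}.gate", zn, c, h * d, bias_init="ones"))
    update = nn.linear(store, f"{p}.out", o * gate, h * d, c, init="zeros")
    if return_weights:
        return update, attn.data
    return update


def transition(store: ParamStore, p: str, x: Tensor, width: int,
               factor: int = 4) -> Tensor:
    """Position-wise two-layer MLP, widened by ``factor``."""
    xn = _ln(store, f"{p}.ln", x, width)
    hidden = nn.relu(nn.linear(store, f"{p}.in", xn, width, factor * width, init="relu"))
    return nn.linear(store, f"{p}.out", hidden, factor * width, width, init="zeros")


def evoformer_block(
    store: ParamStore, p: str, m: Tensor, z: Tensor, cfg: ModelConfig,
    res_mask: np.ndarray | None = None, seq_mask: np.ndarray | None = None,
) -> tuple[Tensor, Tensor]:
    """One full block; all branches residual, in the order: MSA row
    attention (pair-biased), MSA column attention, MSA transition,
    outer-product mean into the pair stack, triangle multiplicative
    outgoing/incoming, triangle attention starting/ending, pair transition."""
    m = m + msa_row_attention_with_pair_bias(store, f"{p}.row", m, z, cfg, res_mask)
    m = m + msa_column_attention(store, f"{p}.col", m, cfg, seq_mask)
    m = m + transition(store, f"{p}.msa_trans", m, cfg.c_m, cfg.transition_factor)
    z = z + outer_product_mean(store, f"{p}.opm", m, cfg, seq_mask)
    z = z + triangle_multiplicative_update(store, f"{p}.tri_out", z, cfg, "outgoing", res_mask)
    z = z + triangle_multiplicative_update(store, f"{p}.tri_in", z, cfg, "incoming", res_mask)
    z = z + triangle_self_attention(store, f"{p}.tri_start", z, cfg, "starting", res_mask)
    z = z + triangle_self_attention(store, f"{p}.tri_end", z, cfg, "ending", res_mask)
    z = z + transition(store, f"{p}.pair_trans", z, cfg.c_z, cfg.transition_factor)
    return m, z


def single_representation(store: ParamStore, m: Tensor, cfg: ModelConfig) -> Tensor:
    """The single representation: linear projection of the first MSA row."""
    return nn.linear(store, "single_proj", m[0], cfg.c_m, cfg.c_s)


def evoformer_stack(
    store: ParamStore, m: Tensor, z: Tensor, cfg: ModelConfig,
    n_blocks: int | None = None,
    res_mask: np.ndarray | None = None, seq_mask: np.ndarray | None = None,
    collect_intermediates: bool = False,
):
    """Apply ``n_blocks`` independent-parameter blocks in series.

    Returns ``(m, z, single)`` and, when requested, the per-block ``(m, z)``
    intermediates for trajectory probing.
    """
    n_blocks = cfg.n_blocks if n_blocks is None else n_blocks
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    intermediates = []
    for b in range(n_blocks):
        m, z = evoformer_block(store, f"block{b}", m, z, cfg, res_mask, seq_mask)
        if collect_intermediates:
            intermediates.append((m, z))
    single = single_representation(store, m, cfg)
    if collect_intermediates:
        return m, z, single, intermediates
    return m, z, single
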