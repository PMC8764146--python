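"""Multi-scale self-transformer (MsST) block.

The block fuses mid-level encoder feature maps (downsampled and projected
to the top stage's shape) into a query map, and attends over the top-stage
features as key/value:

    F_A   = sum_i Conv3x3(Downsample(F_i))          (cross-scale fusion)
    Q     = Conv1x1(F_A),  K = Conv1x1(F_T),  V = Conv1x1(F_T)
    Att   = softmax_j( Q_i . K_j )                   (row-stochastic)
    F_M   = Att-weighted sum of V
    out   = F_T + gamma * F_M,   gamma a scalar initialized at 0

No 1/sqrt(d) scaling is applied to the dot products and no positional
encoding is used: attention is a single application over flattened
(row-major) spatial positions.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor, as_tensor
from .nn import functional as F

__all__ = [
    "MsSTBlock", "project_qkv", "compute_attention", "apply_attention",
    "msst_forward", "attention_oracle",
]


class MsSTBlock(nn.Module):
    """Parameters of the MsST block.

    Parameters
    ----------
    top_channels:
        Channel count ``C`` of the top-stage feature map ``F_T``.
    stage_channels:
        Channels of the three shallower stage maps fed into the
        downsample-normalize path (each mapped to ``C`` by a 3x3 conv).
    reduction:
        Channel reduction ``r`` for the query/key projections
        (``C`` must be divisible by ``r``; default 8).
    """

    def __init__(self, top_channels: int, stage_channels=(64, 128, 256),
                 reduction: int = 8, rng: np.random.Generator | None = None):
        super().__init__()
        if top_channels % reduction:
            raise ValueError(
                f"top_channels={top_channels} not divisible by reduction={reduction}")
        rng = rng or np.random.default_rng(0)
        c, r = top_channels, reduction
        self.top_channels = c
        self.reduction = r
        self.q_proj = nn.Conv2d(c, c // r, 1, rng=rng)
        self.k_proj = nn.Conv2d(c, c // r, 1, rng=rng)
        self.v_proj = nn.Conv2d(c, c, 1, rng=rng)
        self.down = [nn.Conv2d(sc, c, 3, padding=1, rng=rng) for sc in stage_channels]
        self.gamma = nn.Parameter(0.0)

    def forward(self, f1, f2, f3, f_t) -> Tensor:
        return msst_forward(f1, f2, f3, f_t, self)


def project_qkv(f_a, f_t, params: MsSTBlock):
    """1x1-convolution encodings: Q from the fused map, K/V from the top map."""
    f_a, f_t = as_tensor(f_a), as_tensor(f_t)
    if f_a.shape != f_t.shape:
        raise ValueError(f"fused map shape {f_a.shape} != top map shape {f_t.shape}")
    if f_a.shape[1] != params.top_channels:
        raise ValueError(
            f"input has {f_a.shape[1]} channels, block built for {params.top_channels}")
    return params.q_proj(f_a), params.k_proj(f_t), params.v_proj(f_t)


def compute_attention(q, k) -> Tensor:
    """Row-stochastic (B, H*W, H*W) spatial affinity map.

    Entry (b, i, j) is the softmax-over-j of the dot product between the
    channel vector of ``q`` at flattened position i and of ``k`` at j;
    flattening is row-major.
    """
    q, k = as_tensor(q), as_tensor(k)
    if q.shape != k.shape:
        raise ValueError(f"query shape {q.shape} != key shape {k.shape}")
    b, c, h, w = q.shape
    qf = q.reshape(b, c, h * w)
    kf = k.reshape(b, c, h * w)
    energy = qf.transpose(0, 2, 1) @ kf  # (B, HW, HW)
    return energy.softmax(axis=-1)


def apply_attention(v, att) -> Tensor:
    """Attention-weighted sum of value vectors: out_i = sum_j att[i, j] v_j."""
    v, att = as_tensor(v), as_tensor(att)
    b, c, h, w = v.shape
    if att.shape != (b, h * w, h * w):
        raise ValueError(
            f"attention map shape {att.shape} incompatible with value map {v.shape}")
    vf = v.reshape(b, c, h * w)
    out = vf @ att.transpose(0, 2, 1)
    return out.reshape(b, c, h, w)


def msst_forward(f1, f2, f3, f_t, params: MsSTBlock) -> Tensor:
    """Full MsST block: fuse stages, attend, residual-add with scale gamma."""
    f_t = as_tensor(f_t)
    _, _, ht, wt = f_t.shape
    fused = None
    for fmap, conv in zip((f1, f2, f3), params.down):
        fmap = as_tensor(fmap)
        if fmap.shape[2] < ht or fmap.shape[3] < wt:
            raise ValueError(
                f"stage map spatial size {fmap.shape[2:]} smaller than top map {(ht, wt)}; "
                "cannot downsample upward")
        piece = conv(F.bilinear_resize(fmap, ht, wt))
        fused = piece if fused is None else fused + piece
    q, k, v = project_qkv(fused, f_t, params)
    att = compute_attention(q, k)
    f_m = apply_attention(v, att)
    return f_t + params.gamma * f_m


def attention_oracle(q, k, v) -> np.ndarray:
    """Explicit-loop reference for the attention stack (test oracle).

    Computes the same quantity as ``compute_attention`` followed by
    ``apply_attention`` with nested Python loops and no vectorized
    shortcuts; used to validate the fast path.
    """
    q = np.asarray(q, dtype=float)
    k = np.asarray(k, dtype=float)
    v = np.asarray(v, dtype=float)
    if q.shape != k.shape:
        raise ValueError(f"query shape {q.shape} != key shape {k.shape}")
    b, cr, h, w = q.shape
    if v.shape[0] != b or v.shape[2:] != (h, w):
        raise ValueError(f"value shape {v.shape} incompatible with query {q.shape}")
    c = v.shape[1]
    n = h * w
    out = np.zeros((b, c, h, w))
    for bi in range(b):
        # flatten positions row-major
        qpos = [q[bi, :, i // w, i % w] for i in range(n)]
        kpos = [k[bi, :, i // w, i % w] for i in range(n)]
        vpos = [v[bi, :, i // w, i % w] for i in range(n)]
        for i in range(n):
            energies = [float(np.dot(qpos[i], kpos[j])) for j in range(n)]
            m = max(energies)
            exps = [np.exp(e - m) for e in energies]
            z = sum(exps)
            acc = np.zeros(c)
            for j in range(n):
                acc += (exps[j] / z) * vpos[j]
            out[bi, :, i // w, i % w] = acc
    return out
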