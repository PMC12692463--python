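"""Bidirectional Cross-Attention Fusion (BCAF) of the two modality embeddings.

Each embedding is reinterpreted as a short token sequence (n_tokens × d_in,
with n_tokens * d_in = d_out) and updated by single-head scaled dot-product
cross-attention against the other modality, with a residual add:

    z'_q = z_q + Attention(z_q W_Q, z_c W_K) · (z_c W_V)

The two directions (time-series→GMV and GMV→time-series) use independent
projection triples.  With n_tokens = 1 the softmax is over a single key and
the update degenerates to the closed form z' = z + z_c W_V, which is kept as
a tested special case.  A Modality Weighting Allocation Module (MWAM) then
produces per-sample softmax weights ω over the two updated embeddings and
the fused representation is the convex combination

    z_fusion = ω_1 z'_ts + ω_2 z'_gm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, concat, softmax
from .nn import Linear, Module

__all__ = ["BCAFParams", "CrossAttention", "BCAF"]


@dataclass
class BCAFParams:
    d_out: int = 128
    n_tokens: int = 8
    mwam_hidden: int = 64

    def __post_init__(self):
        if self.d_out % self.n_tokens:
            raise ValueError(
                f"d_out={self.d_out} not divisible by n_tokens={self.n_tokens}")

    @property
    def d_in(self) -> int:
        """Per-token width used in the attention scaling."""
        return self.d_out // self.n_tokens


class CrossAttention(Module):
    """One direction of tokenized cross-attention with residual update."""

    def __init__(self, params: BCAFParams, rng: np.random.Generator):
        super().__init__()
        d = params.d_in
        self.w_q = Parameter(_init(rng, d))
        self.w_k = Parameter(_init(rng, d))
        self.w_v = Parameter(_init(rng, d))
        self.params = params
        self.last_attention: np.ndarray | None = None

    def forward(self, query_emb: Tensor, context_emb: Tensor) -> Tensor:
        p = self.params
        B = query_emb.shape[0]
        if query_emb.shape[-1] != p.d_out or context_emb.shape[-1] != p.d_out:
            raise ValueError("embeddings must share the configured d_out")
        q_tok = query_emb.reshape(B, p.n_tokens, p.d_in)
        c_tok = context_emb.reshape(B, p.n_tokens, p.d_in)
        q = q_tok @ self.w_q
        k = c_tok @ self.w_k
        v = c_tok @ self.w_v
        attn = softmax((q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(p.d_in)),
                       axis=-1)
        self.last_attention = attn.data
        upd = (attn @ v).reshape(B, p.d_out)
        return query_emb + upd


def _init(rng: np.random.Generator, d: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (2 * d))
    return rng.uniform(-limit, limit, size=(d, d))


class BCAF(Module):
    """Full fusion stage: both attention directions, MWAM, convex mixing.

    ``bypass=True`` disables the mechanism for ablations: embeddings pass
    through unchanged and are averaged with fixed weights (0.5, 0.5).
    """

    def __init__(self, params: BCAFParams, rng: np.random.Generator,
                 bypass: bool = False):
        super().__init__()
        self.params = params
        self.ts_to_gm = CrossAttention(params, rng)
        self.gm_to_ts = CrossAttention(params, rng)
        self.mwam_hidden = Linear(2 * params.d_out, params.mwam_hidden, rng)
        self.mwam_out = Linear(params.mwam_hidden, 2, rng)
        self.bypass = bypass

    def modality_weights(self, z_ts_u: Tensor, z_gm_u: Tensor) -> Tensor:
        h = self.mwam_hidden(concat([z_ts_u, z_gm_u], axis=-1)).relu()
        return softmax(self.mwam_out(h), axis=-1)

    @staticmethod
    def fuse(omega: Tensor, z_ts_u: Tensor, z_gm_u: Tensor) -> Tensor:
        return omega[:, 0:1] * z_ts_u + omega[:, 1:2] * z_gm_u

    def forward(self, z_ts: Tensor, z_gm: Tensor
                ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Returns (z'_ts, z'_gm, ω, z_fusion)."""
        if self.bypass:
            omega = Tensor(np.full((z_ts.shape[0], 2), 0.5))
            return z_ts, z_gm, omega, self.fuse(omega, z_ts, z_gm)
        z_ts_u = self.ts_to_gm(z_ts, z_gm)
        z_gm_u = self.gm_to_ts(z_gm, z_ts)
        omega = self.modality_weights(z_ts_u, z_gm_u)
        return z_ts_u, z_gm_u, omega, self.fuse(omega, z_ts_u, z_gm_u)
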