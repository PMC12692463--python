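"""Functional-pathway encoder for ROI time series.

A BiLSTM reads the padded region×time sequences (forward and backward
hidden states concatenated), a stack of masked pre-norm Transformer encoder
layers models global temporal dependencies while giving zero attention to
padded positions, and a masked mean pool followed by a linear projection
produces the fixed-size embedding z_ts.  The whole pathway is padding
invariant: appending extra zero-padding to any sample leaves its embedding
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .io_data import TimeSeriesBatch
from .nn import (BiLSTM, Dropout, LayerNorm, Linear, Module,
                 TransformerEncoderLayer, sinusoidal_positions)

__all__ = ["TSEncoderParams", "TimeSeriesEncoder", "masked_mean"]


@dataclass
class TSEncoderParams:
    """Hyper-parameters of the time-series pathway.

    The model width seen by the Transformer is ``2 * lstm_hidden`` (the
    concatenated bidirectional states) and must divide by ``n_heads``.
    """

    d_in: int = 116
    lstm_hidden: int | None = None   # default: d_in
    n_transformer_layers: int = 4
    n_heads: int = 4
    ffn_mult: int = 4
    d_out: int = 128
    dropout: float = 0.1
    positional_encoding: bool = True

    def __post_init__(self):
        if self.lstm_hidden is None:
            self.lstm_hidden = self.d_in
        if (2 * self.lstm_hidden) % self.n_heads:
            raise ValueError("2*lstm_hidden must be divisible by n_heads")
        if self.d_out <= 0:
            raise ValueError("d_out must be positive")


def masked_mean(h: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over valid timesteps only: sum(h * m) / sum(m) per sample."""
    m = mask[:, :, None]
    denom = mask.sum(axis=1, keepdims=True)  # B,1
    return (h * m).sum(axis=1) * (1.0 / denom)


class TimeSeriesEncoder(Module):
    def __init__(self, params: TSEncoderParams, rng: np.random.Generator):
        super().__init__()
        self.params = params
        d_model = 2 * params.lstm_hidden
        self.lstm = BiLSTM(params.d_in, params.lstm_hidden, rng)
        self.layers = [TransformerEncoderLayer(d_model, params.n_heads,
                                               params.ffn_mult,
                                               params.dropout, rng)
                       for _ in range(params.n_transformer_layers)]
        self.final_norm = LayerNorm(d_model)
        self.dropout = Dropout(params.dropout, rng)
        self.proj = Linear(d_model, params.d_out, rng)

    # The stages are exposed separately so each can be tested against its
    # padding-invariance / masking oracle in isolation.
    def bilstm_forward(self, batch: TimeSeriesBatch) -> Tensor:
        x = Tensor(batch.X)
        return self.lstm(x, batch.mask)

    def transformer_encode(self, h_lstm: Tensor, mask: np.ndarray) -> Tensor:
        if (mask.sum(axis=1) == 0).any():
            raise ValueError("a sample in the batch is fully masked")
        h = h_lstm
        if self.params.positional_encoding:
            T, D = h.shape[1], h.shape[2]
            h = h + sinusoidal_positions(T, D)[None]
        for layer in self.layers:
            h = layer(h, mask)
        h = self.final_norm(h)
        return h * mask[:, :, None]

    def masked_pool_project(self, h_trans: Tensor, mask: np.ndarray) -> Tensor:
        pooled = masked_mean(h_trans, mask)
        return self.proj(self.dropout(pooled))

    def forward(self, batch: TimeSeriesBatch) -> Tensor:
        h = self.bilstm_forward(batch)
        h = self.transformer_encode(h, batch.mask)
        return self.masked_pool_project(h, batch.mask)
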