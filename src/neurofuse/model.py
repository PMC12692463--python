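"""The assembled site-adversarial multimodal classifier.

Dual-pathway encoders (BiLSTM–Transformer over ROI time series, 3-D ResNet
over gray-matter volumes), bidirectional cross-attention fusion, and two
heads: an MDD/HC classifier on [z_ts ‖ z_gm ‖ z_fusion] and a site
classifier on GRL(z_fusion) that adversarially strips site information from
the fused embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .fusion import BCAF, BCAFParams
from .gmv_encoder import GMVEncoder, GMVEncoderParams
from .heads import DiseaseHead, HeadsParams, SiteHead
from .io_data import TimeSeriesBatch
from .nn import Module
from .ts_encoder import TimeSeriesEncoder, TSEncoderParams

__all__ = ["ModelConfig", "ModalityEmbeddings", "MultimodalNet"]


@dataclass
class ModelConfig:
    """Bundle of all architecture hyper-parameters.

    ``use_bcaf`` / ``use_grl`` are the ablation switches: without BCAF the
    embeddings bypass the attention stage and are averaged with equal
    weights; without GRL the site head and site loss are dropped and
    training reduces to plain disease classification.
    """

    ts: TSEncoderParams = field(default_factory=TSEncoderParams)
    gmv: GMVEncoderParams = field(default_factory=GMVEncoderParams)
    fusion: BCAFParams = field(default_factory=BCAFParams)
    heads: HeadsParams = field(default_factory=HeadsParams)
    use_bcaf: bool = True
    use_grl: bool = True

    def __post_init__(self):
        if not (self.ts.d_out == self.gmv.d_out == self.fusion.d_out
                == self.heads.d_out):
            raise ValueError("all components must share the same d_out")

    @classmethod
    def compact(cls, d_in: int, n_sites: int, beta: float = 0.1,
                use_bcaf: bool = True, use_grl: bool = True) -> "ModelConfig":
        """Small configuration for desk-scale cohorts on one CPU."""
        d_out = 32
        return cls(
            ts=TSEncoderParams(d_in=d_in, lstm_hidden=16,
                               n_transformer_layers=2, n_heads=2, ffn_mult=2,
                               d_out=d_out, dropout=0.1),
            gmv=GMVEncoderParams(channels=(8, 16, 16, 32), d_out=d_out,
                                 stem_stride=2),
            fusion=BCAFParams(d_out=d_out, n_tokens=4, mwam_hidden=32),
            heads=HeadsParams(d_out=d_out, n_sites=n_sites, beta=beta),
            use_bcaf=use_bcaf, use_grl=use_grl)


@dataclass
class ModalityEmbeddings:
    """Per-batch intermediate representations of the forward pass."""

    z_ts: Tensor
    z_gm: Tensor
    z_ts_updated: Tensor
    z_gm_updated: Tensor
    omega: Tensor
    z_fusion: Tensor
    disease_logits: Tensor
    site_logits: Tensor | None


class MultimodalNet(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.ts_encoder = TimeSeriesEncoder(config.ts, rng)
        self.gmv_encoder = GMVEncoder(config.gmv, rng)
        self.bcaf = BCAF(config.fusion, rng, bypass=not config.use_bcaf)
        self.disease_head = DiseaseHead(config.heads, rng)
        self.site_head = (SiteHead(config.heads, rng)
                          if config.use_grl else None)

    def forward(self, ts_batch: TimeSeriesBatch,
                gmv: np.ndarray) -> ModalityEmbeddings:
        z_ts = self.ts_encoder(ts_batch)
        z_gm = self.gmv_encoder(Tensor(gmv[:, None]))  # add channel axis
        z_ts_u, z_gm_u, omega, z_fusion = self.bcaf(z_ts, z_gm)
        disease_logits = self.disease_head(z_ts, z_gm, z_fusion)
        site_logits = (self.site_head(z_fusion)
                       if self.site_head is not None else None)
        return ModalityEmbeddings(z_ts=z_ts, z_gm=z_gm,
                                  z_ts_updated=z_ts_u, z_gm_updated=z_gm_u,
                                  omega=omega, z_fusion=z_fusion,
                                  disease_logits=disease_logits,
                                  site_logits=site_logits)

    # named parameter groups, matching the adversarial update semantics
    def feature_parameters(self):
        yield from self.ts_encoder.parameters()
        yield from self.gmv_encoder.parameters()

    def fusion_parameters(self):
        yield from self.bcaf.parameters()

    def disease_parameters(self):
        yield from self.disease_head.parameters()

    def site_parameters(self):
        if self.site_head is not None:
            yield from self.site_head.parameters()
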