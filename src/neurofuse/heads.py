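"""Adversarial multitask heads: disease classifier, site classifier behind a
gradient-reversal layer, cross-entropy, and the total objective.

The optimization is a min–max: the disease classifier and the shared
feature/fusion parameters minimize the disease loss, while the site
classifier tries to recover the acquisition site from the fused embedding
and the shared parameters are pushed to *defeat* it.  The max over the site
head is realized with a gradient-reversal layer (identity forward, negated
gradient backward), so a single optimizer descending on the backprop scalar

    total = (1 - beta) * L_D + beta * L_S(through GRL)

performs exactly the coupled updates: the site head descends on beta*L_S,
the disease head on (1-beta)*L_D, and every upstream parameter receives
(1-beta)*dL_D - beta*dL_S.  The literal reported objective
(1-beta)*L_D - beta*L_S is kept for logging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, grad_reverse, log_softmax
from .nn import Linear, Module

__all__ = ["HeadsParams", "LossBundle", "grl", "cross_entropy",
           "total_loss", "DiseaseHead", "SiteHead"]


@dataclass
class HeadsParams:
    d_out: int = 128          # embedding width of each pathway
    n_sites: int = 25
    beta: float = 0.1         # site-loss weight in the adversarial objective

    def __post_init__(self):
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must lie in [0, 1)")


@dataclass
class LossBundle:
    """Losses of one step plus the scalar actually backpropagated."""

    disease: Tensor              # L_D, cross-entropy of the MDD head
    site: Tensor                 # L_S, cross-entropy of the site head
    beta: float
    total: Tensor                # (1-beta)*L_D + beta*L_S-through-GRL
    reported_objective: float    # (1-beta)*L_D - beta*L_S (printed value)


def grl(z: Tensor, strength: float = 1.0) -> Tensor:
    """Gradient reversal layer (identity forward, -strength grad backward)."""
    return grad_reverse(z, strength)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean over the batch of -log softmax(logits)[true class].

    Numerically stabilized through max-subtraction inside log-softmax.
    """
    labels = np.asarray(labels)
    C = logits.shape[-1]
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= C:
        raise ValueError(f"labels must lie in [0, {C})")
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(logits.shape[0]), labels]
    return -picked.mean()


class DiseaseHead(Module):
    """Affine map of [z_ts ‖ z_gm ‖ z_fusion] to the two diagnosis logits."""

    def __init__(self, params: HeadsParams, rng: np.random.Generator):
        super().__init__()
        self.linear = Linear(3 * params.d_out, 2, rng)
        self.d_out = params.d_out

    def forward(self, z_ts: Tensor, z_gm: Tensor, z_fusion: Tensor) -> Tensor:
        for z in (z_ts, z_gm, z_fusion):
            if z.shape[-1] != self.d_out:
                raise ValueError("embedding width mismatch with disease head")
        return self.linear(concat([z_ts, z_gm, z_fusion], axis=-1))


class SiteHead(Module):
    """Affine site classifier applied to GRL(z_fusion)."""

    def __init__(self, params: HeadsParams, rng: np.random.Generator):
        super().__init__()
        self.linear = Linear(params.d_out, params.n_sites, rng)
        self.grl_strength = 1.0

    def forward(self, z_fusion: Tensor, apply_grl: bool = True) -> Tensor:
        z = grl(z_fusion, self.grl_strength) if apply_grl else z_fusion
        return self.linear(z)


def total_loss(loss_disease: Tensor, loss_site: Tensor,
               beta: float) -> LossBundle:
    """Combine the two task losses into the adversarial objective.

    ``loss_site`` must already be computed through the GRL for the parameter
    update semantics to hold; with beta = 0 the site head receives no
    gradient at all.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must lie in [0, 1)")
    total = (1.0 - beta) * loss_disease + beta * loss_site
    reported = (1.0 - beta) * float(loss_disease.data) \
        - beta * float(loss_site.data)
    return LossBundle(disease=loss_disease, site=loss_site, beta=beta,
                      total=total, reported_objective=reported)
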