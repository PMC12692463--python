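"""Region-level Shapley attribution of a trained classifier.

Trains on a small cohort with a known set of disease-affected regions and
checks that the attribution ranking recovers them: each region's Shapley
value is its average marginal contribution to the predicted MDD probability
when regions are occluded with their training-set mean.
"""

import numpy as np

import neurofuse as nf
from neurofuse.model import ModelConfig
from neurofuse.train_eval import TrainConfig, train
from neurofuse.interpret import region_shapley

cfg = nf.SimulationConfig(n_sites=2, subjects_per_site=(15, 15),
                          d_regions=8, t_ranges=[(90, 95)] * 2,
                          gmv_dims=(10, 12, 10), ts_disease_shift=1.5,
                          gmv_disease_shift=1.5, seed=5)
cohort, truth = nf.simulate_cohort(cfg)
print(f"truly affected regions: {truth.affected_regions}")

mc = ModelConfig.compact(d_in=8, n_sites=2)
model, _ = train(cohort, mc, TrainConfig.desk_scale(epochs=8, seed=0))

table = region_shapley(model, cohort, modality="ts", n_permutations=8,
                       seed=0)
print("\ntime-series attribution (sorted by |Shapley value|):")
print(table.round(4).to_string(index=False))
print("\nPositive attribution: the region's observed signal pushes the "
      "model toward the MDD class; the p-values are two-sample Welch tests "
      "on the region's subject-level mean feature.")
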