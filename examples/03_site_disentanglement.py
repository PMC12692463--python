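"""Compare adversarial (gradient-reversal) vs plain training on a
multi-site cohort: how much site information survives in the fused
embedding, and what happens to held-out-site accuracy.

A linear site probe is fit post hoc on the frozen fused embeddings; with
balanced sites its chance level is 1/S.  Expect the probe near chance after
adversarial training and clearly above chance without it.  Runs a reduced
cohort for speed (~4 minutes on one CPU).
"""

import numpy as np

import neurofuse as nf
from neurofuse.model import ModelConfig
from neurofuse.train_eval import (TrainConfig, _prepare, embed_fusion,
                                  loso_cv, site_probe_accuracy, train)

cfg = nf.SimulationConfig(n_sites=4, subjects_per_site=(12, 12),
                          d_regions=24, t_ranges=[(90, 100)] * 4,
                          gmv_dims=(12, 14, 12), ts_disease_shift=1.0,
                          gmv_disease_shift=1.0, seed=3)
cohort, _ = nf.simulate_cohort(cfg)
prep = _prepare(cohort, np.arange(len(cohort)))
chance = 1.0 / cohort.n_sites

for use_grl in (False, True):
    mc = ModelConfig.compact(d_in=24, n_sites=4, use_grl=use_grl)
    tc = TrainConfig.desk_scale(epochs=10, seed=0)
    model, _ = train(cohort, mc, tc, prepared=prep)
    z = embed_fusion(model, prep, np.arange(len(cohort)))
    probe = site_probe_accuracy(z, cohort.sites, seed=0)
    loso = loso_cv(cohort, mc, TrainConfig.desk_scale(epochs=5, seed=0))
    label = "with GRL" if use_grl else "without GRL"
    print(f"{label:12s}: site probe accuracy {probe:.3f} "
          f"(chance {chance:.3f}), mean LOSO accuracy "
          f"{loso.accuracy.mean():.3f}")

print("\nA probe near chance means the acquisition site can no longer be "
      "decoded linearly from the fused embedding — the adversarial head "
      "has stripped the scanner signature while held-out-site accuracy "
      "stays far above the 0.5 chance level for the diagnosis.")
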