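"""Generate a synthetic multi-view cohort and inspect its planted structure.

Builds a cohort of 2,000 participants with two planted environment-symptom
canonical modes (r = 0.30 and 0.15), genotypes in LD blocks, a brain
mediator and confounds, then verifies the planted correlation with a plain
CCA on the true support columns.
"""

import numpy as np

from envlink import SimConfig, cca_unpenalized, simulate_views

# confounds off: this example reads the planted correlations directly off
# the raw views (age/sex/center effects are shared across views and would
# otherwise inflate them -- see example 02 for the residualized analysis)
cfg = SimConfig(n_participants=2000, seed=1, confound_effect_scale=0.0)
dataset, truth = simulate_views(cfg)

print(f"cohort: {dataset.env.n_participants} participants")
print(f"views: env {dataset.env.n_features} categories "
      f"({dataset.env_raw.n_features} raw items), "
      f"{dataset.symptoms.n_features} symptoms, "
      f"{dataset.brain.n_features} brain ROIs, "
      f"{dataset.genotypes.n_variants} variants")

for k, r_planted in enumerate(truth.planted_r):
    sup_env = np.flatnonzero(truth.planted_weights_env[k])
    sup_sym = np.flatnonzero(truth.planted_weights_sym[k])
    fit = cca_unpenalized(dataset.env.values[:, sup_env],
                          dataset.symptoms.values[:, sup_sym], ridge_eps=0.0)
    print(f"mode {k + 1}: planted r = {r_planted:.2f}, "
          f"CCA on true supports recovers r = {fit.canonical_r:.3f}")

# The recovered r sits slightly below the planted latent correlation because
# the support columns are noisy indicators of the mode latents (~6%
# attenuation at the default indicator fidelity).
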