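"""Discover shape modes by K-means and profile their distribution.

Selects the number of modes with the Xie-Beni index, fits the modes,
and prints the per-sample mode distribution and its Shannon entropy --
the core heterogeneity readout.
"""

import numpy as np

from morphomodes import (fit_eigenshapes, fit_shape_modes, generate_templates,
                         mode_distribution, project_and_reconstruct,
                         register_traces, sample_population, select_num_modes,
                         shannon_entropy)

templates = generate_templates(4, irregularity=0.3, seed=5)
boundaries, truth = sample_population(templates, [0.3, 0.3, 0.2, 0.2], 1500,
                                      shape_noise=0.05, seed=6)
X = np.array([s.feature_vector for s in register_traces(boundaries)])
model = fit_eigenshapes(X, 0.95)
scores, _, _ = project_and_reconstruct(model, X)

K, diag = select_num_modes(scores, k_min=2, k_max=8, seed=0, n_init=10)
modes = fit_shape_modes(scores, K, model, seed=0, n_init=10)
dist = mode_distribution(modes.labels, modes.labels, K, K, sample_id="demo")

print("true subtypes:        4 (weights 0.30/0.30/0.20/0.20)")
print(f"selected K:           {K} (Xie-Beni minimum)")
print(diag[["K", "xie_beni", "separation"]].round(4).to_string(index=False))
print(f"mode probabilities:   {np.round(dist.p_nucleus, 3).tolist()}")
print(f"shape entropy S(NS):  {shannon_entropy(dist.p_nucleus):.3f} bits")
print("-> mode ids are ordered by cluster size, so the probabilities")
print("   decrease; the entropy summarizes how evenly the population")
print("   spreads over its shape modes.")
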