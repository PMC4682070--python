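"""Register outlines and learn the eigenshape basis.

Draws 500 cell outlines from 5 latent subtypes, registers each into the
canonical frame (50 points, centroid at the origin, RMS radius 1, major
axis horizontal), and fits a PCA whose retained components capture 95%
of the shape variance.
"""

import numpy as np

from morphomodes import (fit_eigenshapes, generate_templates,
                         project_and_reconstruct, register_traces,
                         sample_population)

templates = generate_templates(5, irregularity=0.3, seed=2)
boundaries, truth = sample_population(templates, np.full(5, 0.2), 500,
                                      shape_noise=0.05, seed=3)
shapes = register_traces(boundaries)
X = np.array([s.feature_vector for s in shapes])

model = fit_eigenshapes(X, variance_threshold=0.95)
scores, recon, residual = project_and_reconstruct(model, X)

print(f"registered shapes:        {len(shapes)} (100 features each)")
print(f"eigenshapes at 95%:       {model.n_components}")
print(f"explained fractions:      "
      f"{np.round(model.explained_fraction, 3).tolist()}")
print(f"reconstruction residual:  {residual:.4f}")
print(f"mean scaling factor R:    {np.mean([s.R for s in shapes]):.2f} px")
print("-> a handful of eigenshapes suffices because the population is")
print("   built from a few latent subtypes; the residual is the fraction")
print("   of shape variance the truncated basis does not explain (< 5%).")
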