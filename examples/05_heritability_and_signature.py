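"""Decompose heterogeneity into heritable and stochastic parts, then
classify samples by the three-feature metastatic-like signature.

Colony (clone) membership carries a multiplicative size factor; the
within-clone variance therefore falls below the population variance,
and the CV of clone means measures the heritable part.  Two sample
groups with different heterogeneity are then classified by subsampled
leave-one-sample-out nearest-centroid cross-validation.
"""

import numpy as np
import pandas as pd

from morphomodes import (heritable_variation, signature_and_classification,
                         synthesize_cell_table, variance_decomposition)

# --- variance decomposition ----------------------------------------------
cells = synthesize_cell_table(5000, seed=8, n_colonies=40, colony_size_cv=0.1,
                              size_cv=0.1, phase_probs=(1.0, 0.0, 0.0),
                              phase_size_coupling=False)
cells["phase"] = cells["phase_true"]
vd = variance_decomposition(cells)
pivot = vd.pivot(index="condition", columns="feature",
                 values="scaled_variance")
print("scaled variances (1.0 = all-population):")
print(pivot.round(3).to_string())
hv = heritable_variation(cells)
print(f"heritable variation (CV of clone means): R_N={hv['R_N']:.3f}, "
      f"R_C={hv['R_C']:.3f} over {hv['n_colonies']} clones")

# --- signature classification --------------------------------------------
frames, labels = [], {}
for i in range(4):
    high = i < 2
    probs = (np.full(5, 0.2) if high
             else np.array([0.8, 0.05, 0.05, 0.05, 0.05]))
    sid = f"P{i}"
    frames.append(synthesize_cell_table(
        1200, seed=20 + i, sample_id=sid, nucleus_mode_probs=probs,
        cell_mode_probs=probs, size_cv=0.25 if high else 0.10))
    labels[sid] = "PT" if high else "LM"
records = pd.concat(frames, ignore_index=True)
sigs, acc = signature_and_classification(records, labels, K_N=5,
                                         subsample_sizes=(50, 100, 200, 400),
                                         n_repeats=10, seed=0)
print("\nsignature vectors (per sample):")
print(sigs.round(3).to_string())
print("\naccuracy vs subsample size:")
print(acc.round(3).to_string(index=False))
print("-> with equal clone and residual variances the within-clone")
print("   variance is ~0.5 of the population variance; the high- vs")
print("   low-heterogeneity groups separate cleanly by the signature.")
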