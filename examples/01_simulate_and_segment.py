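"""Simulate a fluorescence scene with known truth and segment it back.

Builds a two-channel synthetic image (DNA + F-actin) of 30 cells drawn
from 3 latent shape subtypes, runs the watershed segmentation, and
checks how many objects are recovered.
"""

import numpy as np

from morphomodes import segment_scene, simulate_sample

scene = simulate_sample(n_cells=30, k_templates=3, seed=1,
                        image_shape=(800, 800), snr=20.0)
seg = segment_scene(scene.images["dna"], scene.images["actin"])

n_true = len(scene.truth)
n_nuclei = len(np.unique(seg.nucleus_mask)) - 1
n_cells = len(np.unique(seg.cell_mask)) - 1
print(f"simulated cells:  {n_true}")
print(f"segmented nuclei: {n_nuclei}")
print(f"segmented cells:  {n_cells}")
print("-> at SNR 20 the watershed recipe should recover every object;")
print("   nuclei come from the DNA channel, cells from a nucleus-seeded")
print("   watershed on the actin channel, with matching label ids.")
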