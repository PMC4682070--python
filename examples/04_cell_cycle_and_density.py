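"""Attach cell-cycle and local-density context to each cell.

Gates cells into G0/G1, S and G2/M from integrated nuclear DNA
intensity, builds the cell-cell contact graph of a hexagonal rosette,
and measures how mode occupancy trends with DNA content.
"""

import numpy as np

from morphomodes import (build_contact_graph, covariate_trend_analysis,
                         gate_phases, normalize_and_gate_dna, render_scene,
                         rosette_scene, synthesize_cell_table)

# --- DNA gating -----------------------------------------------------------
cells = synthesize_cell_table(3000, seed=7)
norm, phases = normalize_and_gate_dna(cells["dna_content_raw"].to_numpy())
reference = gate_phases(cells["dna_content_true"].to_numpy())
acc = (phases == reference).mean()
print("phase fractions:", {p: round(float((phases == p).mean()), 3)
                           for p in ("G0G1", "S", "G2M")})
print(f"gating accuracy vs noiseless gates: {acc:.3f}")

# --- contact graph on a rosette ------------------------------------------
truth, boundaries = rosette_scene(radius_px=16)
img = render_scene(truth, boundaries, image_shape=(160, 160), seed=0)
_, rho, cat = build_contact_graph(img["cell_mask"])
print(f"rosette contact counts: center={rho[1]}, petals="
      f"{sorted(rho[i] for i in range(2, 8))}")

# --- morphology trends along the cell cycle -------------------------------
cells["dna_content_norm"] = norm
cells["phase"] = phases
table, occurrence, corr = covariate_trend_analysis(cells, "dna", n_groups=9)
print("normalized nucleus size per DNA-content group:",
      np.round(table["norm_R_N"].to_numpy(), 3).tolist())
print("-> nucleus size grows with DNA content (cube-root coupling);")
print("   the center cell of the rosette is 'crowded' (rho_D >= 4),")
print("   its six petals are 'semi-crowded' (rho_D = 3).")
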