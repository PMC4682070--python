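# morphomodes

Single-cell morpho-phenotyping from cellular and nuclear outlines:
registration of boundary traces into similarity-invariant feature
vectors, eigenshape PCA, K-means shape modes, and the decomposition of
population heterogeneity into cell-cycle, cell-contact, stochastic and
heritable components.

## Who this is for

Groups doing high-content imaging of adherent cells (cancer cell lines,
drug panels, clonal growth assays) who want to go beyond scalar shape
descriptors. A single number such as the shape factor 4πA/P² or the
aspect ratio collapses wildly different morphologies onto the same
value; working directly with registered boundary coordinates keeps the
full shape and still yields compact, comparable statistics.

## The method

For each segmented cell and nucleus outline:

1. **Registration.** The closed boundary is resampled at 50 equally
   spaced points, translated to its centroid, divided by the scaling
   factor *R* (centroid size: the RMS distance of boundary points from
   the centroid; *R*<sub>N</sub> for nuclei, *R*<sub>C</sub> for cells),
   and rotated so the major axis of its second-moment matrix is
   horizontal. The 180° ambiguity is fixed by requiring nonnegative
   x-skewness, and the point sequence starts at the outermost crossing
   of the positive x-axis. The result is a 100-vector
   (x₁…x₅₀, y₁…y₅₀) invariant to translation, rotation, uniform scaling
   and vertex indexing.
2. **Eigenshapes.** PCA on the pooled feature matrix; the smallest
   number of components whose cumulative explained variance reaches 95%
   forms the eigenshape basis. Any cell is summarized by its projection
   scores.
3. **Shape modes.** K-means on the scores; the number of modes K is
   selected by minimizing the Xie–Beni index
   Σᵢ‖xᵢ−c<sub>l(i)</sub>‖² / (n·min<sub>j≠k</sub>‖c<sub>j</sub>−c<sub>k</sub>‖²),
   with a Dunn-style separation index reported as a diagnostic. Each
   centroid maps back through the basis to a representative outline
   (NS<sub>k</sub> for nuclei, CS<sub>j</sub> for cells).
4. **Heterogeneity panel.** Per sample: CV(R<sub>N</sub>), CV(R<sub>C</sub>),
   Shannon entropies S(NS), S(CS) of the mode distributions and S(NS&CS)
   of the paired distribution, in bits.
5. **Context and heritability.** DNA-content gating into G0/G1, S and
   G2/M (fold of the G1 peak; gates 1.25/1.75 by default); local density
   ρ_D as the cell-contact count (singlet ρ_D = 0, semi-crowded
   0 < ρ_D < 4, crowded ρ_D ≥ 4); variance decomposition across these
   conditions and across spatial clones; heritable variation as the CV
   of clone-mean sizes; and a three-feature signature
   (CV(R<sub>N</sub>) among clustered cells, CV(R<sub>C</sub>) among
   singlets, S(NS) among singlets) classified by leave-one-sample-out
   nearest centroid under random subsampling.

A synthetic-scene generator (`morphomodes.synth`) produces ground-truthed
populations — latent shape subtypes, DNA-coupled sizes, contacting
clusters, clonal colonies, rendered two-channel images — so every stage
is testable without external data.

## Worked example

```bash
python examples/02_register_and_eigenshapes.py
```

```
registered shapes:        500 (100 features each)
eigenshapes at 95%:       4
explained fractions:      [0.506, 0.333, 0.094, 0.03]
reconstruction residual:  0.0373
mean scaling factor R:    20.96 px
```

500 outlines drawn from 5 latent subtypes compress to 4 eigenshapes at
the 95% threshold; the residual 0.037 is the unexplained variance
fraction. Continuing with mode discovery
(`python examples/03_shape_modes.py`):

```
true subtypes:        4 (weights 0.30/0.30/0.20/0.20)
selected K:           4 (Xie-Beni minimum)
mode probabilities:   [0.311, 0.273, 0.22, 0.196]
shape entropy S(NS):  1.977 bits
```

The Xie–Beni minimum recovers the true subtype count and the mode
probabilities track the mixture weights; the entropy (max log₂4 = 2
bits) quantifies how evenly the population occupies its modes. The
other examples cover simulation + segmentation (01), cell-cycle and
density context (04), and heritability + signature classification (05).

There is also a thin CLI for shell pipelines:

```bash
morphomodes simulate --seed 1 --n-cells 60 --out runs/demo
morphomodes run-all --seed 1 --out runs/full
```

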