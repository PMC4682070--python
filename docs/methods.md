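# Methods

This note documents the models, conventions and numerical choices
behind `morphomodes`, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Boundary registration

**Input.** A closed polygon in pixel coordinates (x = column, y = row,
0-based, origin at the top-left pixel center), counterclockwise by the
positive-shoelace convention, first vertex not repeated.

**Normalization.** Each outline is mapped to 50 points with

* centroid at the origin,
* RMS radius 1 (the divisor is the scaling factor *R*, "centroid
  size" — the RMS distance of boundary points from their centroid, a
  standard morphometric size proxy used for both compartments),
* major axis of the 2×2 second-moment matrix horizontal, with
  x-variance ≥ y-variance and the cross-moment zero,
* nonnegative third moment of x (flipping by 180° otherwise),
* the point sequence starting at the outermost crossing of the positive
  x-axis, counterclockwise.

Mirror images are deliberately **not** pooled: left- and right-handed
shapes remain distinct.

**Why curve moments.** The centroid, second moments, skewness and start
point are computed as exact line integrals of the arc-length measure
over the polygon (closed forms per edge), not from the 50 resampled
points. Line integrals are exactly invariant to how the input curve
happens to be sampled — cyclic shifts of the vertex list, or extra
vertices inserted on edges — so two digitizations of the same physical
outline produce feature vectors agreeing to machine precision. The 50
output points are then re-normalized discretely so the registered-shape
invariants hold exactly on the emitted points. Feature vectors are
invariant to translation, rotation, uniform scaling and reindexing to
better than 1e-6 (measured: ~1e-14).

**Start-point convention.** An arg-max convention ("the point with the
largest x") is discontinuous: whenever two boundary bumps compete for
the largest x, an infinitesimal perturbation relocates the start point
by a finite arc distance, which fragments a population of
near-identical shapes into artificial sub-clusters. The outermost
positive-x-axis crossing is a root of y(s) rather than an arg-max and
moves continuously under small perturbations; the max-x vertex is kept
as a fallback for outlines whose centroid lies outside the curve.

**Degenerate cases.** Zero-perimeter or coincident-point traces raise a
degenerate-shape error. Circularly symmetric outlines (second-moment
eigenvalues equal to within 1e-12 relative) get rotation 0 and a
`degenerate_axis` flag. Registering an already-registered outline
re-applies a transform that is the identity to ~1e-3 (exactly, for
equal-chord polygons such as circles); the points themselves move at the
resampling discretization scale because equal arc spacing along the
original curve is not equal spacing along the 50-gon through the output
points. This is an intrinsic property of any fixed-point-count
resampling, not an implementation artifact.

## Eigenshape model

Covariance PCA (no per-feature standardization — after normalization
all 100 coordinates share the same dimensionless units) on the pooled
feature matrix, one model per compartment. The retained count m is the
smallest number of components whose cumulative explained-variance
fraction reaches the threshold (default 0.95). Numerically-zero
directions (ratio < 1e-12) are discarded so exact low-rank data report
cumulative explained variance 1.0 at exactly rank components.
Component signs follow a deterministic convention (largest-magnitude
entry positive).

## Shape modes

K-means (k-means++, default 20 restarts, fixed seed) in score space.
K is chosen by minimizing the hard-assignment Xie–Beni index; the
"separation index" is implemented as the Dunn-style ratio
min inter-centroid distance / max within-cluster diameter and reported
as a diagnostic only, because the two indices come with no arbitration
rule and Xie–Beni has the unambiguous formula. Zero-scatter separations
are capped at 1e12 to keep diagnostics finite. A `low_confidence` flag
is set when the Xie–Beni curve has no interior minimum (arg-min at the
top of the candidate range), as for a single isotropic cloud. Mode ids
are ordered by descending cluster size so galleries and distributions
are reproducible. Mode-recovery performance: on populations of five
latent subtypes at n = 2000 with 5% shape noise, selection returned
K = 5 with ≥ 95% best-permutation label agreement in 20/20 development
seeds (the acceptance suite requires 18/20).

## Heterogeneity metrics

CV uses the sample (n − 1) standard deviation; entropies are plug-in
estimates in bits (log base 2 — any base only rescales comparisons).
Mode probabilities are computed against the global mode catalogue with
zero-filled absent modes, so panels are comparable across samples.
No small-sample entropy bias correction (Miller–Madow etc.) is applied;
panels in this package are computed on hundreds to thousands of cells
where the plug-in bias (≈ (K−1)/(2n ln 2) bits) is negligible.

## Cell-cycle gating

The G0/G1 peak is located as the dominant mode of a Gaussian-KDE of the
integrated nuclear intensities; dividing by it makes the readout
invariant to detector gain. Default gates: G0/G1 ≤ 1.25, G2/M ≥ 1.75
fold-of-G1, S between. Gating accuracy is evaluated against the same
gates applied to the noiseless DNA content: a DNA-only gate cannot, even
in principle, distinguish an early-S cell from G1, so comparing against
the biological phase label conflates that irreducible overlap with
measurement error. With 5% multiplicative intensity noise the gates are
~97% accurate in this sense (~88% against the raw phase labels, the
difference being exactly the S-phase overlap mass).

## Contacts and density

Two cells are in contact when their masks come within `contact_gap`
pixels (binary dilation overlap, 8-connected, default 1 px). ρ_D is the
contact-graph degree; categories: singlet ρ_D = 0, semi-crowded
0 < ρ_D < 4, crowded ρ_D ≥ 4. Tiled scans are stitched into global
coordinates from manifest origins before the contact test, so edges
crossing tile borders are preserved; tiles disagreeing about a global
pixel raise a conflict error.

## Heritability

Colonies (clones) are single-linkage spatial clusters with a distance
cutoff; clusters below `min_size` (default 5) stay unassigned. The
proximity correlation enters every unordered pair in both orders
(symmetric duplication) so the estimator is exchangeable; its null band
is the 2.5–97.5 percentile range over label permutations (default 1000).
Note the estimator has the usual finite-sample pair-correlation offset
(≈ −1/(n−1)), which the permutation null shares, and a 95% band excludes
a correct null ~5% of the time per bin — aggregate rates, not per-bin
hits, are the meaningful check. Variance decomposition scales every
conditional variance by the all-population variance (that entry is 1 by
construction); within-clone variance is the unweighted mean over
qualifying colonies. Heritable variation is the CV of colony-mean
R_N / R_C, optionally on G0/G1 cells only.

The signature classifier is nearest-centroid on z-scored features with
leave-one-sample-out splitting — deliberately the simplest possible
model, so that discriminative power is attributable to the three
features, not to the classifier. With two samples per class, the
held-out sample's own class centroid is a single sample, which biases
null accuracy slightly below 0.5 (~0.40 measured); this is a known
small-sample LOO artifact and is reported as-is.

## Synthetic-scene generator

**Shape family.** Radial Fourier outlines
r(θ) = s·(1 + Σ_h a_h cos hθ + b_h sin hθ), h = 2…6 — star-convex,
guaranteed simple and closed. Templates are drawn in canonical pose:
elongation (cos 2θ) along x with a floor of 0.6·irregularity and no
sin 2θ; a cos 3θ (front–rear asymmetry) amplitude with a guaranteed
floor, clipped to 0.75 of the elongation; sin 3θ clipped to 0.8 of
cos 3θ; harmonics ≥ 4 damped by 1/h². These constraints ensure each
template has a well-defined registration frame (major axis, flip and
start point all stable under per-cell noise) — real adherent cells have
a clear major axis, and "distinct subtypes" that the registration frame
cannot hold steady are not meaningful subtypes. Candidate templates are
redrawn until the registered distance to every accepted template
exceeds 4.5·irregularity (best-of-200 fallback), enforcing genuine
distinctness.

**Study conditions (defaults, fixed once).** Cell-cycle mixture 60%
G0/G1 (DNA 1.0), 25% S (uniform on (1, 2)), 15% G2/M (2.0);
multiplicative lognormal intensity noise CV 5%; per-cell shape noise
0.05 (per-harmonic, 1/h scaled); template irregularity 0.3; cell and
nucleus linear size ∝ DNA content^(1/3); per-colony lognormal size
factor (the heritable component); rendered DNA channel with integrated
nuclear intensity exactly proportional to DNA content before Gaussian
read noise at the configured SNR.

**What it does not emulate.** No point-spread function, illumination
field, autofluorescence, debris, mitotic rounding, apoptosis,
segmentation-adversarial textures, or non-star-convex (e.g. C-shaped,
protrusive) morphologies. Passing tests therefore demonstrate the
correctness and statistical behavior of the pipeline under controlled
conditions, not segmentation robustness on real micrographs. The
registration, metrics and heritability statistics operate on boundary
polygons and per-cell tables and apply to real segmented data
unchanged.

## Problem sizes

The test suite and acceptance script use n = 100–400 shapes for exact
invariance/bookkeeping checks, n = 2000 × 20 seeds for mode recovery,
n = 4000 for gating and heterogeneity ordering, n = 5000 × 20 reps for
variance-component recovery, and 4 samples × 1200 cells for the
signature — sizes at which every statistical property tested has
comfortable margins while the whole suite runs in well under an hour on
one CPU.

## Known limitations

* Mirror pooling is not implemented; chiral shape pairs count as
  distinct modes.
* The Xie–Beni criterion inherits K-means' preference for convex,
  similar-scale clusters; strongly unbalanced mixtures can absorb a
  small subtype into a neighbor (the selection diagnostics expose the
  near-ties).
* The exact segmentation recipe is a stated, configuration-isolated
  stand-in (Otsu + distance-transform watershed on the DNA channel,
  nucleus-seeded watershed on actin); swap in a stronger segmenter for
  real data via `SegmentationParams` / the `LabeledScene` interface.
* 3D samples are handled by low-pass filtered maximum z-projection of
  the stack, not volumetric analysis.
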