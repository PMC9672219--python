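# Methods

## The model

The pipeline treats a masked grayscale liver slice as a filtered topological
space and asks whether the way its components and loops appear and disappear
across intensity thresholds discriminates patients who decompensate within a
year from those who do not.

**Filtration.** A 2-D image of shape r×c becomes a cubical complex with
V = (r+1)(c+1) vertices, E = r(c+1) + c(r+1) edges and F = r·c squares
(T-construction): each pixel is a top-dimensional cell carrying its own
intensity, and each face carries the minimum over the pixels it bounds. The
sublevel set at ε is then exactly the union of closed pixels with intensity
≤ ε, so H₀ follows 8-connectivity of the dark phase. The filtration direction
is sublevel (dark-first), the convention for grayscale cubical persistence; a
`superlevel` flag negates intensities for the opposite reading.

**Persistence.** Boundary-matrix reduction over **Z**/2, per dimension, with
cells ordered by (filtration value, dimension, row-major position; horizontal
before vertical edges on ties) and the clearing optimization (2-cell columns
reduced first; edges they pair are skipped as 1-dimensional births already
accounted for). Columns are represented as arbitrary-precision integers so a
column addition is a single XOR; an 80×80 mosaic (~26k cells) reduces in
~0.1 s and a 160×160 mosaic in ~1.2 s on one core. One essential H₀ class
per connected component survives with death +∞; a full rectangular image has
no essential H₁. Zero-persistence pairs are discarded from emitted diagrams —
they carry zero weight under the linear persistence-image weighting, so
nothing downstream can see them.

**Independent oracle.** `brute_force_betti` computes b₀ by labelling
8-connected components of the pixel sublevel set (scipy union-find) and b₁
from the Euler characteristic, b₁ = b₀ − (V − E + F) counted over cells with
value ≤ ε. It shares no code with the reduction; the test suite and the
acceptance script require exact agreement of both Betti curves at every
critical value on batches of random images.

**Essential intervals** are capped to the global intensity maximum before
vectorization (policy `cap_to_max`; `drop` available). Capping is idempotent
and can produce a zero-persistence point (e.g. a constant image), which then
carries zero weight.

## Persistence images

Points (b, p = d − b) are rasterized on an n_x×n_y grid (default 20×20 per
homology dimension) with isotropic Gaussian kernels and linear weighting
w(p) = p / p_max. Pixel values are the integral of the weighted Gaussian over
the pixel, computed as products of 1-D normal CDF differences — exact at any
resolution, unlike center-point evaluation. The linear weight vanishes on the
diagonal, which is what makes the representation stable to diagram
perturbations. Grid bounds ([min birth, max birth] × [0, max persistence]),
the bandwidth σ = 0.05 × (training intensity range) and p_max are fitted on
training diagrams only and reused frozen for held-out subjects; the
cross-validation loop refits them inside every fold, and the test suite
asserts that the held-out fold is never seen (leakage audit).

H₀ and H₁ images are computed on shared bounds and both feed the feature
vector by default; a `use_dims` switch restricts to either.

## LBP features

Uniform local binary patterns at P=8, R=1: bit k set iff neighbor_k ≥ center,
neighbors clockwise from the top-left, borders excluded rather than padded.
u2 mapping (58 uniform bins + catch-all = 59 bins per image, 118 per subject
over H₀+H₁) with normalized histograms is the default — the canonical texture
configuration, and a feature count commensurate with cohorts of tens of
subjects. The ≥ convention sends constant regions to code 255 and makes all
codes invariant under strictly increasing intensity transforms.

## Classifier and evaluation

CART decision tree grown to purity: gini criterion, best splitter, no depth
limit, min_samples_split 2, min_samples_leaf 1, no pruning, all features,
uniform class weights, `random_state=33`. Scores are positive-class leaf
fractions. Stratified 5-fold cross-validation (shuffled, configurable seed)
preserves class proportions per fold up to rounding. Metrics: balanced
accuracy, support-weighted F1, AUROC by the Mann–Whitney rank statistic with
ties credited ½ (fully grown trees produce many tied scores, so the tie rule
is load-bearing), and average precision as the step-sum under the
precision–recall curve. Fold values are aggregated as median and unscaled
median absolute deviation. Cohort description uses counts with percentages
(one decimal) and medians with type-7 (linear interpolation) quartiles.

## The phantom generator

Real cohort images are not shareable, so synthetic phantoms define the study
conditions. Each phantom is a 128-px slice: intensity 1.0 outside an
elliptical liver mask (half-axes 48×58 px around the center), background 0.5
inside, and two dark primitives at 0.5 − contrast:

* **blobs** (disks) create H₀ components that die when the background level
  merges them — persistence = contrast depth;
* **rings** (annuli, interior left at background) each create exactly one H₁
  loop, born at the ring intensity and dying when the interior fills —
  persistence = contrast depth. Noise-free, the H₁ interval count equals the
  ring count, which the tests assert against both the reduction and the
  Betti oracle.

Features are placed by seeded rejection sampling (≤1000 attempts per
feature), largest-first, fully inside the mask and mutually non-overlapping,
so the designed topology is realized exactly. Additive Gaussian noise
(σ = 0.1 × contrast by default) is smoothed to a correlation length
(`noise_smoothing`, px) and added inside the mask only; intensities are
clipped to [0, 1]. Gaussian rather than Rician noise is deliberate: the
pipeline consumes only the ordinal structure of intensities.

Class profiles: *decomp* has 30 blobs (r 2–3), 12 rings (r 3.5–5), contrast
0.15, smoothing 2.0; *no_decomp* has 10 blobs (r 4–7), 5 rings (r 8–14),
contrast 0.35, smoothing 1.0. Low contrast makes decomp features short-lived;
the smoother noise field has fewer local minima, so fewer components coexist
at any threshold and the Betti numbers stay in a narrower range, while the
rougher, higher-amplitude no_decomp field sustains many long-lived features —
the qualitative barcode contrast between the clinical outcome groups
(narrow vs wide Betti range, short vs long 1-dimensional bars). Over 20
seeds the simulated contrast is max b₀ ≈ 57 vs ≈ 77 on mosaics (≈ 63 vs
≈ 103 on full slices) and mean H₁ persistence 0.015 vs 0.024, with the
orderings significant at α = 0.01 (one-sided).

**What the phantoms do not emulate:** anatomy (vessels, lesions, lobar
shape), MR physics (bias fields, Rician noise, partial volume), inter-scanner
intensity variation, or any overlap between classes in primitive geometry.
The two classes are far better separated than real patients — the end-to-end
cross-validated AUROC on default phantoms is ≈ 1.0, versus 0.80/0.84
reported for the clinical derivation/validation cohorts. Passing the
end-to-end check therefore demonstrates that the chain of stages preserves
and recovers a designed topological class difference; it says nothing about
clinical effect sizes.

## Numerical and design choices

* **Patch size**: 32 px default in `patching` (divides 256–512 px clinical
  matrices); the pipeline default is 16 px so the 5×5 mosaic (80×80) fits the
  128-px phantoms with ≥25 candidate windows (the ellipse yields 28).
  Candidates live on a non-overlapping stride grid to avoid duplicated
  texture inflating topology; ranking is by descending liver fraction with
  row-major tie-break, so selection needs no seed.
* **Mosaic seams** can create artificial topology where tiles abut;
  provenance (source origin per tile) is recorded so seam-touching features
  can be audited, but they are not suppressed.
* **3-D volumes** contribute their single largest-liver-area axial slice
  (ties to the smallest index).
* **Cohort sizes**: analysis and acceptance runs use 30 subjects per class —
  the scale of the clinical derivation cohort (54) — and 5-fold CV;
  the oracle-equivalence batches use 100 random 8×8 images.
* **Degenerate inputs**: non-finite pixels, non-monotone complexes,
  one-class label vectors, empty diagrams, sub-3×3 LBP inputs and
  out-of-bounds windows all raise typed errors; subjects whose mask cannot
  supply 25 qualifying patches are excluded and listed in the report rather
  than aborting the run, and the run aborts only if fewer than k subjects
  per class remain.
* **Determinism**: every stochastic step (phantom placement and noise, fold
  shuffling) is a pure function of an integer seed; the tree's
  `random_state` is fixed at 33. Identical configuration and seeds reproduce
  reports bit-identically.

## Known limitations

* Only H₀/H₁ of 2-D slices; no 3-D cubical complexes or H₂.
* The published clinical performance cannot be reproduced or refuted here —
  the patient images are unavailable by design; the published per-fold
  metrics are used only as aggregation inputs. Two published dispersion
  values (balanced-accuracy MAD, F1 median) are inconsistent with their own
  fold values; this package reports recomputed values.
* The persistence-image and LBP hyperparameters of the original clinical
  analysis are unreported; the defaults here are the standard choices in the
  respective literatures and are exposed as configuration.
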