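# Methods

`rfseg` segments a single-channel head MR slice into tissue classes by
treating segmentation as *multitexture* clustering: the major brain tissues
(CSF, gray matter, white matter) are assumed to differ in their spatial-
frequency content, not only in mean intensity.  The pipeline has five
stages — skull stripping, undecimated wavelet decomposition, masked feature
extraction, unsupervised feature selection, and rough-fuzzy clustering —
each usable on its own.

## Skull stripping

The brain mask comes from intensity thresholds and binary morphology, and
relies on the T1 intensity ordering *background < membrane < brain < skull*:

1. 3×3 median filter (edge-replicated borders).
2. `T_i` = mean intensity of the filtered image.
3. Bounding rectangle of all pixels brighter than `T_i` ("where the skull
   starts"): the first/last row and column containing any such pixel.  The
   rectangle is inclusive of its boundary rows/columns.
4. `T_f` = mean intensity inside the rectangle.
5. `T` = mean of the membrane set: pixels inside the rectangle with
   `floor < intensity < T_f`.  The exclusive lower bound (default 0) keeps
   pure black background inside the rectangle corners from dragging the
   membrane mean down; it is configurable for images whose background is
   not exactly zero.  An empty membrane set falls back to `T = T_f / 2`
   with a logged warning.
6. Binarize at strictly `> T`, open with a 13×13 octagon (detaches the
   skull ring), keep the largest 8-connected component, close with a 21×21
   octagon (fills interior gaps).

Open design points resolved here: the membrane is defined purely by
intensity (no geometric band construction — the intensity relations are the
only stated property of the meninges in this scheme); the binarization
comparison is strict; the discrete octagon is built as `octagon(m, n)` with
`n = size // 3` so it inscribes the requested box, with square and disk
elements available since octagon vertex offsets are not canonical.
Component ties break toward the component encountered first in raster
order.

## Undecimated wavelet features

Texture features are per-pixel coefficients of an à-trous (undecimated,
shift-covariant) separable 2-D dyadic wavelet decomposition with the
orthonormal Daubechies 6-tap pair.  At level *j* the filters are upsampled
by inserting `2^(j-1) - 1` zeros between taps; rows then columns are
correlated with the forward filters (equivalently, convolved with the
time-reversed filters); nothing is subsampled, so every subband has the
image's shape.  Level *l* yields `d = 3l + 1` subbands —
`LL_l, LH_1, HL_1, HH_1, …, LH_l, HL_l, HH_l` — and the default level is 2
(7 subbands), past which detail subbands mostly encode noise at typical MR
resolutions.

Numerical conventions, fixed for reproducibility:

* sqrt(2) two-scale filter normalization at every level (the downstream
  clustering is scale-sensitive per feature, so the convention matters and
  is fixed rather than optional);
* symmetric (mirror) boundary extension by default — periodic is available
  and makes the transform exactly shift-covariant, but mirrors avoid edge
  artifacts at the skull boundary;
* the highpass filter is rebuilt from the quadrature-mirror relation
  `h_hi[k] = (-1)^k h_lo[5-k]` so the filter-pair identities
  (`sum h_lo = sqrt 2`, `sum h_hi = 0`, `sum h_lo^2 = 1`) hold exactly.

The brain mask is applied to each subband; the masked pixels in raster
order form an `n × d` feature matrix.

## Energy-based MRMS feature selection

With no class labels available, features are scored by *energy*: the mean
squared deviation of all entries of a feature subset from the subset's
grand mean.  Relevance of a feature is the energy of its singleton set;
significance of feature *j* w.r.t. a selected feature *i* is
`E({i,j}) - E({i})` — zero means *j* is dispensable given *i*, and the
value is used signed.  Greedy selection picks the most relevant feature,
then repeatedly prunes candidates with zero significance w.r.t. any
selected feature (relative tolerance `1e-12`, since exact floating-point
zeros are rare) and picks the candidate maximizing relevance plus average
significance over the selected set.  Ties break toward the lowest feature
index for determinism.

The default feature count is `m = ceil(sqrt(d))` — 3 of the 7 level-2
subbands.  Features are used on their raw subband scale: the criterion is
variance-based by design, so per-feature standardization would erase
exactly the signal it ranks.  (An optional z-scoring flag exists for the
clustering stage only.)

Both the scoring and the greedy loop are checked against an independent
exhaustive step-wise oracle on small random matrices; selection decisions
are invariant to translating all features and equivariant under positive
scaling (every score scales by the square).

## Robust rough-fuzzy c-means

Each cluster has a centroid, a possibilistic *lower approximation* (objects
certainly inside) and a probabilistic *boundary region* (objects possibly
shared).  Lower-region objects carry typicalities
`nu_ij = 1 / (1 + (||x_j - v_i||^2 / eta_i)^(1/(m2-1)))` that depend only on
their own cluster; boundary objects carry FCM memberships
`mu_ij ∝ ||x_j - v_i||^(-2/(m1-1))` normalized over clusters.  The region
split is data-driven: `delta_1` is the average gap between each object's two
highest typicalities (gap above `delta_1` ⇒ lower region of the argmax
cluster), and `delta_2` is the average top typicality of the remaining
ambiguous objects; a boundary object also joins the boundary of every other
cluster whose typicality clears `delta_2` (the printed top-two rule,
generalized symmetrically to c > 2).  Centroids are
`omega * C1 + (1-omega) * D1`, the typicality-weighted lower mean blended
with the membership-weighted boundary mean; with the default `omega = 0.99`
the certain objects dominate, giving robustness to noise without the
coincident-cluster collapse of pure possibilistic clustering.

Defaults: fuzzifiers `m1 = m2 = 2`, `omega = 0.99`, scale multiplier
`K = 1`, at most 100 iterations, centroid tolerance `1e-5`.  Iteration
stops when the region assignment repeats *and* the centroid shift is below
tolerance.  Hard output labels are the lower-region cluster where one
exists, else the argmax typicality restricted to the object's boundary
clusters (ties to the lowest index).

Startup and stability choices:

* **Initialization.** Hard c-means (Lloyd) from c distinct randomly chosen
  objects, seeded; empty clusters re-seed at the farthest object.  Its
  converged prototypes are the rough-fuzzy starting centroids.
* **eta bootstrap.**  The typicalities need `eta` and `eta` (the cluster's
  zone of influence, `K * sum nu^m2 d^2 / sum nu^m2`) needs memberships; the
  circle is broken once by plugging the FCM memberships of the initial
  centroids into the eta formula.  Thereafter eta is refreshed each
  iteration from the current typicalities (freezing it for the whole run,
  as classical possibilistic clustering does, is available as a flag).
* **eta floor.**  Refitting eta from typicalities has a known collapse
  mode: once a centroid locks onto its single nearest object, eta tracks
  the shrinking nearest distance and decays superexponentially to zero,
  underflowing the memberships.  Each refreshed `eta_i` is therefore
  floored at `1e-3` of its bootstrap value; on well-conditioned runs the
  floor is never active (phantom runs stay one order of magnitude above
  it), and on degenerate runs it keeps the algebraic invariants
  (`nu ∈ (0, 1]`) intact.
* **Limiting regimes.**  Pinning `delta_1 = 1, delta_2 = 0` puts every
  object in every boundary and the update sequence reduces exactly to plain
  FCM; pinning `delta_1 = 0` puts every object in a lower region and the
  centroid update becomes the possibilistic weighted mean.  Both reductions
  are asserted in tests against independent reference implementations.

Degenerate-input behaviour: membership ties break toward the lowest
cluster index; an object coinciding with several centroids goes to the
lowest-indexed one; a cluster whose lower and boundary regions are both
empty keeps its previous centroid (logged).

## Evaluation

Cluster ids are arbitrary, so predictions are matched to truth classes by
an optimal one-to-one assignment on the contingency table (Hungarian
algorithm) rather than greedily.  Label 0 (background/outside-mask) is
pinned to itself when present in both images.  Per-class metrics — Jaccard,
Dice, sensitivity, specificity, FDR, LR+ — are one-vs-rest within the full
image, so background specificity is meaningful; the macro row is the
unweighted class mean.  Undefined 0/0 rates are reported as NaN and
excluded from macro averages (with a logged note) rather than silently
counted as zero.

## The phantom: what it does and does not emulate

`make_phantom` builds a 256×256 head-like image: background 0, a bright
skull ring (level 250, radii 98–110), a darker membrane band (level 50,
radii 90–98), and a brain disk (radius 90) split into three equal wedges.
The wedges mimic T1 tissue contrast with base levels 100 / 145 / 190
(CSF-, GM-, WM-like) and carry distinct textures: smooth, a period-16
sinusoidal grating, and a period-4 grating at a different orientation
(filtered-noise textures with a chosen correlation length are also
available).  Texture amplitudes default to 8 and additive Gaussian noise to
sigma 3 (Rician magnitude noise is available, as that is the true MR noise
model).  All randomness flows through one seed.

Two deliberate properties:

* the intensity ordering background < membrane < tissues < skull makes the
  phantom a valid input for the mean-threshold skull stripper, and the
  histogram is multi-modal as that procedure assumes;
* textures are zero-mean additive, so they alter subband energies without
  moving class means — but the *base levels* still differ.  That is a
  modelling choice, not an accident: a raw per-pixel wavelet coefficient of
  a pure zero-mean texture oscillates through zero, so two classes that
  differ only in texture overlap heavily in any per-pixel feature and no
  pixelwise clustering can separate them cleanly.  Real T1 tissues differ
  in both mean and texture; the phantom does the same, letting the
  smoothed approximation subband carry the separation while the detail
  subbands differentiate the energy signatures that feature selection
  ranks.

The phantom does not emulate bias fields (intensity inhomogeneity),
partial-volume mixtures, anatomical geometry, or scanner-specific noise
correlation.  Passing the recovery tests therefore demonstrates that the
pipeline's stages compose correctly and recover ground truth under the
method's own assumptions — not clinical-grade accuracy on real scans.

On the default phantom (seed 42) the full default pipeline reaches
per-class Jaccard ≥ 0.80 for all three tissue wedges and brain-mask Dice
≥ 0.95; across other seeds the smooth (CSF-like) class ranges roughly
0.78–0.82, the fluctuation coming entirely from the noise/texture
realization along wedge boundaries, where the level-2 approximation
subband's ~16-pixel support mixes neighbouring classes.

## Problem sizes

Tests and the acceptance script run the full pipeline on the 256×256
phantom (~25k masked pixels, 3 features, 3 clusters; a couple of seconds),
oracle equivalences on 100 random matrices with n ≤ 50, d ≤ 6, and metric
identities on 100 random 9×9 mask pairs.  These sizes were chosen to make
every check exact or tight while keeping the whole suite interactive.

## Known limitations

* 2-D only: volumes are reduced to their middle axial slice.
* No bias-field correction; strongly inhomogeneous images violate the
  global-threshold assumptions of the skull stripper.
* The skull stripper requires a bright skull ring; it fails (by design,
  with a clear error) on constant or ringless images.
* `eta` refresh is a fixed-point iteration without a convergence guarantee;
  the region-stability stopping rule plus `max_iter` bound the run instead.
* The number of clusters is user-supplied; no model selection is attempted.
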