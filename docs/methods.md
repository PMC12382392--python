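# Methods

## Scope and model

nitroscan implements a two-modality phenotyping analysis for potted leafy
vegetables under controlled nitrogen fertigation. The quantities of interest
are leaf total reduced nitrogen (TRN) and nitrate (NO3), both in mg N per g
dry weight, and shoot dry weight (DW) in grams. The working hypotheses are
the field-standard ones: leaf chlorophyll — and hence visible-band greenness
— tracks leaf nitrogen, while canopy geometry (height, width, enclosed
volume) tracks above-ground biomass. The pipeline therefore extracts
greenness-type vegetation indices from calibrated top-view RGB images and
geometric traits from colored point clouds, regresses the measured traits on
them, and models each feature's response to nitrogen dosage to locate an
optimum.

## Spectral processing

Raw digital numbers are converted to relative reflectance per band as
`(DN − mean(dark)) / (mean(white) − mean(dark))`, i.e. both the raw frame
and the white reference are dark-subtracted, so a pixel at the dark mean
maps to 0 and one at the white mean to 1. Reflectance above 1 (specular
highlights) is flagged, not clipped — clipping would silently bias index
means and discard information useful for masking.

Leaf segmentation is Otsu's threshold on the per-pixel excess-green image
(ExG = 2G − R − B) with small components removed (default < 25 px). This is
a deliberately classical stand-in for learned segmenters: the downstream
pipeline needs only a binary mask, and externally produced masks are
accepted verbatim through the same interface, so any CNN segmenter can be
plugged in. Segmentation quality is scored by intersection-over-union
against reference masks.

All 15 vegetation indices are computed **per pixel first, then averaged**
over the mask. The alternative (index of the mean reflectance) differs for
every nonlinear index; per-pixel-first is the convention adopted throughout
and is what the mask-average wording of the field's protocols implies.
Pixels whose denominator magnitude falls below ε = 1e−6 are excluded from
that index's mean and counted, rather than clamped — a single near-singular
pixel (e.g. G + R − B ≈ 0 for VARI) would otherwise dominate a plant mean.
If every pixel is excluded the index is reported missing (NaN), never zero.
TGI uses band-center wavelengths (λR, λG, λB) = (670, 550, 480) nm by
default — the values of the index's source literature, since consumer
cameras do not publish band centers — and is configurable. RGBVI and EGMERI
are implemented exactly as tabulated in the protocol this package follows
(`(G − R·B)/(G + R·B)` and `ExG − ExR` with ExR in its normalized form),
even where other literature variants exist.

## Structural processing

Denoising partitions the cloud into cubic voxels (edge 1 cm) anchored at the
bounding-box minimum corner and keeps points whose voxel holds **more than
4 points**. The anchor matters: the same cloud under a shifted grid denoises
differently, so the origin is an explicit parameter, recorded in the CLI's
JSON sidecar, and defaults to the bounding-box corner. An all-sparse cloud
yields an empty result with a warning rather than an exception, so batch
runs survive degenerate scans.

Plant/background separation is K-means with k = 2 on the RGB attributes
only. Initialization is deterministic and point-order invariant: the first
center is the color farthest from the mean color, the second the color
farthest from the first, ties broken lexicographically. The plant cluster is
the one with the higher mean excess-green of its colors. Degenerate input
(all colors identical) raises.

The nine traits: HT is max z − min z of the segmented plant (using the
z-extent rather than raw elevation makes the trait invariant to the
arbitrary vertical datum of handheld scans). CW is the exact maximum
pairwise distance of the XY-projected points, computed over the 2-D
convex-hull vertices (lossless, since the diameter is attained at hull
vertices; collinear sets fall back to brute force). CV is the convex-hull
volume by default; an alpha-shape mode (Delaunay tetrahedra with
circumradius ≤ α, default α = 0.5 m) gives a tighter envelope and never
exceeds the convex volume. PD = PC/CV and is reported missing when the hull
is degenerate (CV = 0). CR is the population variance of per-occupied-voxel
point counts. PC75/PC50/PC25 count points higher than 75/50/25 % of the
plant height above the base — the height-fraction reading; a z-percentile
variant exists behind `percentile_counts=True` but makes the counts fixed
fractions of PC by construction, which is why it is not the default.

## Regression protocol

The split is 70/30 with the **test partition floored**
(test = ⌊n·(1−fraction)⌋; 84 plants → 59 train / 25 test), stratified by
dose group whenever every group has ≥ 2 members and both partitions can hold
all groups. SVR and Lasso operate on z-scored features whose statistics come
from the training split only; the random forest uses raw features (scaling
is immaterial to axis-aligned trees). Defaults are SVR C = 10, ε = 0.1,
linear kernel; RF 100 trees, depth 5; Lasso λ = 0.01 — with an optional
small grid search (5-fold CV inside the training split) bracketing those
values. The linear kernel is the SVR default so that prediction and the
weight-based relevance analysis use the same model family; RBF is available
by configuration but is rejected for relevance, where per-feature weights
are undefined.

Metrics follow their definitions exactly: ME = mean(pred − obs),
MAE, RMSE, rRMSE = RMSE / mean(obs) (missing when the observed mean is
zero; the mean convention is used rather than the range), and R² computed
on the test set as 1 − SS_res/SS_tot. Relevance is |linear-SVR coefficient|
per standardized feature, normalized to sum to 1 within each fit, averaged
over 100 fits on fresh random splits drawn from a master seed.

## Dose-response analysis

Nitrogen dose designs of this kind (20–800 ppm) are strongly right-skewed,
so each response is regressed on u = √dose; the model is the OLS quadratic
y = a·u² + b·u + c, with fewer than three distinct dose levels rejected as
rank-deficient. A concave fit (a < 0) whose vertex −b/2a lies within the
observed u-range yields an interior peak dose (−b/2a)², reported together
with R² and residual SE (dof = n − 3). Vertices outside the range are
clamped to the boundary and flagged — an optimum is never extrapolated
beyond the design. Indices that respond inversely to greenness (e.g. ExR)
have an interior *minimum* at the same vertex; the aggregation path
therefore asks for an extremum of either sign for its configured features,
while the plain `fit_curve` contract defaults to maxima only.

The optimal dosage is a two-stage mean: interior peaks are averaged within
the spectral group (defaults: ExR, VARI, GMRI — the chlorophyll-linked
trio) and within the structural group (defaults: HT, CV), then the two
group means are averaged. Non-interior fits are excluded and listed; a
group with no interior peak is an error naming the group. The grouping is
fully configurable since no canonical list exists. Model selection support
(`compare_polynomial_orders`) scores linear/quadratic/cubic fits in u by
small-sample-corrected AIC.

## Baselines

SoA-NC computes the Dark Green Color Index per masked pixel,
DGCI = [(H − 60)/60 + (1 − S) + (1 − V)]/3 (hue in degrees), the
source-literature form, bounded in [0, 1] for hues in the green range
[60°, 180°]; achromatic pixels are excluded and counted. It runs either as
a raw index comparison or through a linear calibration to nitrogen. SoA-DW
segments the green channel by Otsu, converts the plant-pixel count PPN to
leaf area as PPN · (PL·MF)² — the squared ground-pixel length, since the
literal product PPN·PL·MF is dimensionally a length, not an area (the
literal form is available behind a flag) — and predicts DW by an OLS line
through destructive calibration pairs.

## Synthetic-experiment generator

The generator emulates the greenhouse design the analysis assumes: 84
plants, 8 dose groups at 20–800 ppm with replicates (11, 11, 11, 11, 10,
10, 10, 10) — which groups carry the 11th replicate is arbitrary and fixed
to the first four. Traits are drawn as curve(dose) + Gaussian noise,
truncated at zero, from concave quadratics in √dose peaking at 150 ppm
with peak values TRN 60, NO3 10, DW 55 — magnitudes typical of leafy
greens. Trait noise defaults are sd 3 g for DW (≈ 6 % CV) and sd 9 / 1.5
for TRN / NO3 (≈ 15 %): the larger nitrogen scatter encodes the design
premise that the *spectral* channel observes the realized leaf nitrogen
(greenness is an affine function of the plant's TRN) while *structure*
reflects only the dose-level mean through DW — without it, the shared dose
dependence would let canopy size predict leaf nitrogen nearly as well as
color does, which is not the regime this kind of study reports.

Imagery: leaves are random ellipses whose count grows with DW (Poisson,
3 + 0.08·DW), painted with the TRN-coupled reflectance onto a dark
background, then converted to digital numbers with per-pixel sensor noise
(sd 1 DN) and per-plant reflectance jitter (sd 0.04) representing
non-uniform illumination and shading — the dominant real-world error source
for plant-level index means, since pixel noise averages out over the mask.
Dark and white calibration frames are generated alongside.

Clouds: the canopy is a half-ellipsoid whose height and width are affine in
DW with multiplicative lognormal jitter (sd 0.15) for scan-to-scan
variability. Points are laid down ≥ 5 per occupied 1 cm voxel, strictly
interior to each cell; a dark background plane occupies z-level-0 voxels,
with one point pinned exactly at the origin so the bounding-box minimum —
and hence the denoiser's grid — is known; injected noise points occupy
otherwise-empty voxels with ≤ 4 points each. Consequently density denoising
at the default threshold removes **exactly** the injected noise set, a
contract the tests assert over 100 seeds. Each plant consumes three
independent RNG substreams (traits, image, cloud) spawned from the
experiment seed, so regenerating one modality never perturbs the others,
and the trait-only fast path reproduces the full generator's values.

The jitter magnitudes were chosen so that model skill on generated data
falls in the realistic sub-unity range reported for studies of this type
(nitrogen-trait R² well below biomass R², both clearly below 1) rather than
the near-perfect recovery a noiseless simulation would give. What passing
tests on this generator demonstrate is that the *pipeline machinery* —
calibration, segmentation, trait math, model protocol, peak analysis — is
correct and that the qualitative multimodal pattern (spectral → nitrogen,
structural → biomass, combined competitive) emerges under the assumed
couplings. They do not demonstrate performance on real imagery: the
generator has no shadows or specularity gradients within a plant, no leaf
occlusion or overlap geometry, no registration artifacts in the clouds, and
its background is trivially separable.

## Numerical choices and degenerate inputs

* Zero-denominator index pixels: excluded at ε = 1e−6, counted, never
  clamped; all-excluded → NaN.
* Empty mask, both-empty IoU, all-identical cloud colors, zero-variance
  segmentation input, zero-variance regression target, < 3 distinct dose
  levels: all raise with specific messages.
* Degenerate hulls (coplanar points) give CV = 0 and PD = NaN rather than
  raising; all-sparse denoising warns and returns an empty cloud.
* K-means on colors is deterministic given the seed and point set, and
  invariant to point order by construction of the initializer.
* Voxel counts use exact integer grid indices; generated points keep a
  0.5 mm margin from voxel faces so floating-point rounding cannot move
  them across cells.
* AICc guards log(0) for exact polynomial fits with an RSS floor of 1e−300.

## Problem sizes

Default runs use the full 84-plant design with 96 px images and ~1,200-point
clouds; the complete pipeline (including 100-iteration relevance for three
targets) takes a few seconds on one CPU. Majority-vote properties
(multimodal accuracy pattern, within- vs between-block correlation) are
asserted over 20 replicate 84-plant experiments; Monte-Carlo checks
(dose-peak recovery, denoising exactness) use 100 seeds. These sizes were
chosen to keep every stochastic assertion's sampling error far from its
decision boundary.

## Known limitations

* The optimal-dose estimate inherits the scatter of individual feature
  peaks; with the default noise the group peaks vary by ±15–25 ppm around
  the 150 ppm truth even though the two-stage mean stays within a few ppm.
* The alpha-shape volume uses a circumradius threshold in meters; it is not
  scale-free, and the default 0.5 m effectively reduces to the convex hull
  on decimeter-scale plants unless α is lowered.
* rRMSE uses the mean-observation convention; range- or SD-normalized
  variants are not provided.
* The ExG+Otsu segmenter assumes a dark, homogeneous background; natural
  scenes will need an external mask through the mask-file interface.
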