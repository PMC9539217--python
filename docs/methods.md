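# Methods

This note documents the models, conventions and defaults behind
`canopyfuse`, the design choices made where the workflow was genuinely
open, and what the synthetic scenes can and cannot tell you about real
data.

## Scene simulator

The simulator emulates a UAV acquisition over a temperate mixed
conifer/broadleaf stand: a multi-return LiDAR cloud (default
180 points/m², up to 5 echoes, 16-bit intensity) and a co-registered
at-surface-reflectance cube (default 10 cm GSD, 300 bands over
400–1000 nm, so ~2.0 nm sampling), plus a ground-truth stem map.

**Terrain** is the sum of two low-frequency sinusoids with seed-drawn
phases, under 3 m of relief over 100 m — enough to exercise ground
filtering without dominating crown geometry.

**Trees.** Stems are placed by rejection sampling with a minimum
spacing; two presets ship: `sparse` (50 trees / 50×50 m, spacing
≥ 3.5 m, essentially non-overlapping crowns) and `dense` (90 trees,
spacing ≥ 2.0 m, overlapping crowns). Each of the five species (JM, LG,
TA, QM, UP) has a crown form (larch is a cone; the broadleaves are
ellipsoids or domes), a height and crown-radius range, a 300-band
sunlit reflectance endmember built from a green bump, a logistic red
edge and a 970 nm water dip, and a Gaussian echo-intensity
distribution. On top of the species parameters every tree draws three
random effects — an intensity factor (sd 0.12), a spectral brightness
factor (sd 0.06) and an NIR tilt (sd 0.05) — because without
within-species variation all three feature sources classify perfectly
and the selection/fusion machinery is never stressed.

**LiDAR sampling.** Pulses sit on a jittered grid at the configured
density. A pulse over one or more crowns returns first from the highest
crown top surface (z jitter sd 0.15 m); each further echo occurs with
probability 0.4 given the previous one (so ~40% of crown pulses have a
second return), lies deeper in the crown but above the crown base, gets
±0.3 m horizontal jitter, and its intensity is attenuated by 0.7 per
echo order — making first-echo and total-echo intensity statistics
genuinely different. Open-ground pulses return once from the terrain
with 1 cm vertical noise (the ranging-accuracy class of survey-grade UAV
scanners); ground under crowns is considered occluded. Every point
carries a hidden provenance tag (`ground`, `crown:<id>`,
`noise_high/low`) used only by tests.

**Cube rendering.** Background pixels get a linear soil ramp. A crown
pixel takes the endmember of the tree whose top surface is highest
there, scaled 1.0 if sunlit or 0.45 if shaded, times a per-pixel
jitter (sd 0.03), plus i.i.d. band noise (sd 0.01), clipped to [0, 1].
Sunlit/shaded is decided by the cosine between the analytic crown
surface normal and a fixed sun direction (azimuth 180°, elevation 45°),
thresholded at the per-crown `shadow_fraction` quantile (default 0.35) —
the simplest mechanism that reproduces the NIR sunlit/shadow gap the
850 nm > 0.25 rule exploits (shaded pixels land near 0.45 × NIR < 0.25).

**What it does not model:** radiative transfer and BRDF, mixed boundary
pixels beyond geometric overlap, wind or registration error,
multi-temporal change, understory vegetation, and occluded ground
returns. Passing tests therefore demonstrate internal correctness and
the workflow's statistical behaviour under controlled conditions — not
accuracy on any real stand; real accuracies will be lower and
segmentation harder wherever canopies interlock.

## Preprocessing

* **Denoise**: statistical outlier removal; a point is noise when its
  mean distance to its k=10 nearest neighbours exceeds the global mean
  by more than 3 sd. Note the rule necessarily trims a sub-percent tail
  on any Poisson-distributed clean cloud; it is a flagging partition,
  never a coordinate transformation.
* **Ground filter**: progressive TIN densification. Seeds are the
  lowest point per 20 m cell plus virtual boundary seeds (bounding-box
  corners and edge midpoints at the nearest seed's elevation) so the
  initial TIN covers the full extent. A candidate joins the ground set
  when its distance to its containing triangle's plane is ≤ 1.5 m and
  the angle to each triangle vertex is ≤ 10°; sweeps repeat, with
  retriangulation, until no point is admitted.
* **Height normalization**: height above ground = z minus the linearly
  TIN-interpolated ground elevation; outside the ground hull the nearest
  ground point is used and counted; negative heights are clamped to 0
  (interpolation artifacts are physically meaningless) with the count
  reported.
* **Spectral smoothing**: Savitzky–Golay, window 7, polynomial order 2,
  endpoint handling by polynomial fit on the truncated window. The
  filter is linear and reproduces polynomials up to its order exactly.
* **Co-registration**: full 2-D quadratics x′(x,y), y′(x,y) fitted by
  least squares to ≥ 6 control-point pairs (rank checked); resampling
  onto the LiDAR frame is nearest-neighbour so reflectance values are
  never blended across crown boundaries.

## Segmentation and crown geometry

The clusterer sweeps vegetation points (height ≥ 2 m) in descending
height: a point joins the existing cluster whose 2-D point set is
nearest if that distance is ≤ the 2 m spacing threshold, else it seeds a
new cluster whose seed is recorded as the apex. Clusters under 50 points
are discarded. A uniform spatial hash with cell = threshold makes the
sweep O(n); an exhaustive-sweep oracle checks equivalence on small
clouds.

Crown outlines are alpha shapes (union of Delaunay triangles with
circumradius ≤ alpha); alpha defaults to 3× the median nearest-neighbour
spacing of the projected points, which is scale-free across densities,
with a convex-hull fallback when the shape is disconnected or
degenerate. Structural parameters: H_T = max height; W_C = mean
bounding-box extent of the outline (no standard definition exists, this
one is symmetric and cheap); A_C = outline area; V_C = Σ over 0.5 m
height slices of slice convex-hull area × 0.5 m, from the lowest point
up (a single-height crown degenerates to one slice).

Matching against a reference stem map is greedy one-to-one by ascending
apex-to-stem distance, accepting pairs within 2 m and 20% height
agreement; stems claimed by ≥ 2 detections are over-segmented,
detections covering ≥ 2 stems under-segmented, unmatched stems missed.
The distance+height correctness rule is this package's convention;
detection rate = detected/reference and total accuracy =
correct/reference may legitimately exceed or trail each other.

## Crown spectra

Crown pixels are those whose centres (standard raster convention) fall
inside the outline. The tree spectrum is the mean of the 100 sunlit
pixels (850 nm reflectance > 0.25, on the [0, 1] scale) nearest the
outline centroid, ties broken row-major. Fewer sunlit pixels → all are
used and a shortfall flag set; none → the brightest-NIR decile is used
with a fallback flag (real sun-exposed crowns essentially always have
sunlit pixels; the fallback keeps degenerate synthetic or shaded crowns
in the table rather than dropping them silently).

## Feature catalogs

**Hyperspectral (363)**: 300 bands (`band_1..band_300`, 1-based display
names), 18 vegetation indices, PCA1–10, MNF1–15, ICA1–20. All
wavelength lookups are nearest-band on the metadata grid (≤ ~1 nm off at
2 nm sampling). Index conventions worth noting:

* SGI is the mean over 500–599 nm, RGRI the ratio of band sums
  600–699 nm over 500–599 nm.
* REPI is the wavelength of the maximum finite-difference first
  derivative over 690–740 nm, each difference assigned to the upper band
  of its pair; ties take the longest wavelength (the far side of the
  inflection). REPI is scale-invariant.
* MRESRI uses the denominator (ρ705 + ρ445) as printed in the source
  table this catalog follows; `mresri_literature=True` switches to the
  common (ρ705 − ρ445) form. PRI likewise follows its printed form
  (ρ570 − ρ531)/(ρ531 + ρ570), the sign-flip of the common form.
* Zero denominators (e.g. SIPI and MRENDVI on a flat spectrum, where
  they are 0/0 by construction) yield a missing value plus a flag,
  never a fabricated number.

The PCA/MNF/ICA triple is fitted on the matrix of crown mean spectra —
one 300-vector per tree, not image pixels — keeping the pipeline
image-free after crown extraction. MNF estimates a **diagonal** noise
covariance from band-to-band first differences of each spectrum (robust
when trees ≪ bands), whitens, rotates by PCA and orders components by
SNR. ICA is FastICA with a fixed seed; since ICA has no canonical order
or sign, components are sorted by descending log-cosh negentropy and
signed so the largest-magnitude loading is positive, making the catalog
deterministic. Rank shortfalls (too few trees) truncate the component
count with a warning.

**LiDAR (60)**: 3 shape ratios (W_C/H_T, A_C/H_T, V_C/H_T) + per echo
class n ∈ {0 total, 1 first, 2 second}: mean, sample sd (n−1), CV,
Fisher–Pearson adjusted skewness, excess kurtosis and the 25/50/75/95
height percentiles (linear interpolation); five relative-height bins
h/H_T in [0,.2), …, [.8,1] (top closed) whose proportions sum to 1; and
the five intensity moments. The raw H_T, W_C, A_C, V_C stay on the tree
record — 3+27+15+15 is the only decomposition consistent with a
60-column catalog. A statistic whose preconditions fail (empty
partition, mean 0 for CV) is 0 with a sidecar flag, keeping the matrix
rectangular. Bins are tree-relative because absolute bins degenerate
across tree heights; an absolute variant would be a config switch, not a
default.

## Selection and classification

Importance is the random-forest standard mean decrease in Gini impurity
(500 trees, √p features per split, fixed seed; columns sorted by name
internally so the ranking is column-order invariant). Pruning sweeps
features in descending importance and drops any with |Pearson r| ≥ 0.90
against an already-kept feature; pruning runs before truncation to the
top 40, and both lists are exported.

Classification is an RBF SVM (C = 10, gamma scaled by feature variance,
one-vs-one; the workflow fixes these rather than grid-searching, for
reproducibility) trained on the top-k features for k = 1..40, over 120
independent stratified 60/40 splits (seeded from one master seed).
Standardization uses training-fold statistics only; a poisoning test
asserts held-out rows cannot influence the model. The importance ranking
is computed once on the full labeled set — a mild, deliberate selection
leakage matching how such rankings are usually produced and reported; a
strict per-split re-ranking would cost 120× the ranking time and is left
to the caller by re-running with disjoint subsets. Optimal k is the
smallest k whose mean OA is within a stability margin (default 0) of the
curve maximum.

## Accuracy assessment

Confusion matrices are predicted-rows × reference-columns. OA =
100·trace/total; UA_i = 100·m_ii/row_i (commission = 100 − UA);
PA_j = 100·m_jj/col_j (omission = 100 − PA); Kappa =
(p_o − p_e)/(1 − p_e) with p_e = Σ row_i·col_i / total². Display values
round half-up to 2 decimals (matching how such tables are printed);
full-precision values are kept alongside. Zero rows/columns give missing
(NaN) per-class entries, listed explicitly. Segmentation rates are
100·detected/reference and 100·correct/reference; over-detection
(> 100%) is allowed and flagged.

## Determinism and problem sizes

One master seed is expanded by hashing into independent per-stage
streams (scene, ICA, per-source forests and SVM splits), so no stage's
draw count affects another. The shipped demo and the acceptance script
use scaled stands — 40–60 trees on 42–50 m squares, 100–180 points/m²,
and 10–30 split repetitions instead of 120 — sizes chosen so a full run
stays in the minutes range on a single CPU while every catalog,
ranking and curve retains its full structure; all parameters scale up
by config.

## Known limitations

* The spacing-threshold clusterer under-segments interlocking crowns of
  similar height (the `dense` preset shows this by design) and cannot
  find understory trees below the 2 m cutoff or inside larger crowns.
* MNF with a diagonal noise model ignores band-to-band noise
  correlation; with many samples a full noise covariance would be
  preferable.
* The sunlit rule's 0.25 threshold presumes reflectance in [0, 1]; data
  scaled in percent must be rescaled first.
* V_C from 0.5 m slice hulls is biased low for very sparse crowns
  (slices with < 3 points contribute nothing).
* The SVM hyperparameters are fixed, not tuned; on harder stands a small
  grid search over C/gamma may shift the accuracy plateau.
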