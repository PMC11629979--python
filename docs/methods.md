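# Methods

This package quantifies circular nano-size objects (CNOs) on corneocyte
surfaces imaged by atomic force microscopy, and derives a robust density
statistic — the Effective Corneocyte Topographical Index (ECTI) — designed
to be insensitive to imaging artefacts (scan-line stripes, ridges, and
large structural occlusions) that bias the naive whole-image density (the
DTI convention: CNO count divided by the full imaged area).

## Image model and geometry

Height maps are 512 × 512 px covering 20 × 20 µm² (39.0625 nm/px) unless a
metadata sidecar states otherwise. CNOs are circular protrusions with
typical dimensions 273 nm (height) × 305 nm (width); these two scalars
anchor both the detector's size window and the synthetic generator.

## Enhancement

Four deterministic stages, in order:

1. **Gaussian smoothing**, σ = 1 px by default (suppresses pixel noise while
   leaving the ~8 px-wide CNOs intact).
2. **Row-mean subtraction.** AFM scan lines carry per-row offsets; removing
   each row's mean zeroes them exactly and is idempotent.
3. **Min–max normalization** to [0, 1]. A constant image maps to all zeros
   (the only sensible degenerate rule; it propagates to "no detections").
4. **Disk-percentile local-background subtraction.** Rank filters with disk
   footprints of diameter 9 and 15 px at the 50th percentile (running
   medians at the CNO scale and a coarser scale); the mean of the two maps
   is subtracted and the result renormalized. Subtracting a median-disk
   background is the standard local-contrast operator for small bright
   features on structured backgrounds; two scales capture CNO-scale and
   super-CNO-scale background. The operator (percentile, diameters) is
   exposed in `EnhanceConfig` so alternatives can be swapped without
   touching callers.

All stages use reflect boundary handling (no edge discontinuities). The
pipeline is bit-deterministic.

## CNO detection

The classical engine is a multi-scale Laplacian-of-Gaussian detector over
σ ∈ [d_min, d_max] / (2√2 · pixel size) with d defaulting to 150–600 nm,
bracketing the 305 nm CNO width. Scale-space maxima above a response
threshold are filtered by two geometric criteria of the classical
corneocyte-texture lineage:

* **prominence** — peak value minus the local median background (window of
  4σ) must exceed `min_height_prominence` (default 0.05 on the [0, 1]
  image);
* **circularity** — 4πA/P² of the connected half-prominence support
  component must exceed `min_circularity` (default 0.5).

Survivors get score = response / max response and pass through greedy
non-maximum suppression (IoU ≥ 0.3; ties broken by score, then y, then x,
for determinism). External detector outputs (YOLO text with confidences)
plug in through `load_external_detections` and are interchangeable with the
classical engine downstream.

Evaluation follows the standard object-detection protocol: greedy
score-ordered matching at an IoU threshold, COCO-style 101-point
interpolated AP, AP50-95 over thresholds 0.50–0.95 (step 0.05), and an
F1-versus-confidence sweep whose argmax picks the operating threshold
(ties resolve to the lowest threshold).

## Spatial density and the ECTI

Detected centroids are smoothed with an isotropic Gaussian KDE in pixel
coordinates. Edge bias is corrected by reflection: each point contributes
its full mirror series at the image borders, so the integrated density
equals the point count to machine precision (verified against a
sum-of-Gaussians oracle at 1e-9 relative). Densities are reported in
CNOs/µm², making ECTI and DTI directly comparable.

The bandwidth is selected by 5-fold cross-validated held-out log-likelihood
over a 2–80 px log-spaced grid (40 steps), balancing undersmoothing against
oversmoothing; selection is deterministic given a seed and invariant to
point order (points are canonically sorted before fold assignment). A
typical selected bandwidth on realistic patterns is a few tens of pixels.

The density map is stratified into 25 equal-width iso-density bands between
its min and max ("value" mode; "quantile" mode is available by config).
The **ECTI is the mean density over the central 5 bands (indices 11–15)**:
the low bands are dominated by ridges/fringes/occlusions with near-zero CNO
presence, the top bands by hotspots; the central bands represent the
effective corneocyte surface. On a constant map the ECTI is that constant.
Values equal to a band's upper edge join the higher band; the maximum joins
band 25.

Interpreting "central": middle *indices* of the value range was chosen over
quantile bands because it is what makes the statistic exclude
occlusion-dominated regions (which compress into the lowest value bands
regardless of their pixel count); the quantile alternative remains
switchable via `layer_mode`.

## Synthetic data

`generate_corneocyte_image` composes: a smooth correlated background
(Gaussian-filtered white noise, default std 40 nm, correlation 40 px),
elongated ridges (default 2, height 150 nm, width 600 nm), smooth occlusion
plateaus covering a target area fraction, Gaussian CNO bumps (amplitude
~N(273, (0.15·273)²) nm, FWHM ~N(305, (0.15·305)²) nm) at uniform random
non-occluded positions, and per-row stripe offsets ~N(0, 15²) nm. Noise
defaults are fixed, field-realistic choices: background roughness and
stripe amplitude are set well below the CNO amplitude (as in usable real
scans) but far from negligible.

`cno_density_per_um2` is the density *within effective (non-occluded)
regions*: occlusions hide CNOs, so the planted count is
λ · (1 − occluded fraction) · area. Consequently whole-image DTI
underestimates λ by about the occluded fraction while the ECTI recovers λ —
the mechanism the index exists for. Ground-truth boxes have side = planted
FWHM. CNO "height" is realized as amplitude above the local background
(the only testable reading of the stated dimensions).

Cohorts emulate the study design: groups G1–G3 (mild/moderate/severe, 15
patients each, lesional + nonlesional tapes) and G4 (healthy controls,
nonlesional only), 10 images per tape. The default density ladder
(lesional/nonlesional): G1 0.25/0.15, G2 0.6/0.35, G3 1.2/0.7, G4 –/0.05
CNOs/µm², echoing representative per-image counts of 22–483 on 400 µm².
Rate variability is hierarchical lognormal: patient multiplier σ = 0.3
(shared by both tapes of a patient, which is what gives the paired
lesional/nonlesional tests their power), tape σ = 0.15, image σ = 0.25.
With occlusions enabled, per-image occlusion severity is drawn uniformly in
[0, 2 × mean] — occlusion varies image to image, which is exactly what
inflates the DTI's coefficient of variation.

What the generator does **not** emulate: AFM tip convolution, spatially
correlated CNO clustering, drift/creep distortions, or the real dataset's
intensity statistics. Passing tests therefore demonstrate correctness of
the algorithms and the claimed robustness *mechanism*, not clinical
performance on real tapes.

`simulate_cohort_table` samples per-image observed densities from the same
hierarchical rate model (Poisson counts over the effective area) without
rendering pixels. It exists to calibrate the statistics stage (type-I
error, power) at simulation scales where rendering every image would be
wasteful; it shares the cohort plan, so the two routes agree in
distribution of rates.

## Cohort statistics

Per tape, the CV is the sample standard deviation (ddof = 1, the
small-sample convention) of its ≥ 2 image densities divided by their mean;
group mean CV averages tapes equally, and the KDE ablation reports
100 · (CV_without − CV_with) / CV_without per group. Tapes with fewer than
two estimates are excluded with a warning.

The test battery takes per-tape means over the 10 images first, then:
Shapiro–Wilk normality per (group, lesional status); two-sided Wilcoxon
signed-rank for paired lesional vs nonlesional tapes within G1–G3 (zero
differences dropped; unpaired samples excluded from pairing only); and
two-sided Wilcoxon rank-sum for nonlesional G1/G2/G3 against G4.
Significance bands: ns, * (p ≤ 0.05), ** (p ≤ 0.01). No multiple-testing
correction is applied by default (matching the per-comparison reporting
convention); results are deterministic and independent of table row order.

Both Wilcoxon tests compute exact two-sided p-values from the full null
distribution via dynamic programming (sign-flip polynomial for signed-rank,
n ≤ 25; subset count × sum table for rank-sum, n + m ≤ 30; average ranks
are doubled to remain integral, so ties are handled exactly), falling back
to the normal approximation with tie and continuity correction for larger
samples. scipy's implementations serve as an independent cross-check in the
test suite, not as the implementation.

## Numerical and problem-size choices

* KDE evaluation grid: step 1 px by default; cohort-scale simulations use
  step 4 px (well below any plausible bandwidth) and, where thousands of
  images are processed, a fixed 25 px bandwidth — per-image cross-validated
  bandwidths are the default for single-image analysis.
* Simulation sizes in the test and acceptance suites: 512 × 512 images
  (the study geometry) for parameter recovery, the occlusion mechanism and
  the detector floor; table-level simulation for test calibration. These
  sizes are the package's chosen trade-off between statistical resolution
  and runtime.
* Degenerate inputs are pinned: constant images normalize to zero, constant
  density maps stratify to a single layer with ECTI = the constant, empty
  detection sets yield zero densities, all-zero paired differences give
  p = 1.

## Known limitations

* At very high CNO density (λ ≈ 1.2/µm², ~480 objects per image) physically
  overlapping bumps merge; no single-peak detector can separate them, which
  caps recall at roughly 0.85–0.9 in those scenes. The detector-floor
  guarantee is stated at the generator's default density (λ = 0.6).
* The classical detector is a stand-in for fine-tuned deep detectors at the
  evaluation interface; published benchmark figures of such detectors
  require their weights and the clinical dataset and are out of scope.
* CV-based bandwidth selection on a strictly uniform pattern drifts to the
  top of the bandwidth grid (oversmoothing is optimal there); this is
  expected likelihood behaviour, not a defect.
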