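# ecti — corneocyte nanotexture analysis

Tools for quantifying **circular nano-size objects (CNOs)** — nanoscale
protrusions (~273 nm high, ~305 nm wide) on corneocyte surfaces linked to
skin-barrier impairment in atopic dermatitis — from atomic-force-microscopy
height maps of stratum corneum tape strips, and for turning detections into
a robust density biomarker.

The pipeline:

1. **Enhancement** — Gaussian smoothing, per-row destriping, [0, 1]
   normalization, and disk-percentile local-background subtraction turn a
   raw 512 × 512 px height map (20 × 20 µm²) into a detection-ready image.
2. **Detection** — a multi-scale Laplacian-of-Gaussian detector with size,
   prominence and circularity criteria; external deep-detector predictions
   (YOLO text) plug into the same interface. Evaluation: IoU, COCO-style
   AP50 / AP50-95, F1-vs-confidence.
3. **Spatial density** — an edge-corrected Gaussian KDE of CNO centroids
   (bandwidth by cross-validation), stratified into 25 iso-density layers.
   The **ECTI** (Effective Corneocyte Topographical Index) is the mean
   density over the central 5 layers:

   ECTI = mean{ f̂(x) : layer(x) ∈ {11, …, 15} },  f̂ = KDE of centroids (CNOs/µm²)

   which excludes the low-density layers produced by ridges and structural
   occlusions. The classical whole-image baseline (DTI convention) is
   count / imaged area.
4. **Cohort statistics** — per-tape coefficient of variation over 10
   images, per-group CV with/without KDE and the reduction percentage,
   Shapiro–Wilk, exact Wilcoxon signed-rank (paired lesional/nonlesional)
   and rank-sum (severity groups vs healthy controls) tests with ns/*/**
   significance bands.

A fully deterministic **synthetic generator** renders corneocyte-like
height maps (bumps, ridges, occlusion plateaus, stripe noise) with
ground-truth boxes, plus whole severity cohorts (G1–G3 patients with
lesional + nonlesional tapes, G4 controls), so every stage is testable
without any external dataset.

## Worked example

```python
from ecti import (SyntheticSpec, generate_corneocyte_image, enhance_pipeline,
                  detect_blobs, match_detections, PointSet, ecti_from_points)

spec = SyntheticSpec(cno_density_per_um2=0.6, occlusion_fraction=0.25, seed=42)
image = generate_corneocyte_image(spec)
print(f"planted CNOs: {len(image.ground_truth)}")

enhanced = enhance_pipeline(image.height_map)
detections = detect_blobs(enhanced, spec.pixel_size_nm)
ledger = match_detections(detections, image.ground_truth, iou_thresh=0.5)
print(f"detected: {len(detections)}  (precision {ledger.n_tp/len(detections):.2f}, "
      f"recall {ledger.n_tp/ledger.n_gt:.2f})")

points = PointSet.from_detections(detections, spec.pixel_size_nm)
result = ecti_from_points(points, seed=0)
print(f"bandwidth: {result.bandwidth_px:.1f} px")
print(f"ECTI: {result.ecti:.3f} CNOs/um^2   DTI: {result.dti_density:.3f} CNOs/um^2")
```

Output:

```
planted CNOs: 181
detected: 176  (precision 0.94, recall 0.91)
bandwidth: 41.3 px
ECTI: 0.614 CNOs/um^2   DTI: 0.440 CNOs/um^2
```

The image carries a true CNO density of 0.6/µm² on its effective surface,
with 25% of the field hidden by an occlusion plateau. The whole-image DTI
(0.440) underestimates by roughly that occluded fraction; the ECTI (0.614)
recovers the effective-region density because the occluded area falls into
the excluded low-density layers. This robustness is what stabilises
per-sample density estimates across the 10 images of a tape.

A CLI mirrors the library:

```
ecti synth --out-dir fixtures --cohort --seed 7
ecti enhance --input map.tif --output enhanced.tif
ecti detect --input enhanced.tif --output dets.txt
ecti eval --pred dets.txt --gt gt.txt --report eval.json
ecti density --detections dets.txt --bw auto --report ecti.json
ecti stats --table cohort.csv --report stats.json
ecti run --input-dir fixtures --report run.json
```

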