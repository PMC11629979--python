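"""Classical CNO detection and detector-agnostic evaluation.

The classical engine is a multi-scale Laplacian-of-Gaussian blob detector
with the geometric criteria of the DTI lineage (size window bracketing the
~305 nm CNO width, peak prominence, circularity of the thresholded support),
followed by greedy non-maximum suppression. Evaluation implements the
standard object-detection protocol: greedy score-ordered matching at an IoU
threshold, COCO-style 101-point average precision, AP50-95, and the
F1-versus-confidence sweep used to pick an operating threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .afm_io import BoundingBox, Detection, DetectionSet, read_detections_yolo
from .enhancement import EnhancedImage
from .exceptions import FormatError, ParameterError, UndefinedMetricError

__all__ = [
    "BlobParams",
    "PRCurve",
    "EvalResult",
    "MatchLedger",
    "iou",
    "detect_blobs",
    "nms",
    "match_detections",
    "average_precision",
    "ap50_95",
    "f1_confidence_curve",
    "load_external_detections",
]

AP5095_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass(frozen=True)
class BlobParams:
    """Geometric criteria of the classical CNO detector.

    The diameter window brackets the typical 305 nm CNO width; prominence is
    measured on the [0, 1] enhanced image against the local median background;
    circularity is 4*pi*A/P^2 of the half-prominence support component.
    """

    min_diameter_nm: float = 150.0
    max_diameter_nm: float = 600.0
    min_height_prominence: float = 0.05
    min_circularity: float = 0.5
    detect_threshold: float = 0.02
    num_sigma: int = 8
    nms_iou: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.min_diameter_nm < self.max_diameter_nm):
            raise ParameterError("need 0 < min_diameter_nm < max_diameter_nm")
        for name in ("min_height_prominence", "min_circularity"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.detect_threshold < 0:
            raise ParameterError("detect_threshold must be >= 0")
        if self.num_sigma < 2:
            raise ParameterError("num_sigma must be >= 2")
        if not (0.0 < self.nms_iou < 1.0):
            raise ParameterError("nms_iou must lie in (0, 1)")


@dataclass
class PRCurve:
    """Precision/recall/F1 as functions of a descending confidence cutoff."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    best_threshold: float
    best_f1: float


@dataclass
class MatchLedger:
    """TP/FP flags for score-sorted detections plus the FN count."""

    det_scores: np.ndarray   # sorted descending
    is_tp: np.ndarray        # bool per sorted detection
    matched_gt: np.ndarray   # gt index per detection, -1 for FP
    n_gt: int

    @property
    def n_tp(self) -> int:
        return int(self.is_tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.is_tp).sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp


@dataclass
class EvalResult:
    """AP summary over IoU thresholds 0.50-0.95."""

    ap50: float
    ap50_95: float
    n_gt: int
    n_det: int
    ap_per_iou: dict[float, float] = field(default_factory=dict)
    matches: dict[float, MatchLedger] = field(default_factory=dict)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _iou_matrix(dets: DetectionSet, gts: DetectionSet) -> np.ndarray:
    if len(dets) == 0 or len(gts) == 0:
        return np.zeros((len(dets), len(gts)))
    da = np.array([[d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max] for d in dets])
    ga = np.array([[g.box.x_min, g.box.y_min, g.box.x_max, g.box.y_max] for g in gts])
    ix = np.clip(np.minimum(da[:, None, 2], ga[None, :, 2])
                 - np.maximum(da[:, None, 0], ga[None, :, 0]), 0, None)
    iy = np.clip(np.minimum(da[:, None, 3], ga[None, :, 3])
                 - np.maximum(da[:, None, 1], ga[None, :, 1]), 0, None)
    inter = ix * iy
    area_d = (da[:, 2] - da[:, 0]) * (da[:, 3] - da[:, 1])
    area_g = (ga[:, 2] - ga[:, 0]) * (ga[:, 3] - ga[:, 1])
    union = area_d[:, None] + area_g[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def detect_blobs(img: EnhancedImage | np.ndarray, pixel_size_nm: float,
                 params: BlobParams | None = None) -> DetectionSet:
    """Detect CNOs on an enhanced [0, 1] image.

    Candidates are scale-space maxima of the scale-normalized negative
    Laplacian over sigmas spanning the diameter window (sigma = d / (2*sqrt2)),
    kept if response >= ``detect_threshold``, local peak prominence >=
    ``min_height_prominence`` and support circularity >= ``min_circularity``,
    then greedily NMS-suppressed. Scores are responses normalized by the
    image's maximum response.
    """
    params = params or BlobParams()
    values = img.values if isinstance(img, EnhancedImage) else np.asarray(img, dtype=float)
    if pixel_size_nm <= 0:
        raise ParameterError("pixel_size_nm must be > 0")
    h, w = values.shape

    sigma_min = params.min_diameter_nm / pixel_size_nm / (2.0 * np.sqrt(2.0))
    sigma_max = params.max_diameter_nm / pixel_size_nm / (2.0 * np.sqrt(2.0))
    sigmas = np.geomspace(sigma_min, sigma_max, params.num_sigma)

    stack = np.stack([
        -(s ** 2) * ndimage.gaussian_laplace(values, sigma=s, mode="reflect")
        for s in sigmas
    ])
    # local maxima in (scale, y, x)
    local_max = stack == ndimage.maximum_filter(stack, size=3, mode="reflect")
    cand = np.argwhere(local_max & (stack >= params.detect_threshold))
    if cand.size == 0:
        return DetectionSet(detections=[], image_w=w, image_h=h, source="classical")

    max_resp = stack.max()
    dets: list[Detection] = []
    for si, yi, xi in cand:
        s = sigmas[si]
        radius_px = np.sqrt(2.0) * s
        # local window for prominence + circularity (4 sigma context)
        r = int(np.ceil(4 * s))
        y0, y1 = max(0, yi - r), min(h, yi + r + 1)
        x0, x1 = max(0, xi - r), min(w, xi + r + 1)
        window = values[y0:y1, x0:x1]
        peak = values[yi, xi]
        background = np.median(window)
        prominence = peak - background
        if prominence < params.min_height_prominence:
            continue
        if params.min_circularity > 0:
            support = window >= background + 0.5 * prominence
            labels = measure.label(support, connectivity=2)
            lab = labels[yi - y0, xi - x0]
            if lab == 0:
                continue
            region = labels == lab
            area = float(region.sum())
            perim = measure.perimeter(region, neighborhood=4)
            if perim > 0:
                circularity = min(1.0, 4.0 * np.pi * area / perim ** 2)
            else:
                circularity = 1.0  # single-pixel support
            if circularity < params.min_circularity:
                continue
        score = float(stack[si, yi, xi] / max_resp) if max_resp > 0 else 0.0
        box = BoundingBox(
            x_min=max(0.0, xi - radius_px), y_min=max(0.0, yi - radius_px),
            x_max=min(float(w), xi + radius_px), y_max=min(float(h), yi + radius_px),
        )
        dets.append(Detection(box=box, score=min(1.0, score)))

    ds = DetectionSet(detections=dets, image_w=w, image_h=h, source="classical")
    return nms(ds, params.nms_iou)


def nms(ds: DetectionSet, iou_thresh: float) -> DetectionSet:
    """Greedy non-maximum suppression.

    Repeatedly keeps the highest-score detection and drops all others whose
    IoU with it is >= ``iou_thresh``. Ties broken by (score desc, y asc, x asc)
    of the box centroid, for determinism.
    """
    if not (0.0 < iou_thresh < 1.0):
        raise ParameterError("iou_thresh must lie in (0, 1)")
    if any(d.score is None for d in ds):
        raise ParameterError("nms requires scored detections")
    order = sorted(
        range(len(ds)),
        key=lambda i: (-ds.detections[i].score, ds.detections[i].centroid_y,
                       ds.detections[i].centroid_x),
    )
    kept: list[int] = []
    suppressed = np.zeros(len(ds), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(i)
        for j in order:
            if j != i and not suppressed[j] and iou(ds.detections[i].box, ds.detections[j].box) >= iou_thresh:
                suppressed[j] = True
    return DetectionSet(detections=[ds.detections[i] for i in kept],
                        image_w=ds.image_w, image_h=ds.image_h, source=ds.source)


def match_detections(dets: DetectionSet, gts: DetectionSet,
                     iou_thresh: float = 0.5) -> MatchLedger:
    """Greedy score-ordered matching of detections to ground truths.

    Detections are visited in descending score order (ties by input order);
    each claims its highest-IoU unmatched ground truth if that IoU reaches
    ``iou_thresh`` (TP), else it is a FP. Ground truths left unclaimed are FN.
    """
    if any(d.score is None for d in dets):
        raise ParameterError("match_detections requires scored detections")
    scores = np.array([d.score for d in dets], dtype=float)
    order = np.argsort(-scores, kind="stable")
    mat = _iou_matrix(dets, gts)
    gt_taken = np.zeros(len(gts), dtype=bool)
    is_tp = np.zeros(len(dets), dtype=bool)
    matched = np.full(len(dets), -1, dtype=int)
    for rank, i in enumerate(order):
        if len(gts):
            ious = np.where(gt_taken, -1.0, mat[i])
            j = int(np.argmax(ious))
            if ious[j] >= iou_thresh:
                is_tp[rank] = True
                matched[rank] = j
                gt_taken[j] = True
    return MatchLedger(det_scores=scores[order], is_tp=is_tp,
                       matched_gt=matched, n_gt=len(gts))


def _ap_101(ledger: MatchLedger) -> float:
    if ledger.n_gt == 0:
        raise UndefinedMetricError("average precision undefined without ground truth")
    if len(ledger.det_scores) == 0:
        return 0.0
    tp = np.cumsum(ledger.is_tp)
    fp = np.cumsum(~ledger.is_tp)
    recall = tp / ledger.n_gt
    precision = tp / (tp + fp)
    # precision envelope: max precision at recall >= r
    env = np.maximum.accumulate(precision[::-1])[::-1]
    sample_recalls = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, sample_recalls, side="left")
    sampled = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(sampled.mean())


def average_precision(dets: DetectionSet, gts: DetectionSet,
                      iou_thresh: float = 0.5) -> float:
    """COCO-style 101-point interpolated AP at one IoU threshold."""
    return _ap_101(match_detections(dets, gts, iou_thresh))


def ap50_95(dets: DetectionSet, gts: DetectionSet) -> EvalResult:
    """AP50 and mean AP over IoU thresholds 0.50-0.95 (step 0.05)."""
    ap_per: dict[float, float] = {}
    matches: dict[float, MatchLedger] = {}
    for t in AP5095_THRESHOLDS:
        ledger = match_detections(dets, gts, float(t))
        matches[float(t)] = ledger
        ap_per[float(t)] = _ap_101(ledger)
    ap50 = ap_per[0.5]
    return EvalResult(ap50=ap50, ap50_95=float(np.mean(list(ap_per.values()))),
                      n_gt=len(gts), n_det=len(dets), ap_per_iou=ap_per, matches=matches)


def f1_confidence_curve(dets: DetectionSet, gts: DetectionSet,
                        iou_thresh: float = 0.5) -> PRCurve:
    """Precision/recall/F1 swept over the detections' unique confidence values.

    ``best_threshold`` is the cutoff maximizing F1 (ties -> lowest cutoff),
    the rule used to pick a detector's operating point.
    """
    if len(dets) == 0:
        z = np.zeros(1)
        return PRCurve(thresholds=z, precision=z.copy(), recall=z.copy(),
                       f1=z.copy(), best_threshold=0.0, best_f1=0.0)
    ledger = match_detections(dets, gts, iou_thresh)
    thresholds = np.unique(ledger.det_scores)[::-1]
    precision = np.empty_like(thresholds)
    recall = np.empty_like(thresholds)
    f1 = np.empty_like(thresholds)
    for k, t in enumerate(thresholds):
        sel = ledger.det_scores >= t
        tp = int(ledger.is_tp[sel].sum())
        n_sel = int(sel.sum())
        p = tp / n_sel if n_sel else 0.0
        r = tp / ledger.n_gt if ledger.n_gt else 0.0
        precision[k] = p
        recall[k] = r
        f1[k] = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    # argmax F1; ties -> lowest threshold (thresholds are descending)
    best = len(f1) - 1 - int(np.argmax(f1[::-1]))
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall,
                   f1=f1, best_threshold=float(thresholds[best]), best_f1=float(f1[best]))


def load_external_detections(path, image_w: int, image_h: int) -> DetectionSet:
    """Adapter for external (e.g. deep-detector) YOLO prediction files.

    The returned set is interchangeable with :func:`detect_blobs` output in
    every downstream operation. Scores are mandatory.
    """
    try:
        return read_detections_yolo(path, image_w, image_h, has_scores=True,
                                    source="external")
    except FormatError as exc:
        raise FormatError(f"external predictions must carry scores: {exc}") from exc
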