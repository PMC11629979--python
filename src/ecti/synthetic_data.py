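"""Synthetic corneocyte nanotexture images with known ground truth.

The generator composes the structural elements seen in real AFM scans of
corneocytes: a smooth correlated background, circular nano-size objects
(CNOs) modelled as isotropic Gaussian bumps (~273 nm high, ~305 nm wide),
elongated ridges, large smooth occlusion patches (which hide CNOs), and
per-scan-row stripe offsets. Every planted CNO carries a ground-truth
bounding box, so each pipeline stage can be tested against known truth.

``cno_density_per_um2`` is the CNO surface density within *effective*
(non-occluded) regions: occlusions hide CNOs, so the whole-image count
underestimates the density by roughly the occluded fraction — the artefact
the ECTI is designed to be robust to.

A companion table-level simulator (:func:`simulate_cohort_table`) samples
per-image observed densities from the same hierarchical rate model without
rendering pixels, for fast statistical calibration of the cohort tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .afm_io import BoundingBox, Detection, DetectionSet, HeightMap, DEFAULT_PIXEL_SIZE_NM
from .exceptions import CapacityError, ParameterError

__all__ = [
    "SyntheticSpec",
    "SyntheticImage",
    "DEFAULT_GROUP_LAMBDAS",
    "generate_corneocyte_image",
    "cohort_table_skeleton",
    "generate_cohort",
    "simulate_cohort_table",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic corneocyte image.

    Physical scales are in nanometres; the defaults reproduce the study
    geometry (512 px over 20 um, CNOs 273 nm high and 305 nm wide with 15%
    relative size jitter). Noise/structure defaults are fixed, field-realistic
    choices documented in the methods note.
    """

    n_rows: int = 512
    n_cols: int = 512
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    cno_density_per_um2: float = 0.6
    cno_height_nm: float = 273.0
    cno_width_nm: float = 305.0
    size_jitter: float = 0.15
    n_ridges: int = 2
    ridge_height_nm: float = 150.0
    ridge_width_nm: float = 600.0
    occlusion_fraction: float = 0.0
    occlusion_height_nm: float = 350.0
    stripe_amp_nm: float = 15.0
    background_roughness_nm: float = 40.0
    background_corr_px: float = 40.0
    min_cno_spacing_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "cno_height_nm", "cno_width_nm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("cno_density_per_um2", "size_jitter", "stripe_amp_nm",
                     "background_roughness_nm", "ridge_height_nm", "ridge_width_nm",
                     "occlusion_height_nm", "min_cno_spacing_px"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0.0 <= self.occlusion_fraction <= 0.5):
            raise ParameterError("occlusion_fraction must lie in [0, 0.5]")
        if self.n_rows < 8 or self.n_cols < 8:
            raise ParameterError("image must be at least 8x8")
        if self.n_ridges < 0:
            raise ParameterError("n_ridges must be >= 0")
        if self.background_corr_px <= 0:
            raise ParameterError("background_corr_px must be > 0")

    @property
    def area_um2(self) -> float:
        px_um = self.pixel_size_nm / 1000.0
        return self.n_rows * self.n_cols * px_um * px_um


@dataclass
class SyntheticImage:
    """A generated height map plus the truth it was built from."""

    height_map: HeightMap
    ground_truth: DetectionSet
    masks: dict[str, np.ndarray]
    spec: SyntheticSpec


def _correlated_field(rng: np.random.Generator, shape: tuple[int, int],
                      corr_px: float, std: float) -> np.ndarray:
    if std == 0:
        return np.zeros(shape)
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=corr_px, mode="wrap")
    s = raw.std()
    if s == 0:
        return np.zeros(shape)
    return raw * (std / s)


def _add_ridges(rng: np.random.Generator, canvas: np.ndarray,
                spec: SyntheticSpec) -> np.ndarray:
    """Raised elongated bands with Gaussian cross-section; returns their mask."""
    h, w = canvas.shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(canvas.shape, dtype=bool)
    sigma_px = spec.ridge_width_nm / spec.pixel_size_nm * _FWHM_TO_SIGMA
    for _ in range(spec.n_ridges):
        x0 = rng.uniform(0, w)
        y0 = rng.uniform(0, h)
        theta = rng.uniform(0, np.pi)
        # signed distance from the line through (x0, y0) at angle theta
        dist = (xx - x0) * np.sin(theta) - (yy - y0) * np.cos(theta)
        profile = spec.ridge_height_nm * np.exp(-0.5 * (dist / sigma_px) ** 2)
        canvas += profile
        mask |= np.abs(dist) <= spec.ridge_width_nm / spec.pixel_size_nm
    return mask


def _add_occlusions(rng: np.random.Generator, canvas: np.ndarray,
                    spec: SyntheticSpec) -> np.ndarray:
    """Large smooth plateaus covering ~occlusion_fraction of the area."""
    h, w = canvas.shape
    mask = np.zeros(canvas.shape, dtype=bool)
    if spec.occlusion_fraction == 0:
        return mask
    yy, xx = np.mgrid[0:h, 0:w]
    target = spec.occlusion_fraction * h * w
    plateau = np.zeros(canvas.shape)
    for _ in range(64):
        deficit = target - mask.sum()
        if deficit <= 0.02 * target:
            break
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        ax = rng.uniform(0.12, 0.3) * w
        ay = rng.uniform(0.12, 0.3) * h
        # shrink the patch so it cannot overshoot the target area by much
        if np.pi * ax * ay > 1.3 * deficit:
            scale = np.sqrt(1.3 * deficit / (np.pi * ax * ay))
            ax *= scale
            ay *= scale
        theta = rng.uniform(0, np.pi)
        dx = xx - cx
        dy = yy - cy
        u = (dx * np.cos(theta) + dy * np.sin(theta)) / ax
        v = (-dx * np.sin(theta) + dy * np.cos(theta)) / ay
        inside = u * u + v * v <= 1.0
        mask |= inside
        plateau = np.maximum(plateau, inside.astype(float))
    smooth = ndimage.gaussian_filter(plateau, sigma=6.0, mode="reflect")
    canvas += spec.occlusion_height_nm * smooth
    return mask


def _place_cnos(rng: np.random.Generator, spec: SyntheticSpec,
                occlusion: np.ndarray) -> np.ndarray:
    """Uniform-random CNO centers on non-occluded pixels; (n, 2) as (x, y)."""
    h, w = spec.n_rows, spec.n_cols
    free_frac = 1.0 - occlusion.mean()
    n = int(round(spec.cno_density_per_um2 * spec.area_um2 * free_frac))
    if n == 0:
        return np.empty((0, 2))
    centers: list[tuple[float, float]] = []
    max_tries = 200 * n + 1000
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise CapacityError(
                f"could not place {n} CNOs (placed {len(centers)}) within retry budget"
            )
        x = rng.uniform(0, w)
        y = rng.uniform(0, h)
        if occlusion[min(int(y), h - 1), min(int(x), w - 1)]:
            continue
        if spec.min_cno_spacing_px > 0 and centers:
            d2 = min((x - cx) ** 2 + (y - cy) ** 2 for cx, cy in centers)
            if d2 < spec.min_cno_spacing_px ** 2:
                continue
        centers.append((x, y))
    return np.array(centers)


def generate_corneocyte_image(spec: SyntheticSpec) -> SyntheticImage:
    """Render one synthetic corneocyte height map; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.n_rows, spec.n_cols

    canvas = _correlated_field(rng, (h, w), spec.background_corr_px,
                               spec.background_roughness_nm)
    ridge_mask = _add_ridges(rng, canvas, spec) if spec.n_ridges else np.zeros_like(canvas, bool)
    occlusion_mask = _add_occlusions(rng, canvas, spec)
    centers = _place_cnos(rng, spec, occlusion_mask)

    n = len(centers)
    amplitudes = np.maximum(
        rng.normal(spec.cno_height_nm, spec.size_jitter * spec.cno_height_nm, size=n),
        0.1 * spec.cno_height_nm,
    )
    fwhms_nm = np.maximum(
        rng.normal(spec.cno_width_nm, spec.size_jitter * spec.cno_width_nm, size=n),
        0.3 * spec.cno_width_nm,
    )

    dets: list[Detection] = []
    for (x, y), amp, fwhm_nm in zip(centers, amplitudes, fwhms_nm):
        fwhm_px = fwhm_nm / spec.pixel_size_nm
        sigma_px = fwhm_px * _FWHM_TO_SIGMA
        r = int(np.ceil(4 * sigma_px))
        x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
        y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        canvas[y0:y1, x0:x1] += amp * np.exp(
            -((xs - x) ** 2 + (ys - y) ** 2) / (2 * sigma_px ** 2)
        )
        half = fwhm_px / 2
        box = BoundingBox(
            x_min=max(0.0, x - half), y_min=max(0.0, y - half),
            x_max=min(float(w), x + half), y_max=min(float(h), y + half),
        )
        dets.append(Detection(box=box))

    if spec.stripe_amp_nm > 0:
        canvas += rng.normal(0.0, spec.stripe_amp_nm, size=(h, 1))

    hm = HeightMap(heights=canvas, pixel_size_nm=spec.pixel_size_nm,
                   meta={"synthetic": True, "seed": int(spec.seed)})
    gt = DetectionSet(detections=dets, image_w=w, image_h=h, source="ground_truth")
    return SyntheticImage(height_map=hm, ground_truth=gt,
                          masks={"ridge": ridge_mask, "occlusion": occlusion_mask},
                          spec=spec)


#: Default severity ladder: group -> (lesional rate, nonlesional rate), CNOs/um^2.
#: G4 (healthy controls) has nonlesional samples only.
DEFAULT_GROUP_LAMBDAS: dict[str, tuple[float | None, float]] = {
    "G1": (0.25, 0.15),
    "G2": (0.6, 0.35),
    "G3": (1.2, 0.7),
    "G4": (None, 0.05),
}


@dataclass(frozen=True)
class CohortNoise:
    """Hierarchical variability of the rate model.

    Per patient a shared lognormal multiplier (sigma ``patient_sigma_log``)
    scales both of their tapes; each tape and each image add further
    lognormal multipliers. Per image, occlusion severity is drawn uniformly
    in [0, 2 x mean] (clipped to [0, 0.5]) when occlusions are enabled.
    """

    patient_sigma_log: float = 0.3
    tape_sigma_log: float = 0.15
    image_sigma_log: float = 0.25


def cohort_table_skeleton(
    group_lambdas: dict[str, tuple[float | None, float]] | None = None,
    n_samples_per_group: int = 15,
    images_per_sample: int = 10,
    base_spec: SyntheticSpec | None = None,
    seed: int = 0,
    noise: CohortNoise | None = None,
) -> pd.DataFrame:
    """Deterministic per-image plan of a synthetic cohort.

    One row per image slot with columns ``sample_id, group, lesional,
    image_index, lam_image, occlusion_fraction, image_seed``. G4 contributes
    nonlesional tapes only; image seeds are derived from ``seed``.
    """
    if images_per_sample < 2:
        raise ParameterError("images_per_sample must be >= 2 (CV needs >= 2)")
    group_lambdas = group_lambdas or DEFAULT_GROUP_LAMBDAS
    base_spec = base_spec or SyntheticSpec()
    noise = noise or CohortNoise()
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(group_lambdas):
        lam_les, lam_non = group_lambdas[group]
        for s in range(n_samples_per_group):
            sample_id = f"{group}_S{s + 1:02d}"
            patient_mult = rng.lognormal(0.0, noise.patient_sigma_log)
            for lesional, lam in ((True, lam_les), (False, lam_non)):
                if lam is None:
                    continue
                tape_mult = rng.lognormal(0.0, noise.tape_sigma_log)
                for i in range(images_per_sample):
                    lam_image = lam * patient_mult * tape_mult * rng.lognormal(
                        0.0, noise.image_sigma_log
                    )
                    if base_spec.occlusion_fraction > 0:
                        occ = float(np.clip(
                            rng.uniform(0.0, 2.0 * base_spec.occlusion_fraction), 0.0, 0.5))
                    else:
                        occ = 0.0
                    rows.append({
                        "sample_id": sample_id,
                        "group": group,
                        "lesional": lesional,
                        "image_index": i + 1,
                        "lam_image": lam_image,
                        "occlusion_fraction": occ,
                        "image_seed": int(rng.integers(0, 2**31 - 1)),
                    })
    return pd.DataFrame(rows)


def generate_cohort(
    group_lambdas: dict[str, tuple[float | None, float]] | None = None,
    n_samples_per_group: int = 15,
    images_per_sample: int = 10,
    base_spec: SyntheticSpec | None = None,
    seed: int = 0,
    noise: CohortNoise | None = None,
) -> Iterator[tuple[pd.Series, SyntheticImage]]:
    """Yield ``(plan_row, SyntheticImage)`` for every image slot of the cohort.

    Images are rendered lazily from the deterministic skeleton, so a cohort
    never has to fit in memory at once.
    """
    base_spec = base_spec or SyntheticSpec()
    plan = cohort_table_skeleton(group_lambdas, n_samples_per_group,
                                 images_per_sample, base_spec, seed, noise)
    for _, row in plan.iterrows():
        spec = replace(
            base_spec,
            cno_density_per_um2=float(row.lam_image),
            occlusion_fraction=float(row.occlusion_fraction),
            seed=int(row.image_seed),
        )
        yield row, generate_corneocyte_image(spec)


def simulate_cohort_table(
    group_lambdas: dict[str, tuple[float | None, float]] | None = None,
    n_samples_per_group: int = 15,
    images_per_sample: int = 10,
    base_spec: SyntheticSpec | None = None,
    seed: int = 0,
    noise: CohortNoise | None = None,
) -> pd.DataFrame:
    """Fast cohort table of observed densities, without rendering images.

    Per image, the observed CNO count is Poisson with mean
    ``lam_image x effective area``; the whole-image (DTI) density divides by
    the total area, while the effective (ECTI-like) density divides by the
    non-occluded area. Output is a long-format CohortTable with one row per
    (image, method).
    """
    base_spec = base_spec or SyntheticSpec()
    plan = cohort_table_skeleton(group_lambdas, n_samples_per_group,
                                 images_per_sample, base_spec, seed, noise)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9173]))
    area = base_spec.area_um2
    rows = []
    for _, r in plan.iterrows():
        eff_area = area * (1.0 - r.occlusion_fraction)
        count = rng.poisson(r.lam_image * eff_area)
        for method, dens in (("dti", count / area), ("ecti", count / eff_area)):
            rows.append({
                "sample_id": r.sample_id, "group": r.group, "lesional": r.lesional,
                "image_index": r.image_index, "density": dens, "method": method,
            })
    return pd.DataFrame(rows)
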