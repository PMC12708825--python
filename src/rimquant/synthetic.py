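"""Synthetic phantoms and cohorts with known ground truth.

The phantom emulates a bread-loaf NIR image: a low-intensity tumor core, a
peritumoral fluorescent rim decaying exponentially with distance from the
tumor, noisy parenchymal background, and optional stasis blobs of pooled dye.
The exponential profile is a modeling choice that gives closed-form band
averages, so the measured MSFI of a noise-free phantom can be checked against
the analytic mean of ``b + a·exp(−d/λ)`` over the same rim pixels.

The cohort generator draws per-lesion covariates matching the study cohort's
marginals (chemotherapy prevalence 10/32, capsular tumors 22/32, diameters
normal 29.9 ± 15.4 mm truncated at 5 mm, steatosis grades 9:19:4:0) and
builds fluorescence outcomes as a skewed log-normal baseline plus planted
linear covariate effects plus Gaussian residual — chemotherapy lowers MSFI by
0.36, SBR by 3.8 and maximum intensity by 0.72; each cm of tumor diameter
adds 0.25 to the maximum intensity.  The planted coefficients are returned as
ground truth so regression recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .bands import build_band_masks, distance_to_tumor
from .imaging_io import AnnotationSet, FluorescenceImage, rasterize

MM_PER_UM = 1.0 / 1000.0


def ellipse_polygon(
    center_xy_px: tuple[float, float],
    semi_axes_mm: tuple[float, float],
    pixel_size_um: float,
    n_vertices: int = 256,
) -> Polygon:
    """Polygonal approximation of an axis-aligned ellipse, in pixel coords."""
    scale = 1000.0 / pixel_size_um  # mm -> px
    cx, cy = center_xy_px
    ax, ay = semi_axes_mm[0] * scale, semi_axes_mm[1] * scale
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return Polygon(np.column_stack([cx + ax * np.cos(theta), cy + ay * np.sin(theta)]))


@dataclass
class PhantomSpec:
    """Parameters of one synthetic bread-loaf image.

    Geometry is given in millimetres (converted through ``pixel_size_um``);
    intensities in arbitrary units.  ``rim_decay_lambda_mm`` is the e-folding
    length of the rim profile ``b + a·exp(−d/λ)`` outside the tumor.
    """

    shape: tuple[int, int] = (400, 520)  # rows, cols
    pixel_size_um: float = 85.0
    tumor_center_px: tuple[float, float] | None = None  # (x, y); default image center
    tumor_semi_axes_mm: tuple[float, float] = (4.0, 3.0)
    tissue_semi_axes_mm: tuple[float, float] | None = (20.0, 15.0)
    tissue_rect_mm: tuple[float, float] | None = None  # width, height; overrides ellipse
    background_level: float = 0.104
    tumor_core_level: float = 0.05
    rim_amplitude: float = 1.0
    rim_decay_lambda_mm: float = 1.0
    noise_sd: float = 0.02
    stasis_blobs: list[tuple[tuple[float, float], tuple[float, float], float]] = dc_field(
        default_factory=list
    )  # ((center_x_px, center_y_px), (semi_a_mm, semi_b_mm), level)
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if self.background_level < 0 or self.rim_amplitude < 0:
            raise ValueError("background level and rim amplitude must be >= 0")
        if not self.rim_decay_lambda_mm > 0:
            raise ValueError("rim decay length must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel size must be positive")
        return self


def _phantom_geometry(spec: PhantomSpec) -> tuple[Polygon, Polygon]:
    rows, cols = spec.shape
    center = spec.tumor_center_px or (cols / 2.0, rows / 2.0)
    tumor = ellipse_polygon(center, spec.tumor_semi_axes_mm, spec.pixel_size_um)
    if spec.tissue_rect_mm is not None:
        scale = 1000.0 / spec.pixel_size_um
        w, h = spec.tissue_rect_mm[0] * scale, spec.tissue_rect_mm[1] * scale
        tissue = box(center[0] - w / 2, center[1] - h / 2, center[0] + w / 2, center[1] + h / 2)
    elif spec.tissue_semi_axes_mm is not None:
        tissue = ellipse_polygon(center, spec.tissue_semi_axes_mm, spec.pixel_size_um)
    else:
        raise ValueError("spec needs a tissue ellipse or rectangle")
    if not tissue.covers(tumor):
        raise ValueError("tumor region must lie inside the tissue region")
    return tumor, tissue


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[FluorescenceImage, AnnotationSet, dict]:
    """Render one phantom loaf: image, annotations and ground truth.

    The truth record carries the analytic noise-free band means computed over
    the same grid the measurement pipeline uses (expected MSFI/MBFI/SBR), the
    band pixel counts, and the spec parameters.
    """
    spec.validate()
    tumor_poly, tissue_poly = _phantom_geometry(spec)
    tumor_mask = rasterize([tumor_poly], spec.shape)
    tissue_mask = rasterize([tissue_poly], spec.shape)
    if not tumor_mask.any():
        raise ValueError("tumor rasterizes to an empty mask; enlarge it")
    dist_mm = distance_to_tumor(tumor_mask, spec.pixel_size_um)
    noisefree = spec.background_level + spec.rim_amplitude * np.exp(
        -dist_mm / spec.rim_decay_lambda_mm
    )
    noisefree[tumor_mask] = spec.tumor_core_level
    stasis_polys = []
    for blob_center, blob_axes, level in spec.stasis_blobs:
        blob = ellipse_polygon(blob_center, blob_axes, spec.pixel_size_um)
        blob_mask = rasterize([blob], spec.shape) & ~tumor_mask
        noisefree[blob_mask] += level
        stasis_polys.append(blob)
    rng = np.random.default_rng(spec.seed)
    pixels = noisefree + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    np.clip(pixels, 0.0, None, out=pixels)
    image = FluorescenceImage(
        pixels=pixels, pixel_size_um=spec.pixel_size_um, channel="NIR", loaf_id="L0"
    )
    annotations = AnnotationSet(
        tumor=[tumor_poly], tissue=[tissue_poly], stasis=stasis_polys
    )
    masks = build_band_masks(tumor_mask, tissue_mask, spec.pixel_size_um)
    expected_msfi = float(noisefree[masks.rim_mask].mean()) if masks.rim_mask.any() else math.nan
    expected_mbfi = (
        float(noisefree[masks.background_mask].mean()) if masks.background_mask.any() else math.nan
    )
    truth = {
        "expected_msfi": expected_msfi,
        "expected_mbfi": expected_mbfi,
        "expected_sbr": expected_msfi / expected_mbfi if expected_mbfi else math.nan,
        "n_rim_pixels": int(masks.rim_mask.sum()),
        "n_background_pixels": int(masks.background_mask.sum()),
        "background_area_mm2": masks.background_area_mm2,
        "noise_sd": spec.noise_sd,
        "background_level": spec.background_level,
        "rim_amplitude": spec.rim_amplitude,
        "rim_decay_lambda_mm": spec.rim_decay_lambda_mm,
        "seed": spec.seed,
        "profile_note": "defaults are placeholders; true in-patient rim width/decay unknown",
    }
    return image, annotations, truth


def generate_multi_loaf_specimen(
    spec: PhantomSpec,
    n_loaves: int = 3,
    center_index: int | None = None,
    small_background_index: int | None = None,
) -> list[tuple[FluorescenceImage, AnnotationSet, dict]]:
    """Phantom loaves through an ellipsoidal lesion.

    Tumor cross-sections shrink away from ``center_index`` like circles of an
    ellipsoid (factor √(1 − z²)), so the designated central loaf has the
    largest tumor area.  ``small_background_index`` shrinks one loaf's tissue
    so its own background falls below 100 mm², to exercise pooling.
    """
    if n_loaves < 1:
        raise ValueError("need at least one loaf")
    center_index = n_loaves // 2 if center_index is None else center_index
    out = []
    for i in range(n_loaves):
        # normalized out-of-plane offset in (-1, 1); 0 at the central loaf
        z = (i - center_index) / (n_loaves + 0.5)
        factor = math.sqrt(max(1.0 - z * z, 0.05))
        loaf_spec = PhantomSpec(
            shape=spec.shape,
            pixel_size_um=spec.pixel_size_um,
            tumor_center_px=spec.tumor_center_px,
            tumor_semi_axes_mm=(
                spec.tumor_semi_axes_mm[0] * factor,
                spec.tumor_semi_axes_mm[1] * factor,
            ),
            tissue_semi_axes_mm=spec.tissue_semi_axes_mm,
            tissue_rect_mm=spec.tissue_rect_mm,
            background_level=spec.background_level,
            tumor_core_level=spec.tumor_core_level,
            rim_amplitude=spec.rim_amplitude,
            rim_decay_lambda_mm=spec.rim_decay_lambda_mm,
            noise_sd=spec.noise_sd,
            stasis_blobs=spec.stasis_blobs,
            seed=spec.seed + i,
        )
        if i == small_background_index:
            # tissue barely larger than rim+gap -> background < 100 mm^2
            loaf_spec.tissue_semi_axes_mm = (
                loaf_spec.tumor_semi_axes_mm[0] + 5.6,
                loaf_spec.tumor_semi_axes_mm[1] + 5.6,
            )
            loaf_spec.tissue_rect_mm = None
        image, annotations, truth = generate_phantom(loaf_spec)
        image = FluorescenceImage(
            pixels=image.pixels,
            pixel_size_um=image.pixel_size_um,
            channel="NIR",
            loaf_id=f"L{i}",
            specimen_id="S0",
        )
        truth["loaf_index"] = i
        truth["is_central"] = i == center_index
        out.append((image, annotations, truth))
    return out


@dataclass
class CohortSpec:
    """Parameters of a synthetic lesion cohort.

    Prevalences and distributions default to the study cohort's marginals;
    planted effects are the regression-scale associations (a.u. per covariate
    unit) the statistics layer should recover.
    """

    n_patients: int = 32
    chemo_prevalence: float = 10 / 32
    capsular_prevalence: float = 22 / 32
    diameter_mean_mm: float = 29.9
    diameter_sd_mm: float = 15.4
    diameter_min_mm: float = 5.0
    steatosis_grade_probs: tuple[float, float, float, float] = (9 / 32, 19 / 32, 4 / 32, 0.0)
    male_prevalence: float = 19 / 32
    age_mean: float = 63.2
    age_sd: float = 8.9
    bmi_mean: float = 25.3
    bmi_sd: float = 3.0
    # untreated log-normal baselines (medians) and log-scale sigmas
    baseline_msfi_median: float = 0.65
    baseline_mbfi_median: float = 0.104
    baseline_sbr_median: float = 6.08
    baseline_max_median: float = 1.80
    sigma_log_msfi: float = 0.65
    sigma_log_mbfi: float = 0.55
    sigma_log_sbr: float = 0.55
    sigma_log_max: float = 0.25
    # planted effects (chemo on MSFI/SBR/max; size on max, per cm)
    effect_chemo_msfi: float = -0.36
    effect_chemo_sbr: float = -3.8
    effect_chemo_max: float = -0.72
    effect_size_max_per_cm: float = 0.25
    # additive Gaussian residual scales
    noise_msfi: float = 0.10
    noise_mbfi: float = 0.02
    noise_sbr: float = 1.0
    noise_max: float = 0.35
    # response mix among pretreated patients (7 PR : 3 SD in the cohort)
    partial_response_prob: float = 0.7
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.steatosis_grade_probs) - 1.0) > 1e-9:
            raise ValueError("steatosis grade probabilities must sum to 1")
        for p in (self.chemo_prevalence, self.capsular_prevalence, self.male_prevalence):
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")
        return self

    @property
    def planted_coefficients(self) -> dict[str, dict[str, float]]:
        zero = {"pretreatment": 0.0, "superficiality": 0.0, "size_cm": 0.0}
        return {
            "msfi_au": {**zero, "pretreatment": self.effect_chemo_msfi},
            "mbfi_au": dict(zero),
            "sbr": {**zero, "pretreatment": self.effect_chemo_sbr},
            "max_intensity_au": {
                **zero,
                "pretreatment": self.effect_chemo_max,
                "size_cm": self.effect_size_max_per_cm,
            },
        }


_GRADES = ("none", "mild", "moderate", "severe")


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic lesion cohort with planted covariate effects.

    Returns the per-lesion record table (covariates joined to fluorescence
    outcomes, ready for :func:`rimquant.cohort_stats.run_cohort_analyses`) and
    the ground-truth record of the planted coefficients.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    chemo = rng.random(n) < spec.chemo_prevalence
    capsular = rng.random(n) < spec.capsular_prevalence
    male = rng.random(n) < spec.male_prevalence
    diameters = rng.normal(spec.diameter_mean_mm, spec.diameter_sd_mm, size=n)
    while np.any(diameters < spec.diameter_min_mm):  # truncate by resampling
        bad = diameters < spec.diameter_min_mm
        diameters[bad] = rng.normal(spec.diameter_mean_mm, spec.diameter_sd_mm, size=bad.sum())
    grades = rng.choice(_GRADES, size=n, p=spec.steatosis_grade_probs)
    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, size=n)
    size_cm = diameters / 10.0

    def lognormal(median: float, sigma: float) -> np.ndarray:
        return np.exp(np.log(median) + sigma * rng.standard_normal(n))

    chemo_f = chemo.astype(float)
    msfi = (
        lognormal(spec.baseline_msfi_median, spec.sigma_log_msfi)
        + spec.effect_chemo_msfi * chemo_f
        + rng.normal(0.0, spec.noise_msfi, n)
    )
    mbfi = lognormal(spec.baseline_mbfi_median, spec.sigma_log_mbfi) + rng.normal(
        0.0, spec.noise_mbfi, n
    )
    sbr = (
        lognormal(spec.baseline_sbr_median, spec.sigma_log_sbr)
        + spec.effect_chemo_sbr * chemo_f
        + rng.normal(0.0, spec.noise_sbr, n)
    )
    max_int = (
        lognormal(spec.baseline_max_median, spec.sigma_log_max)
        + spec.effect_chemo_max * chemo_f
        + spec.effect_size_max_per_cm * size_cm
        + rng.normal(0.0, spec.noise_max, n)
    )
    # radiological response drives the pre-surgery diameter for treated patients
    partial = rng.random(n) < spec.partial_response_prob
    change = np.zeros(n)
    change[chemo & partial] = rng.uniform(-60.0, -30.0, size=int((chemo & partial).sum()))
    change[chemo & ~partial] = rng.uniform(-25.0, 15.0, size=int((chemo & ~partial).sum()))
    post = diameters * (1.0 + change / 100.0)
    recist = np.where(
        ~chemo, "not_treated", np.where(change <= -30.0, "partial_response", "stable_disease")
    )
    frame = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "pretreated": chemo,
            "superficiality": np.where(capsular, "capsular", "subcapsular"),
            "sex": np.where(male, "M", "F"),
            "age_years": age,
            "bmi": bmi,
            "steatosis_grade": grades,
            "diameter_baseline_mm": diameters,
            "diameter_presurgery_mm": post,
            "size_cm": size_cm,
            "recist": recist,
            "msfi_au": msfi,
            "mbfi_au": mbfi,
            "sbr": sbr,
            "max_intensity_au": max_int,
        }
    )
    truth = {
        "planted_coefficients": spec.planted_coefficients,
        "n_patients": n,
        "seed": spec.seed,
    }
    return frame, truth
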