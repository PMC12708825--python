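"""Distance-banded rim / background masks and the four fluorescence parameters.

The signal (rim) region is the non-tumor tissue within ``rim_mm`` (default
3 mm) of the tumor; the background is the tissue at least
``background_from_mm`` (default 5 mm) away; tissue strictly between the two
thresholds forms an explicit exclusion gap that enters neither estimate.
Distances are Euclidean between pixel centers, with the tumor treated as its
rasterized pixel set.

From these masks a loaf yields the mean signal fluorescence intensity (MSFI),
the mean background fluorescence intensity (MBFI), their ratio (SBR) and the
maximum intensity, plus the background area in mm² which drives the 100 mm²
sufficiency rule: lesions whose background is too small pool background pixels
from further loaves of the same specimen, and are excluded when even the
pooled area falls short.  Backgrounds contaminated by ICG stasis are
recomputed over an operator-chosen representative area or with the stasis
region subtracted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imaging_io import AnnotationSet, FluorescenceImage, rasterize

logger = logging.getLogger(__name__)

DEFAULT_RIM_MM = 3.0
DEFAULT_BACKGROUND_FROM_MM = 5.0
DEFAULT_MIN_BACKGROUND_MM2 = 100.0


class EmptyTumorMaskError(ValueError):
    """Raised when a distance field is requested for an empty tumor mask."""


@dataclass
class BandMasks:
    """Disjoint pixel sets partitioning the tissue of one loaf.

    ``tumor ∪ rim ∪ gap ∪ background`` equals the tissue mask exactly; the
    per-pixel distance-to-tumor field (mm) is kept for downstream overrides.
    """

    tumor_mask: np.ndarray
    rim_mask: np.ndarray
    gap_mask: np.ndarray
    background_mask: np.ndarray
    pixel_size_um: float
    distance_mm: np.ndarray
    rim_mm: float = DEFAULT_RIM_MM
    background_from_mm: float = DEFAULT_BACKGROUND_FROM_MM

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.tumor_mask | self.rim_mask | self.gap_mask | self.background_mask

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um / 1000.0) ** 2

    @property
    def background_area_mm2(self) -> float:
        return float(self.background_mask.sum()) * self.pixel_area_mm2


@dataclass
class LesionResult:
    """The four fluorescence parameters of one lesion plus provenance flags.

    ``sbr = msfi_au / mbfi_au`` whenever the background mean is defined and
    positive; undefined quantities are NaN.
    """

    msfi_au: float
    mbfi_au: float
    sbr: float
    max_intensity_au: float
    background_area_mm2: float
    background_pooled: bool = False
    stasis_override: bool = False
    excluded_insufficient_tissue: bool = False
    loaf_ids_used: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "msfi_au": self.msfi_au,
            "mbfi_au": self.mbfi_au,
            "sbr": self.sbr,
            "max_intensity_au": self.max_intensity_au,
            "background_area_mm2": self.background_area_mm2,
            "background_pooled": self.background_pooled,
            "stasis_override": self.stasis_override,
            "excluded_insufficient_tissue": self.excluded_insufficient_tissue,
            "loaf_ids_used": ";".join(self.loaf_ids_used),
        }


def distance_to_tumor(
    tumor_mask: np.ndarray,
    pixel_size_um: float,
) -> np.ndarray:
    """Per-pixel Euclidean distance (mm) from each pixel center to the nearest
    tumor-pixel center; tumor pixels hold 0."""
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise EmptyTumorMaskError("empty tumor mask")
    dist_px = ndimage.distance_transform_edt(~tumor_mask)
    return dist_px * (pixel_size_um / 1000.0)


def build_band_masks(
    tumor_mask: np.ndarray,
    tissue_mask: np.ndarray,
    pixel_size_um: float,
    rim_mm: float = DEFAULT_RIM_MM,
    background_from_mm: float = DEFAULT_BACKGROUND_FROM_MM,
) -> BandMasks:
    """Partition the tissue into tumor, rim (d ≤ rim_mm), exclusion gap and
    background (d ≥ background_from_mm).

    Both thresholds are inclusive; at ``rim_mm == background_from_mm`` the rim
    takes the boundary pixels and the gap is empty.  Tumor pixels outside the
    tissue are intersected away (logged).
    """
    if rim_mm > background_from_mm:
        raise ValueError(
            f"rim_mm ({rim_mm}) must not exceed background_from_mm ({background_from_mm})"
        )
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    stray = tumor_mask & ~tissue_mask
    if stray.any():
        logger.warning("%d tumor pixels outside tissue; intersecting away", int(stray.sum()))
        tumor_mask = tumor_mask & tissue_mask
    dist = distance_to_tumor(tumor_mask, pixel_size_um)
    nontumor = tissue_mask & ~tumor_mask
    rim = nontumor & (dist <= rim_mm)
    background = nontumor & ~rim & (dist >= background_from_mm)
    gap = nontumor & ~rim & ~background
    return BandMasks(
        tumor_mask=tumor_mask,
        rim_mask=rim,
        gap_mask=gap,
        background_mask=background,
        pixel_size_um=pixel_size_um,
        distance_mm=dist,
        rim_mm=rim_mm,
        background_from_mm=background_from_mm,
    )


def quantify_loaf(
    image: FluorescenceImage,
    masks: BandMasks,
    max_scope: str = "tissue",
) -> LesionResult:
    """Compute MSFI, MBFI, SBR, maximum intensity and background area.

    ``max_scope`` selects where the maximum is taken: ``"tissue"`` (default,
    all tissue pixels of the loaf), ``"image"`` (whole frame) or ``"rim"``.
    An empty background yields NaN MBFI/SBR and zero area; exclusion is
    decided downstream by :func:`pool_background`.
    """
    if not masks.rim_mask.any():
        raise ValueError("no rim pixels")
    px = image.pixels
    msfi = float(px[masks.rim_mask].mean())
    if masks.background_mask.any():
        mbfi = float(px[masks.background_mask].mean())
        sbr = msfi / mbfi if mbfi > 0 else math.nan
    else:
        mbfi = math.nan
        sbr = math.nan
    if max_scope == "tissue":
        max_int = float(px[masks.tissue_mask].max())
    elif max_scope == "image":
        max_int = float(px.max())
    elif max_scope == "rim":
        max_int = float(px[masks.rim_mask].max())
    else:
        raise ValueError(f"unknown max_scope {max_scope!r}")
    return LesionResult(
        msfi_au=msfi,
        mbfi_au=mbfi,
        sbr=sbr,
        max_intensity_au=max_int,
        background_area_mm2=masks.background_area_mm2,
        loaf_ids_used=[image.loaf_id] if image.loaf_id else [],
    )


def apply_stasis_override(
    image: FluorescenceImage,
    masks: BandMasks,
    annotations: AnnotationSet,
    result: LesionResult,
) -> LesionResult:
    """Recalculate an outlying background contaminated by ICG stasis.

    If the operator drew a representative ``background_override`` region, the
    MBFI is recomputed over that region intersected with tissue at background
    distance; otherwise, if stasis polygons exist, the stasis pixels are
    subtracted from the background.  Without either, the result is returned
    unchanged with the flag false.
    """
    at_background_distance = masks.distance_mm >= masks.background_from_mm
    if annotations.background_override:
        override = rasterize(annotations.background_override, image)
        region = override & masks.tissue_mask & at_background_distance
        if not region.any():
            raise ValueError("override region invalid: empty after intersection")
    elif annotations.stasis:
        stasis = rasterize(annotations.stasis, image)
        region = masks.background_mask & ~stasis
        if not region.any():
            raise ValueError("override region invalid: stasis covers entire background")
    else:
        return result
    mbfi = float(image.pixels[region].mean())
    sbr = result.msfi_au / mbfi if mbfi > 0 else math.nan
    return replace(result, mbfi_au=mbfi, sbr=sbr, stasis_override=True)


def pool_background(
    primary: LesionResult,
    primary_image: FluorescenceImage,
    primary_masks: BandMasks,
    others: Sequence[tuple[FluorescenceImage, "BandMasks | np.ndarray"]] = (),
    min_area_mm2: float = DEFAULT_MIN_BACKGROUND_MM2,
) -> LesionResult:
    """Apply the 100 mm² background-sufficiency rule.

    A primary background of at least ``min_area_mm2`` is kept as-is.  A
    smaller one is augmented by appending the background pixels (their own
    ≥ 5 mm regions, passed as :class:`BandMasks` or a bare boolean mask) of
    further loaves in the given order until the cumulative area reaches the
    threshold, and the MBFI becomes the pooled pixel mean.  If all loaves
    together still fall short the lesion is flagged excluded and MBFI/SBR are
    withheld.
    """
    if primary.background_area_mm2 >= min_area_mm2:
        return primary
    pixel_values = [primary_image.pixels[primary_masks.background_mask]]
    area = primary.background_area_mm2
    used = list(primary.loaf_ids_used)
    for image, masks in others:
        bg = getattr(masks, "background_mask", masks)
        pixel_values.append(image.pixels[bg])
        area += float(np.sum(bg)) * image.pixel_area_mm2
        if image.loaf_id:
            used.append(image.loaf_id)
        if area >= min_area_mm2:
            break
    if area < min_area_mm2:
        return replace(
            primary,
            mbfi_au=math.nan,
            sbr=math.nan,
            background_area_mm2=area,
            excluded_insufficient_tissue=True,
            loaf_ids_used=used,
        )
    pooled = np.concatenate(pixel_values)
    mbfi = float(pooled.mean())
    sbr = primary.msfi_au / mbfi if mbfi > 0 else math.nan
    return replace(
        primary,
        mbfi_au=mbfi,
        sbr=sbr,
        background_area_mm2=area,
        background_pooled=True,
        loaf_ids_used=used,
    )


def select_central_loaf(
    loaves: Sequence[tuple[FluorescenceImage, AnnotationSet]],
) -> int:
    """Pick the loaf at the center of the tumor as the analysis slice.

    The central cross-section of an ellipsoidal lesion is the one with the
    largest tumor area, so the loaf maximizing rasterized tumor area is
    selected; ties break to the lowest index.
    """
    best_index = -1
    best_area = -1
    for i, (image, annotations) in enumerate(loaves):
        if not annotations.tumor:
            continue
        area = int(rasterize(annotations.tumor, image).sum())
        if area > best_area:
            best_index, best_area = i, area
    if best_index < 0:
        raise ValueError("no loaf carries a tumor annotation")
    return best_index
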