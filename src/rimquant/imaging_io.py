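"""Readers, writers and rasterization for slice images, annotations and tables.

Images are single-plane grayscale TIFFs in arbitrary device units (a.u.);
intensities are never rescaled on read.  Annotations are GeoJSON
FeatureCollections in image pixel coordinates (origin top-left, x rightward,
y downward); the classification label is read from ``classification.name`` or
``properties.label`` and mapped through a case-insensitive synonym table.
Cohort covariates and per-lesion results travel as CSV with a header row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon, shape as geojson_shape

logger = logging.getLogger(__name__)

#: default physical pixel edge length of the imaging system, micrometres
DEFAULT_PIXEL_SIZE_UM = 85.0

#: case-insensitive mapping from annotation-tool class names to canonical roles
DEFAULT_LABEL_SYNONYMS: dict[str, str] = {
    "tumor": "tumor",
    "tumour": "tumor",
    "lesion": "tumor",
    "metastasis": "tumor",
    "tissue": "tissue",
    "liver": "tissue",
    "parenchyma": "tissue",
    "bread loaf": "tissue",
    "breadloaf": "tissue",
    "stasis": "stasis",
    "icg stasis": "stasis",
    "background_override": "background_override",
    "background override": "background_override",
    "background": "background_override",
    "representative background": "background_override",
}

#: columns a cohort CSV must provide
COHORT_REQUIRED_COLUMNS = (
    "patient_id",
    "surgery_date",
    "chemo_last_cycle_start",
    "targeted_therapy",
    "superficiality",
    "steatosis_fraction",
    "diameter_baseline_mm",
    "diameter_presurgery_mm",
    "sex",
    "age_years",
    "bmi",
    "primary_location",
)

_COHORT_DATE_COLUMNS = ("surgery_date", "chemo_last_cycle_start")


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass(frozen=True)
class FluorescenceImage:
    """One channel of one bread-loaf image.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities in arbitrary units.
    pixel_size_um
        Physical edge length of a pixel in micrometres.
    channel
        ``"NIR"`` (fluorescence) or ``"WHITE"`` (white light).
    loaf_id, specimen_id
        Identifiers of the slice and the resected specimen.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel: str = "NIR"
    loaf_id: str = ""
    specimen_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"image must be a 2-D grid, got shape {px.shape}")
        if np.any(px < 0):
            raise ValueError("image intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if self.channel not in ("NIR", "WHITE"):
            raise ValueError(f"channel must be 'NIR' or 'WHITE', got {self.channel!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um / 1000.0) ** 2


@dataclass
class AnnotationSet:
    """Labeled polygons for one loaf, in image pixel coordinates."""

    tumor: list[Polygon] = field(default_factory=list)
    tissue: list[Polygon] = field(default_factory=list)
    stasis: list[Polygon] = field(default_factory=list)
    background_override: list[Polygon] = field(default_factory=list)

    def validate(self) -> "AnnotationSet":
        if not self.tumor:
            raise FormatError("missing tumor annotation")
        if not self.tissue:
            raise FormatError("missing tissue annotation")
        for role in ("tumor", "tissue", "stasis", "background_override"):
            for poly in getattr(self, role):
                if not poly.is_valid:
                    raise FormatError(f"invalid (self-intersecting?) {role} polygon")
        return self


@dataclass
class CohortTable:
    """Per-lesion clinical covariates (one row per lesion/patient)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"cohort table missing required column(s): {', '.join(missing)}")
        f = self.frame
        diam = f[["diameter_baseline_mm", "diameter_presurgery_mm"]].to_numpy(dtype=float)
        if np.any(diam[np.isfinite(diam)] < 0):
            raise ValueError("diameters must be non-negative")
        steat = f["steatosis_fraction"].to_numpy(dtype=float)
        if np.any((steat < 0) | (steat > 100)):
            raise ValueError("steatosis_fraction must lie in [0, 100]")
        both = f["chemo_last_cycle_start"].notna() & f["surgery_date"].notna()
        if np.any(
            pd.to_datetime(f.loc[both, "surgery_date"])
            < pd.to_datetime(f.loc[both, "chemo_last_cycle_start"])
        ):
            raise ValueError("surgery_date earlier than chemo_last_cycle_start")

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b)


def read_fluorescence_image(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    channel: str = "NIR",
    loaf_id: str = "",
    specimen_id: str = "",
) -> FluorescenceImage:
    """Read a single-plane grayscale TIFF without rescaling intensities.

    Integer rasters are converted to floats bit-exactly; multi-plane or color
    rasters are rejected with an error naming the offending axis.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        # report which axis makes the raster non-planar
        axis = 0 if arr.ndim > 2 else arr.ndim
        raise FormatError(
            f"{path}: expected a single-plane grayscale raster, got shape "
            f"{arr.shape} (extra axis {axis} of length {arr.shape[axis]})"
        )
    return FluorescenceImage(
        pixels=np.asarray(arr, dtype=np.float64),
        pixel_size_um=pixel_size_um,
        channel=channel,
        loaf_id=loaf_id,
        specimen_id=specimen_id,
    )


def write_fluorescence_image(image: FluorescenceImage, path: str | Path) -> None:
    """Write the intensity grid as a 32-bit float TIFF."""
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def _feature_label(feature: Mapping) -> str | None:
    props = feature.get("properties") or {}
    cls = props.get("classification")
    if isinstance(cls, Mapping) and cls.get("name"):
        return str(cls["name"])
    if props.get("label"):
        return str(props["label"])
    cls_top = feature.get("classification")
    if isinstance(cls_top, Mapping) and cls_top.get("name"):
        return str(cls_top["name"])
    return None


def read_annotations(
    path: str | Path,
    image: FluorescenceImage | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection of labeled polygons.

    Out-of-frame vertices are retained; clipping to the image frame happens at
    rasterization.  Features with unknown labels are ignored with a warning.
    """
    table = {k.lower(): v for k, v in (synonyms or DEFAULT_LABEL_SYNONYMS).items()}
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    out = AnnotationSet()
    for feature in doc.get("features", []):
        label = _feature_label(feature)
        role = table.get(label.lower()) if label else None
        if role is None:
            logger.warning("%s: ignoring feature with unknown label %r", path, label)
            continue
        geom = geojson_shape(feature["geometry"])
        polys: list[Polygon]
        if isinstance(geom, Polygon):
            polys = [geom]
        elif geom.geom_type == "MultiPolygon":
            polys = list(geom.geoms)
        else:
            logger.warning("%s: ignoring non-polygon geometry %s", path, geom.geom_type)
            continue
        getattr(out, role).extend(polys)
    return out.validate()


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` as a GeoJSON FeatureCollection."""
    features = []
    for role in ("tumor", "tissue", "stasis", "background_override"):
        for poly in getattr(annotations, role):
            features.append(
                {
                    "type": "Feature",
                    "geometry": json.loads(shapely.to_geojson(poly)),
                    "properties": {"classification": {"name": role}},
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def rasterize(
    polygons: Sequence[Polygon],
    image: FluorescenceImage | tuple[int, int],
) -> np.ndarray:
    """Rasterize polygons to a boolean mask by pixel-center sampling.

    A pixel (row, col) belongs to the mask iff its center ``(col+0.5,
    row+0.5)`` lies strictly inside the union of the polygons; pixels outside
    the image frame are dropped.  An empty polygon list yields an empty mask.
    """
    shape = image.shape if isinstance(image, FluorescenceImage) else tuple(image)
    mask = np.zeros(shape, dtype=bool)
    if not polygons:
        return mask
    union = shapely.union_all(list(polygons))
    minx, miny, maxx, maxy = union.bounds
    # only centers within the polygon bounding box can be inside
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx + 0.5)), shape[1])
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy + 0.5)), shape[0])
    if c1 <= c0 or r1 <= r0:
        return mask
    cols = np.arange(c0, c1) + 0.5
    rows = np.arange(r0, r1) + 0.5
    xx, yy = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(union, xx.ravel(), yy.ravel()).reshape(xx.shape)
    mask[r0:r1, c0:c1] = inside
    return mask


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort covariate CSV (one row per lesion) with validation."""
    frame = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in _COHORT_DATE_COLUMNS:
        frame[col] = pd.to_datetime(frame[col], format="ISO8601")
    frame["targeted_therapy"] = frame["targeted_therapy"].astype(bool)
    return CohortTable(frame)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort table back to CSV (ISO-8601 dates); inverse of read_cohort."""
    frame = table.frame.copy()
    for col in _COHORT_DATE_COLUMNS:
        frame[col] = pd.to_datetime(frame[col]).dt.strftime("%Y-%m-%d")
    frame.to_csv(path, index=False)


def write_results(records: Iterable[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write per-lesion results (one row per lesion, all fields and flags).

    ``records`` is a DataFrame or an iterable of flat mappings.  A ``.json``
    suffix selects JSON output, anything else CSV.
    """
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame.to_json(path, orient="records", indent=2)
    else:
        frame.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results table written by :func:`write_results`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.read_json(path, orient="records")
    return pd.read_csv(path)
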