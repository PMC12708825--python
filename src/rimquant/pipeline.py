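"""End-to-end orchestration: quantify loaves, derive covariates, run cohort stats.

The pipeline walks paired image/annotation files (``<specimen>__<loaf>.tif``
with a same-stem ``.geojson``), selects the central loaf per specimen,
builds the band masks, applies the stasis and background-pooling rules,
joins the clinical covariates, and runs the statistical battery.  Exclusions
are reported with enumerated reasons, never silent; identical inputs and
config produce byte-identical outputs, and every artifact records the config
hash.
"""

from __future__ import annotations

import dataclasses
import glob as globlib
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import (
    DEFAULT_BACKGROUND_FROM_MM,
    DEFAULT_MIN_BACKGROUND_MM2,
    DEFAULT_RIM_MM,
    apply_stasis_override,
    build_band_masks,
    pool_background,
    quantify_loaf,
    select_central_loaf,
)
from .clinical import classify_recist, grade_steatosis, is_pretreated
from .cohort_stats import run_cohort_analyses
from .imaging_io import (
    DEFAULT_PIXEL_SIZE_UM,
    AnnotationSet,
    FluorescenceImage,
    rasterize,
    read_annotations,
    read_cohort,
    read_fluorescence_image,
    write_results,
)

logger = logging.getLogger(__name__)

EXCLUSION_INSUFFICIENT_TISSUE = "insufficient_tissue"
EXCLUSION_NO_ANNOTATION = "missing_annotation"
EXCLUSION_NON_COLORECTAL = "non_colorectal_primary"


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    images: str = ""
    annotations: str = ""
    cohort_csv: str = ""
    out_dir: str = "results"
    rim_mm: float = DEFAULT_RIM_MM
    background_from_mm: float = DEFAULT_BACKGROUND_FROM_MM
    min_background_mm2: float = DEFAULT_MIN_BACKGROUND_MM2
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    max_scope: str = "tissue"
    test_per_parameter: dict = field(default_factory=dict)
    exclude_non_colorectal: bool = True
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for name in ("rim_mm", "background_from_mm", "min_background_mm2", "pixel_size_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.rim_mm > self.background_from_mm:
            raise ValueError("rim_mm must not exceed background_from_mm")
        if self.max_scope not in ("tissue", "image", "rim"):
            raise ValueError(f"unknown max_scope {self.max_scope!r}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc).validate()

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _pair_files(images_glob: str, annotations_glob: str) -> dict[str, list[tuple[Path, Path]]]:
    """Group image/annotation pairs by specimen (stem before '__')."""
    ann_by_stem = {Path(p).stem: Path(p) for p in globlib.glob(annotations_glob)}
    specimens: dict[str, list[tuple[Path, Path]]] = {}
    for img_path in sorted(globlib.glob(images_glob)):
        img = Path(img_path)
        ann = ann_by_stem.get(img.stem)
        specimen = img.stem.split("__")[0]
        specimens.setdefault(specimen, []).append((img, ann))
    return specimens


def _loaf_background_mask(image: FluorescenceImage, annotations: AnnotationSet, config):
    """A loaf's own ≥ background_from_mm region, for pooling.

    Loaves without a tumor annotation contribute their whole tissue (no
    peritumoral signal to keep at distance).
    """
    tissue = rasterize(annotations.tissue, image)
    if not annotations.tumor:
        return tissue
    tumor = rasterize(annotations.tumor, image)
    if not tumor.any():
        return tissue
    masks = build_band_masks(
        tumor, tissue, config.pixel_size_um, config.rim_mm, config.background_from_mm
    )
    return masks.background_mask


def quantify_specimen(
    loaves: list[tuple[FluorescenceImage, AnnotationSet]],
    config: PipelineConfig,
) -> tuple[dict, dict]:
    """Quantify one specimen from its loaves; returns (result row, audit record)."""
    central = select_central_loaf(loaves)
    image, annotations = loaves[central]
    tumor = rasterize(annotations.tumor, image)
    tissue = rasterize(annotations.tissue, image)
    masks = build_band_masks(
        tumor, tissue, config.pixel_size_um, config.rim_mm, config.background_from_mm
    )
    result = quantify_loaf(image, masks, max_scope=config.max_scope)
    result = apply_stasis_override(image, masks, annotations, result)
    others = [
        (img, _loaf_background_mask(img, ann, config))
        for i, (img, ann) in enumerate(loaves)
        if i != central
    ]
    result = pool_background(result, image, masks, others, config.min_background_mm2)
    audit = {
        "central_loaf_index": central,
        "n_loaves": len(loaves),
        "tumor_pixels": int(masks.tumor_mask.sum()),
        "rim_pixels": int(masks.rim_mask.sum()),
        "gap_pixels": int(masks.gap_mask.sum()),
        "background_pixels": int(masks.background_mask.sum()),
        "background_area_mm2": result.background_area_mm2,
        "flags": {
            "background_pooled": result.background_pooled,
            "stasis_override": result.stasis_override,
            "excluded_insufficient_tissue": result.excluded_insufficient_tissue,
        },
        "pooling_order": result.loaf_ids_used,
    }
    return result.to_dict(), audit


def _covariate_row(row: pd.Series) -> dict:
    chemo = row.get("chemo_last_cycle_start")
    chemo = None if pd.isna(chemo) else pd.Timestamp(chemo)
    surgery = pd.Timestamp(row["surgery_date"])
    pretreated = is_pretreated(chemo, surgery)
    baseline = float(row["diameter_baseline_mm"])
    post = row.get("diameter_presurgery_mm")
    if pretreated and baseline > 0 and not pd.isna(post):
        recist = classify_recist(baseline, float(post)).response.value
    else:
        recist = "not_treated"
    return {
        "pretreated": pretreated,
        "recist": recist,
        "superficiality": row["superficiality"],
        "steatosis_grade": grade_steatosis(float(row["steatosis_fraction"])).value,
        "size_cm": baseline / 10.0,
        "sex": row.get("sex"),
        "age_years": row.get("age_years"),
        "bmi": row.get("bmi"),
        "primary_location": row.get("primary_location"),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run quantify → classify → cohort statistics; write all artifacts.

    Emits ``results.csv`` (one row per lesion: fluorescence parameters,
    covariates, flags), ``report.json`` (the statistical battery) and
    ``audit.jsonl`` (per-lesion mask sizes, flags, pooling order).  Lesions
    failing hard preconditions are recorded as excluded and the pipeline
    continues.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.cohort_csv).frame.set_index("patient_id", drop=False)
    specimens = _pair_files(config.images, config.annotations)
    rows: list[dict] = []
    audits: list[dict] = []
    for specimen_id in sorted(specimens):
        audit: dict = {"specimen_id": specimen_id, "config_hash": config.hash()}
        row: dict = {"patient_id": specimen_id}
        try:
            loaves = []
            for img_path, ann_path in specimens[specimen_id]:
                if ann_path is None:
                    raise FileNotFoundError(f"no annotation for {img_path.name}")
                image = read_fluorescence_image(
                    img_path,
                    pixel_size_um=config.pixel_size_um,
                    loaf_id=img_path.stem.split("__")[-1],
                    specimen_id=specimen_id,
                )
                loaves.append((image, read_annotations(ann_path)))
            result, loaf_audit = quantify_specimen(loaves, config)
            row.update(result)
            audit.update(loaf_audit)
            if result["excluded_insufficient_tissue"]:
                row["excluded"] = EXCLUSION_INSUFFICIENT_TISSUE
        except (FileNotFoundError, ValueError) as exc:
            logger.warning("specimen %s excluded: %s", specimen_id, exc)
            row["excluded"] = EXCLUSION_NO_ANNOTATION
            audit["error"] = str(exc)
        if specimen_id in cohort.index:
            row.update(_covariate_row(cohort.loc[specimen_id]))
            primary = str(cohort.loc[specimen_id].get("primary_location", "")).lower()
            if config.exclude_non_colorectal and primary in ("non_colorectal", "other"):
                row["excluded"] = EXCLUSION_NON_COLORECTAL
        row.setdefault("excluded", "")
        rows.append(row)
        audits.append(audit)
    results = pd.DataFrame(rows)
    write_results(results, out_dir / "results.csv")
    with open(out_dir / "audit.jsonl", "w") as fh:
        for record in audits:
            fh.write(json.dumps(record, sort_keys=True) + "\n")
    analyzable = results[results["excluded"] == ""] if "excluded" in results else results
    report: dict = {
        "version": __version__,
        "config_hash": config.hash(),
        "n_specimens": int(len(results)),
        "n_analyzed": int(len(analyzable)),
        "exclusions": results.loc[results["excluded"] != "", ["patient_id", "excluded"]]
        .to_dict(orient="records"),
    }
    if len(analyzable) >= 4 and "msfi_au" in analyzable:
        report["analyses"] = run_cohort_analyses(analyzable, config.test_per_parameter)
    else:
        report["analyses"] = None
        logger.info("too few analyzable lesions for cohort statistics")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
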