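"""Landmark- and annotation-based measurements on oriented sections.

Three measurements quantify hard- and soft-tissue regeneration around the
tooth:

* **CEJ-to-crest distance** — Euclidean distance between the
  cemento-enamel junction and the top of the alveolar crest; shorter means
  more regenerated bone height.
* **Cementum area** — cementum-positive pixels inside a fixed measuring
  frame of 1,000 px^2 drawn downward from the CEJ; the frame area is a
  constant so areas are comparable across sections.
* **Vessel counts** — annotated vessels per compartment, with PDL vessels
  split into small (< 50 um) and large (>= 50 um diameter) classes.

Aggregation follows the study protocol: each measurement is taken twice,
blinded, per section; the two replicates are averaged; at least five
sections per periodontal defect are measured and their mean is the
per-defect value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .fiber_entropy import EntropyResult
from .preprocess import AnnotationSet, ValidationError, polygon_mask

logger = logging.getLogger(__name__)

PDL_SIZE_CLASSES = ("small", "large")
VESSEL_KEYS = (
    ("PDL", "small"),
    ("PDL", "large"),
    ("alveolar_bone", "all"),
    ("gingiva", "all"),
)

LINKAGE_COLUMNS = ["animal_id", "side", "timepoint_weeks", "section_index", "replicate_index"]


class Distance(NamedTuple):
    px: float
    um: float | None


@dataclass(eq=False)
class HistomorphRecord:
    """Per-section, per-replicate measurement bundle."""

    animal_id: str
    side: str
    timepoint_weeks: int | str
    section_index: int
    replicate_index: int
    cej_crest_distance_px: float | None = None
    cementum_area_px2: float | None = None
    vessel_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def to_tidy(self) -> list[dict]:
        base = {
            "animal_id": self.animal_id,
            "side": self.side,
            "timepoint_weeks": self.timepoint_weeks,
            "section_index": self.section_index,
            "replicate_index": self.replicate_index,
        }
        rows = []
        if self.cej_crest_distance_px is not None:
            rows.append(base | {"measurement": "cej_crest_distance", "value": self.cej_crest_distance_px})
        if self.cementum_area_px2 is not None:
            rows.append(base | {"measurement": "cementum_area", "value": self.cementum_area_px2})
        for (comp, size), n in self.vessel_counts.items():
            name = f"vessel_count_{comp.lower()}" + (f"_{size}" if size != "all" else "")
            rows.append(base | {"measurement": name, "value": float(n)})
        return rows


@dataclass(eq=False)
class DefectMeasurement:
    """Per-defect (animal x side x timepoint) mean of one measurement."""

    animal_id: str
    side: str
    timepoint_weeks: int | str
    measurement: str
    value: float
    n_sections: int
    section_values: np.ndarray
    replicate_agreement: dict[int, float]
    incomplete_replicates: bool = False


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def cej_crest_distance(ann: AnnotationSet, scale_um_per_px: float | None = None) -> Distance:
    """Euclidean CEJ-to-alveolar-crest distance in oriented-image pixels.

    Also reported in micrometers when a pixel scale is supplied.
    """
    if ann.cej_point is None or ann.crest_point is None:
        raise ValidationError("both cej_point and crest_point are required")
    d = float(math.hypot(*(ann.crest_point - ann.cej_point)))
    um = d * scale_um_per_px if scale_um_per_px is not None else None
    return Distance(px=d, um=um)


def cementum_area(
    ann: AnnotationSet,
    cementum_mask: np.ndarray,
    frame_area_px2: int = 1000,
    frame_tolerance: float = 0.02,
) -> float:
    """Cementum-positive pixels inside the fixed measuring frame.

    The annotator draws the frame polygon (compartment ``cementum_frame``)
    downward from the CEJ; its rasterized area must equal
    ``frame_area_px2`` within ``frame_tolerance`` (default 2%) or the
    measurement is refused, so areas stay comparable across sections.
    """
    frames = [r for r in ann.rois if r.compartment == "cementum_frame"]
    if not frames:
        raise ValidationError("annotation set has no cementum_frame ROI")
    if len(frames) > 1:
        raise ValidationError("annotation set has more than one cementum_frame ROI")
    mask = np.asarray(cementum_mask)
    if mask.ndim != 2:
        raise ValidationError("cementum mask must be a 2-D binary raster")
    mask = mask.astype(bool)
    frame_mask = polygon_mask(frames[0].vertices, mask.shape)
    frame_px = int(np.count_nonzero(frame_mask))
    if abs(frame_px - frame_area_px2) > frame_tolerance * frame_area_px2:
        raise ValidationError(
            f"cementum frame rasterizes to {frame_px} px^2, outside "
            f"{frame_area_px2} +/- {frame_tolerance:.0%}"
        )
    return float(np.count_nonzero(mask & frame_mask))


def count_vessels(
    ann: AnnotationSet, size_threshold_um: float = 50.0
) -> dict[tuple[str, str], int]:
    """Vessel counts per (compartment, size class).

    PDL vessels are split at ``size_threshold_um``: a diameter strictly
    below the threshold is "small", at or above it "large" (the tie at
    exactly 50 um is assigned to the large class by convention). Alveolar
    bone and gingiva vessels are counted without a size split (class
    "all"). Compartments with no marks report zero.
    """
    if size_threshold_um <= 0:
        raise ValidationError("size_threshold_um must be positive")
    counts: dict[tuple[str, str], int] = {k: 0 for k in VESSEL_KEYS}
    for v in ann.vessels:
        if v.diameter_um <= 0:
            raise ValidationError("vessel diameter_um must be positive")
        if v.compartment == "PDL":
            cls = "small" if v.diameter_um < size_threshold_um else "large"
            counts[("PDL", cls)] += 1
        else:
            counts[(v.compartment, "all")] += 1
    return counts


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[HistomorphRecord | EntropyResult | dict]) -> pd.DataFrame:
    """Tidy DataFrame (one row per section x replicate x measurement)."""
    rows: list[dict] = []
    for rec in records:
        if isinstance(rec, HistomorphRecord):
            rows.extend(rec.to_tidy())
        elif isinstance(rec, EntropyResult):
            rows.append(
                {
                    "animal_id": rec.animal_id,
                    "side": rec.side,
                    "timepoint_weeks": rec.timepoint_weeks,
                    "section_index": rec.section_index,
                    "replicate_index": rec.replicate_index,
                    "measurement": f"entropy_{rec.fiber_class}",
                    "value": rec.entropy_bits,
                }
            )
        elif isinstance(rec, dict):
            rows.append(dict(rec))
        else:
            raise ValidationError(f"unsupported record type {type(rec).__name__}")
    return pd.DataFrame(rows)


def aggregate_defect(
    records: Iterable[HistomorphRecord | EntropyResult | dict] | pd.DataFrame,
    min_sections: int = 5,
    require_min_sections: bool = True,
) -> DefectMeasurement:
    """Aggregate one defect's records for one measurement.

    Per section the two blinded replicates are averaged (a missing
    replicate falls back to the single value, with a warning and a flag);
    the per-defect value is the arithmetic mean of the section values.
    Fewer than ``min_sections`` sections is an error unless relaxed.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValidationError("no records to aggregate")
    for col in ("animal_id", "side", "timepoint_weeks", "measurement"):
        if df[col].nunique() != 1:
            raise ValidationError(f"records span multiple values of {col!r}")
    section_values = []
    agreement: dict[int, float] = {}
    incomplete = False
    for sec, grp in df.groupby("section_index", sort=True):
        reps = grp.groupby("replicate_index")["value"].mean()
        if set(reps.index) == {1, 2}:
            section_values.append(float(reps.mean()))
            agreement[int(sec)] = float(abs(reps[1] - reps[2]))
        else:
            logger.warning(
                "section %s has replicate(s) %s only; single-replicate fallback",
                sec,
                sorted(reps.index),
            )
            incomplete = True
            section_values.append(float(reps.mean()))
            agreement[int(sec)] = float("nan")
    n_sections = len(section_values)
    if require_min_sections and n_sections < min_sections:
        raise ValidationError(
            f"defect has {n_sections} sections; at least {min_sections} required"
        )
    row = df.iloc[0]
    return DefectMeasurement(
        animal_id=row["animal_id"],
        side=row["side"],
        timepoint_weeks=row["timepoint_weeks"],
        measurement=row["measurement"],
        value=float(np.mean(section_values)),
        n_sections=n_sections,
        section_values=np.asarray(section_values, dtype=float),
        replicate_agreement=agreement,
        incomplete_replicates=incomplete,
    )


def aggregate_study(
    tidy: pd.DataFrame, min_sections: int = 5, require_min_sections: bool = True
) -> pd.DataFrame:
    """Aggregate a whole study's tidy records to per-defect means.

    Returns one row per (animal_id, side, timepoint_weeks, measurement)
    with columns ``value`` and ``n_sections``.
    """
    required = set(LINKAGE_COLUMNS + ["measurement", "value"])
    missing = required - set(tidy.columns)
    if missing:
        raise ValidationError(f"tidy table is missing columns {sorted(missing)}")
    out = []
    keys = ["animal_id", "side", "timepoint_weeks", "measurement"]
    for key, grp in tidy.groupby(keys, sort=True):
        dm = aggregate_defect(grp, min_sections=min_sections, require_min_sections=require_min_sections)
        out.append(dict(zip(keys, key)) | {"value": dm.value, "n_sections": dm.n_sections})
    return pd.DataFrame(out)
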