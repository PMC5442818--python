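"""Synthetic histology: fiber fields and whole split-mouth study datasets.

No imaging data accompanies the measurement protocol this package
implements, so every pipeline stage is exercised on synthetic sections
with known ground truth:

* :func:`generate_fiber_image` renders a field of straight fiber segments
  whose orientations follow an axial von Mises distribution — the
  circular-Gaussian analogue, with mean direction ``mu`` and
  concentration ``kappa`` (kappa = 0 is isotropic, large kappa is tightly
  aligned). Orientations are axial (theta and theta + 180 deg are the
  same fiber), handled by the standard angle-doubling construction.
* :func:`generate_study` emits a complete split-mouth dataset — every
  animal carries a treated (experimental) and a contralateral control
  defect — with programmed side/time effects on fiber concentration,
  cementum area fraction, and vessel counts, plus an animal-level random
  effect on log kappa, replicate re-measurement jitter on landmarks, and
  full metadata/ground-truth tables.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .preprocess import (
    NOT_COLONIZED,
    AnnotationSet,
    ROIPolygon,
    SectionImage,
    ValidationError,
    VesselMark,
    save_annotations,
)

TIMEPOINT_LABELS = (0, 1, 6, 12, NOT_COLONIZED)


def sample_axial_von_mises(
    rng: np.random.Generator, mean_deg: float, kappa: float, size: int
) -> np.ndarray:
    """Sample fiber orientations in [0, 180) degrees.

    Axial von Mises: the doubled angles 2*theta follow a von Mises
    distribution with mean 2*mean_deg and concentration kappa; kappa = 0
    degenerates to the uniform distribution on the half-circle.
    """
    if kappa < 0:
        raise ValidationError("concentration kappa must be >= 0")
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size)
    doubled = rng.vonmises(math.radians(2.0 * mean_deg), kappa, size)
    return (np.degrees(doubled) / 2.0) % 180.0


@dataclass(frozen=True)
class FiberFieldParams:
    """Parameters of one synthetic fiber field.

    Intensities are 8-bit R-channel values; the background is
    blue-green-dominant (Masson-like) so fibers are the bright structures
    in the red plane. The seed is mandatory: every image is reproducible.
    """

    seed: int
    image_size: tuple[int, int] = (192, 192)  # (width, height)
    n_fibers: int = 60
    mean_direction_deg: float = 60.0
    concentration_kappa: float = 8.0
    fiber_length_mean_px: float = 55.0
    fiber_length_sd_px: float = 14.0
    fiber_width_px: int = 2
    fiber_intensity: int = 200
    background_rgb: tuple[int, int, int] = (40, 70, 110)
    noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.concentration_kappa < 0:
            raise ValidationError("concentration_kappa must be >= 0")
        if not (0.0 <= self.mean_direction_deg < 180.0):
            raise ValidationError("mean_direction_deg must lie in [0, 180)")
        if self.n_fibers < 1 or self.fiber_width_px < 1:
            raise ValidationError("n_fibers and fiber_width_px must be positive")
        if not (0 <= self.fiber_intensity <= 255) or any(
            not 0 <= v <= 255 for v in self.background_rgb
        ):
            raise ValidationError("intensities must lie within 0-255")
        if self.noise_sd < 0 or self.fiber_length_mean_px <= 0:
            raise ValidationError("noise_sd >= 0 and fiber_length_mean_px > 0 required")
        if min(self.image_size) < 16:
            raise ValidationError("image_size must be at least 16x16")


@dataclass(eq=False)
class FiberGroundTruth:
    """What the generator actually drew: angles and the fiber mask."""

    angles_deg: np.ndarray
    fiber_mask: np.ndarray
    params: FiberFieldParams


def _draw_fiber_population(
    canvas: np.ndarray,
    rng: np.random.Generator,
    n_fibers: int,
    mean_direction_deg: float,
    kappa: float,
    length_mean: float,
    length_sd: float,
    width: int,
    intensity: int,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Render one fiber population onto a float RGB canvas; returns
    (drawn angles, fiber mask). Fiber angle 0 deg = horizontal (+x)."""
    h, w = canvas.shape[:2]
    angles = sample_axial_von_mises(rng, mean_direction_deg, kappa, n_fibers)
    cx = rng.uniform(x_range[0], x_range[1], n_fibers)
    cy = rng.uniform(y_range[0], y_range[1], n_fibers)
    lengths = np.clip(rng.normal(length_mean, length_sd, n_fibers), 4.0, None)
    mask = np.zeros((h, w), dtype=bool)
    color = np.array(
        [intensity, 0.35 * intensity, 0.35 * intensity], dtype=float
    )
    half_w = width / 2.0
    for phi, x0, y0, L in zip(np.radians(angles), cx, cy, lengths):
        u = np.array([math.cos(phi), math.sin(phi)])
        nrm = np.array([-math.sin(phi), math.cos(phi)])
        c = np.array([x0, y0])
        corners = np.array(
            [
                c + (L / 2) * u + half_w * nrm,
                c + (L / 2) * u - half_w * nrm,
                c - (L / 2) * u - half_w * nrm,
                c - (L / 2) * u + half_w * nrm,
            ]
        )
        rr, cc = draw_polygon(corners[:, 1], corners[:, 0], shape=(h, w))
        canvas[rr, cc] = color
        mask[rr, cc] = True
    return angles, mask


def _finalize_canvas(canvas: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    if noise_sd > 0:
        canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


def full_field_roi(width: int, height: int, fiber_class: str = "oblique") -> ROIPolygon:
    """PDL ROI covering every pixel center of a width x height raster."""
    v = np.array(
        [
            [-0.5, -0.5],
            [width - 0.5, -0.5],
            [width - 0.5, height - 0.5],
            [-0.5, height - 0.5],
        ]
    )
    return ROIPolygon(vertices=v, compartment="PDL", fiber_class=fiber_class)


def generate_fiber_image(
    params: FiberFieldParams,
    fiber_class: str = "oblique",
    metadata: Mapping | None = None,
) -> tuple[SectionImage, AnnotationSet, FiberGroundTruth]:
    """Render one synthetic fiber field with its annotations.

    The annotation set holds a trivial vertical root tangent (the field is
    already oriented), token CEJ/crest landmarks, and a single full-field
    PDL ROI carrying ``fiber_class``.
    """
    rng = np.random.default_rng(params.seed)
    w, h = params.image_size
    canvas = np.empty((h, w, 3), dtype=float)
    canvas[:] = np.asarray(params.background_rgb, dtype=float)
    angles, mask = _draw_fiber_population(
        canvas,
        rng,
        params.n_fibers,
        params.mean_direction_deg,
        params.concentration_kappa,
        params.fiber_length_mean_px,
        params.fiber_length_sd_px,
        params.fiber_width_px,
        params.fiber_intensity,
        x_range=(0.0, w - 1.0),
        y_range=(0.0, h - 1.0),
    )
    pixels = _finalize_canvas(canvas, rng, params.noise_sd)
    meta = {
        "animal_id": "synthetic",
        "side": "experimental",
        "timepoint_weeks": 0,
        "section_index": 1,
        "replicate_index": 1,
    } | dict(metadata or {})
    section = SectionImage(pixels=pixels, **meta)
    ann = AnnotationSet(
        tangent_a=np.array([(w - 1) / 2.0, 0.0]),
        tangent_b=np.array([(w - 1) / 2.0, h - 1.0]),
        cej_point=np.array([w * 0.25, h * 0.2]),
        crest_point=np.array([w * 0.25, h * 0.6]),
        rois=[full_field_roi(w, h, fiber_class)],
        vessels=[],
    )
    return section, ann, FiberGroundTruth(angles_deg=angles, fiber_mask=mask, params=params)


# ---------------------------------------------------------------------------
# split-mouth study generator
# ---------------------------------------------------------------------------

def _default_kappa() -> dict:
    # fiber concentration per (side, timepoint): healthy tissue is tightly
    # organized; the grafted side reorganizes from week 6 on, the control
    # side only partially.
    return {
        ("control", NOT_COLONIZED): 12.0,
        ("experimental", NOT_COLONIZED): 12.0,
        ("control", 0): 0.7,
        ("experimental", 0): 0.7,
        ("control", 1): 0.9,
        ("experimental", 1): 1.2,
        ("control", 6): 2.0,
        ("experimental", 6): 6.0,
        ("control", 12): 3.0,
        ("experimental", 12): 12.0,
    }


def _default_cementum_fraction() -> dict:
    # fraction of the 1,000 px^2 frame that is cementum-positive; fully
    # rescued at 12 weeks on the grafted side only.
    return {
        ("control", NOT_COLONIZED): 0.95,
        ("experimental", NOT_COLONIZED): 0.95,
        ("control", 0): 0.25,
        ("experimental", 0): 0.25,
        ("control", 1): 0.30,
        ("experimental", 1): 0.35,
        ("control", 6): 0.50,
        ("experimental", 6): 0.70,
        ("control", 12): 0.55,
        ("experimental", 12): 0.95,
    }


def _default_vessel_means() -> dict:
    # Poisson means per (compartment, size class); grafted side shows a
    # two- to four-fold vascularization increase at 6 weeks (all
    # compartments) persisting at 12 weeks in PDL and gingiva.
    base = {("PDL", "small"): 4.0, ("PDL", "large"): 2.0, ("alveolar_bone", "all"): 3.0, ("gingiva", "all"): 3.0}
    means = {}
    for side in ("control", "experimental"):
        for tp in TIMEPOINT_LABELS:
            means[(side, tp)] = dict(base)
    means[("experimental", 6)] = {
        ("PDL", "small"): 13.0,
        ("PDL", "large"): 6.0,
        ("alveolar_bone", "all"): 8.0,
        ("gingiva", "all"): 9.0,
    }
    means[("experimental", 12)] = {
        ("PDL", "small"): 10.0,
        ("PDL", "large"): 5.0,
        ("alveolar_bone", "all"): 3.0,
        ("gingiva", "all"): 7.0,
    }
    return means


@dataclass(frozen=True)
class StudyDesign:
    """Generative design of a synthetic split-mouth study.

    ``n_animals`` colonized mice are distributed evenly over
    ``timepoints``; ``n_not_colonized`` healthy mice form the reference
    group. Each animal contributes both sides (paired split-mouth). The
    per-cell dictionaries program the side/time effects; the animal random
    effect perturbs log kappa multiplicatively, shared by both sides of an
    animal, which is what makes the pairing informative.
    """

    seed: int
    n_animals: int = 24
    n_not_colonized: int = 6
    timepoints: tuple[int, ...] = (0, 1, 6, 12)
    sections_per_defect: int = 5
    image_size: tuple[int, int] = (128, 128)
    n_fibers_per_class: int = 24
    fiber_length_mean_px: float = 36.0
    fiber_length_sd_px: float = 9.0
    fiber_width_px: int = 2
    fiber_intensity: int = 200
    background_rgb: tuple[int, int, int] = (40, 70, 110)
    noise_sd: float = 8.0
    kappa: Mapping = field(default_factory=_default_kappa)
    cementum_fraction: Mapping = field(default_factory=_default_cementum_fraction)
    vessel_means: Mapping = field(default_factory=_default_vessel_means)
    animal_random_effect_sd: float = 0.25
    replicate_noise_sd: float = 1.0
    cementum_area_jitter_px2: float = 25.0
    frame_area_px2: int = 1000
    crest_distance_px: float = 25.0
    pixel_scale_um: float = 2.0

    def __post_init__(self) -> None:
        if self.sections_per_defect < 1:
            raise ValidationError("sections_per_defect must be >= 1")
        if self.n_animals < len(self.timepoints) or self.n_animals % len(self.timepoints):
            raise ValidationError(
                "n_animals must distribute evenly over the timepoints"
            )
        for mapping in (self.kappa, self.cementum_fraction):
            if any(v < 0 for v in mapping.values()):
                raise ValidationError("rate parameters must be >= 0")
        for cell in self.vessel_means.values():
            if any(m < 0 for m in cell.values()):
                raise ValidationError("vessel means must be >= 0")

    @property
    def cells(self) -> list[tuple[str, object]]:
        tps = list(self.timepoints) + ([NOT_COLONIZED] if self.n_not_colonized else [])
        return [(side, tp) for tp in tps for side in ("experimental", "control")]


@dataclass(eq=False)
class StudyDataset:
    """A generated study on disk: metadata + ground truth tables."""

    root: Path
    metadata: pd.DataFrame
    ground_truth: pd.DataFrame


def _frame_geometry(image_size: tuple[int, int]) -> tuple[int, int, int, int]:
    """Fixed 25 x 40 px measuring frame (1,000 px^2) below the CEJ."""
    w, h = image_size
    c0 = max(2, int(w * 0.15))
    r0 = max(2, int(h * 0.2))
    return c0, r0, 25, 40


def _frame_polygon(c0: float, r0: float, ncols: int, nrows: int) -> np.ndarray:
    return np.array(
        [
            [c0 - 0.5, r0 - 0.5],
            [c0 + ncols - 0.5, r0 - 0.5],
            [c0 + ncols - 0.5, r0 + nrows - 0.5],
            [c0 - 0.5, r0 + nrows - 0.5],
        ]
    )


def _render_study_section(
    design: StudyDesign, rng: np.random.Generator, kappa_eff: float
) -> tuple[np.ndarray, dict[str, ROIPolygon], dict[str, np.ndarray]]:
    """One section image with a horizontal-fiber field on the left half
    and an oblique-fiber field on the right half, each with its ROI."""
    w, h = design.image_size
    canvas = np.empty((h, w, 3), dtype=float)
    canvas[:] = np.asarray(design.background_rgb, dtype=float)
    xm = w / 2.0
    common = dict(
        n_fibers=design.n_fibers_per_class,
        kappa=kappa_eff,
        length_mean=design.fiber_length_mean_px,
        length_sd=design.fiber_length_sd_px,
        width=design.fiber_width_px,
        intensity=design.fiber_intensity,
        y_range=(2.0, h - 3.0),
    )
    ang_h, _ = _draw_fiber_population(
        canvas, rng, mean_direction_deg=0.0, x_range=(2.0, xm - 3.0), **common
    )
    ang_o, _ = _draw_fiber_population(
        canvas, rng, mean_direction_deg=60.0, x_range=(xm + 2.0, w - 3.0), **common
    )
    pixels = _finalize_canvas(canvas, rng, design.noise_sd)
    rois = {
        "horizontal": ROIPolygon(
            np.array([[1.5, 1.5], [xm - 2.5, 1.5], [xm - 2.5, h - 2.5], [1.5, h - 2.5]]),
            "PDL",
            "horizontal",
        ),
        "oblique": ROIPolygon(
            np.array([[xm + 1.5, 1.5], [w - 2.5, 1.5], [w - 2.5, h - 2.5], [xm + 1.5, h - 2.5]]),
            "PDL",
            "oblique",
        ),
    }
    return pixels, rois, {"horizontal": ang_h, "oblique": ang_o}


def _make_cementum_mask(
    design: StudyDesign, rng: np.random.Generator, fraction: float
) -> tuple[np.ndarray, int]:
    """Binary cementum raster filling the frame top-down to a target area
    (deterministic fraction plus truncated Gaussian jitter)."""
    w, h = design.image_size
    c0, r0, ncols, nrows = _frame_geometry(design.image_size)
    frame_area = ncols * nrows
    target = fraction * frame_area + rng.normal(0.0, design.cementum_area_jitter_px2)
    target_px = int(np.clip(round(target), 0, frame_area))
    mask = np.zeros((h, w), dtype=np.uint8)
    full_rows, rem = divmod(target_px, ncols)
    if full_rows:
        mask[r0 : r0 + full_rows, c0 : c0 + ncols] = 255
    if rem:
        mask[r0 + full_rows, c0 : c0 + rem] = 255
    return mask, target_px


def _draw_vessels(
    design: StudyDesign, rng: np.random.Generator, means: Mapping
) -> tuple[list[VesselMark], dict]:
    w, h = design.image_size
    diameter_ranges = {
        ("PDL", "small"): (15.0, 45.0),
        ("PDL", "large"): (55.0, 110.0),
        ("alveolar_bone", "all"): (15.0, 90.0),
        ("gingiva", "all"): (15.0, 90.0),
    }
    marks: list[VesselMark] = []
    counts = {}
    for key, mean in means.items():
        n = int(rng.poisson(mean))
        counts[key] = n
        for _ in range(n):
            marks.append(
                VesselMark(
                    center=rng.uniform((1.0, 1.0), (w - 2.0, h - 2.0)),
                    compartment=key[0],
                    diameter_um=float(rng.uniform(*diameter_ranges[key])),
                )
            )
    return marks, counts


def generate_study(design: StudyDesign, out_dir: str | Path) -> StudyDataset:
    """Generate and write a complete synthetic split-mouth dataset.

    Layout under ``out_dir``: ``images/`` (one PNG per section),
    ``masks/`` (binary cementum PNG per section), ``annotations/`` (one
    JSON per section and replicate — the two blinded replicates share the
    section image but carry independently jittered landmarks),
    ``metadata.csv`` (one row per section x replicate) and
    ``ground_truth.csv`` (the generating parameters actually realized).
    """
    root = Path(out_dir)
    for sub in ("images", "masks", "annotations"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)
    w, h = design.image_size
    c0, r0, ncols, nrows = _frame_geometry(design.image_size)
    cej_base = np.array([c0 + (ncols - 1) / 2.0, r0 - 0.5])

    per_tp = design.n_animals // len(design.timepoints)
    animals: list[tuple[str, object]] = []
    i = 0
    for tp in design.timepoints:
        for _ in range(per_tp):
            i += 1
            animals.append((f"M{i:02d}", tp))
    for j in range(design.n_not_colonized):
        animals.append((f"NC{j + 1:02d}", NOT_COLONIZED))

    meta_rows: list[dict] = []
    gt_rows: list[dict] = []
    for animal_id, tp in animals:
        u = rng.normal(0.0, design.animal_random_effect_sd)
        for side in ("experimental", "control"):
            kappa_eff = design.kappa[(side, tp)] * math.exp(u)
            for sec in range(1, design.sections_per_defect + 1):
                stem = f"{animal_id}_{side}_{tp}_s{sec}"
                pixels, rois, angles = _render_study_section(design, rng, kappa_eff)
                image_path = root / "images" / f"{stem}.png"
                iio.imwrite(image_path, pixels)
                mask, target_px = _make_cementum_mask(
                    design, rng, design.cementum_fraction[(side, tp)]
                )
                mask_path = root / "masks" / f"{stem}_cementum.png"
                iio.imwrite(mask_path, mask)
                vessels, counts = _draw_vessels(design, rng, design.vessel_means[(side, tp)])
                for rep in (1, 2):
                    jitter = rng.normal(0.0, design.replicate_noise_sd, 4)
                    jitter = np.clip(jitter, -3.0, 3.0)
                    cej = cej_base + jitter[:2]
                    crest = cej_base + np.array([0.0, design.crest_distance_px]) + jitter[2:]
                    frame = _frame_polygon(c0 + jitter[0], r0 + jitter[1], ncols, nrows)
                    ann = AnnotationSet(
                        tangent_a=np.array([(w - 1) / 2.0, 0.0]),
                        tangent_b=np.array([(w - 1) / 2.0, h - 1.0]),
                        cej_point=cej,
                        crest_point=crest,
                        rois=[
                            rois["horizontal"],
                            rois["oblique"],
                            ROIPolygon(frame, "cementum_frame"),
                        ],
                        vessels=vessels,
                    )
                    ann_path = root / "annotations" / f"{stem}_rep{rep}.json"
                    save_annotations(ann, ann_path)
                    meta_rows.append(
                        {
                            "animal_id": animal_id,
                            "side": side,
                            "timepoint_weeks": tp,
                            "section_index": sec,
                            "replicate_index": rep,
                            "image_path": str(image_path.relative_to(root)),
                            "annotation_path": str(ann_path.relative_to(root)),
                            "mask_path": str(mask_path.relative_to(root)),
                            "pixel_scale_um": design.pixel_scale_um,
                        }
                    )
                gt_rows.append(
                    {
                        "animal_id": animal_id,
                        "side": side,
                        "timepoint_weeks": tp,
                        "section_index": sec,
                        "kappa_eff": kappa_eff,
                        "mean_direction_horizontal_deg": 0.0,
                        "mean_direction_oblique_deg": 60.0,
                        "cementum_target_px2": target_px,
                        **{
                            f"n_vessels_{comp.lower()}_{size}": n
                            for (comp, size), n in counts.items()
                        },
                    }
                )
    metadata = pd.DataFrame(meta_rows)
    ground_truth = pd.DataFrame(gt_rows)
    metadata.to_csv(root / "metadata.csv", index=False)
    ground_truth.to_csv(root / "ground_truth.csv", index=False)
    return StudyDataset(root=root, metadata=metadata, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# measurement-level simulators for the statistics layer
# ---------------------------------------------------------------------------

def simulate_paired_table(
    n_pairs: int,
    paired_effect_d: float = 0.0,
    rng: np.random.Generator | None = None,
    timepoint: int | str = 12,
    measurement: str = "entropy_oblique",
    animal_sd: float = 1.0,
    resid_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-defect table for a paired side contrast.

    value = animal effect + side shift + residual; ``paired_effect_d`` is
    the standardized paired effect (mean within-animal difference divided
    by its SD, which is sqrt(2)*resid_sd here), added to the experimental
    side.
    """
    rng = rng or np.random.default_rng()
    shift = paired_effect_d * math.sqrt(2.0) * resid_sd
    rows = []
    for i in range(n_pairs):
        a = rng.normal(0.0, animal_sd)
        for side, mu in (("experimental", shift), ("control", 0.0)):
            rows.append(
                {
                    "animal_id": f"M{i + 1:02d}",
                    "side": side,
                    "timepoint_weeks": timepoint,
                    "measurement": measurement,
                    "value": a + mu + rng.normal(0.0, resid_sd),
                }
            )
    return pd.DataFrame(rows)


def simulate_reference_table(
    n_per_group: int,
    timepoints: tuple = (1, 6, 12),
    reference_timepoint: int | str = 0,
    shifts: Mapping | None = None,
    rng: np.random.Generator | None = None,
    measurement: str = "entropy_oblique",
) -> pd.DataFrame:
    """Experimental-side groups at a reference timepoint and several
    contrast timepoints (independent animals), for reference contrasts."""
    rng = rng or np.random.default_rng()
    shifts = shifts or {}
    rows = []
    i = 0
    for tp in (reference_timepoint, *timepoints):
        for _ in range(n_per_group):
            i += 1
            rows.append(
                {
                    "animal_id": f"M{i:02d}",
                    "side": "experimental",
                    "timepoint_weeks": tp,
                    "measurement": measurement,
                    "value": float(shifts.get(tp, 0.0)) + rng.normal(),
                }
            )
    return pd.DataFrame(rows)
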