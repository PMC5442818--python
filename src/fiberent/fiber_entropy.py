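"""Fiber-organization statistic: Hough transform -> angular distribution -> entropy.

The periodontal ligament (PDL) anchors the tooth root through collagen
fiber bundles whose orientations are tightly organized in healthy tissue
(distinct horizontal and oblique groups) and disorganized in diseased or
healing tissue. This module quantifies that organization on the
red-channel image of an oriented section:

1. gradient edges of the ROI-masked raster (Sobel magnitude, Otsu or fixed
   threshold),
2. a straight-line Hough transform with the standard normal
   parameterization ``rho = x*cos(theta) + y*sin(theta)`` — implemented
   here by direct voting, because the exact accumulator is the object the
   statistic is defined on,
3. a probability distribution over angular bins derived from the
   accumulator columns,
4. the Shannon entropy of that distribution, in bits.

Low entropy means a concentrated angular distribution, i.e. well-aligned
fibers; the maximum, ``log2(n_bins)``, corresponds to a fully isotropic
field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import sobel, threshold_otsu

from .preprocess import (
    AnnotationSet,
    RoiCrop,
    SectionImage,
    ValidationError,
    crop_roi,
    extract_red_channel,
    orient_vertical,
)


class NoFiberSignalError(ValueError):
    """Raised when an ROI contributes no edge votes ("no fiber signal in ROI")."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name is attached to the message."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r}: {original}")
        self.stage = stage
        self.original = original


@dataclass(eq=False)
class EdgeMap:
    """Binary edge raster for one ROI crop, with detector provenance."""

    pixels: np.ndarray
    method_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError("EdgeMap pixels must be 2-D")
        self.pixels = px.astype(bool)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.pixels))


@dataclass(eq=False)
class HoughAccumulator:
    """Vote matrix over (rho, theta) bins.

    ``votes[k, j]`` counts edge pixels whose offset ``x*cos(theta_j) +
    y*sin(theta_j)`` falls nearest to ``rhos[k]``. ``thetas_deg`` are bin
    centers covering [-90, +90) at resolution ``delta_theta_deg``; ``rhos``
    are symmetric about 0 at resolution ``delta_rho_px`` and span the crop
    diagonal. Every edge pixel votes exactly once per theta bin.
    """

    votes: np.ndarray
    thetas_deg: np.ndarray
    rhos: np.ndarray
    delta_theta_deg: float
    delta_rho_px: float

    @property
    def n_theta(self) -> int:
        return self.votes.shape[1]

    @property
    def total_votes(self) -> int:
        return int(self.votes.sum())


@dataclass(eq=False)
class AngularDistribution:
    """Normalized probability mass over fiber-orientation bins.

    ``thetas_deg`` are the Hough normal angles of the bins; the physical
    fiber orientation of bin j is ``(thetas_deg[j] + 90) mod 180`` with
    0 deg = horizontal in the oriented image (so a fiber perpendicular to
    the vertical root axis reads 0 deg).
    """

    p: np.ndarray
    thetas_deg: np.ndarray
    q: float
    column_stat: str = "max"

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.size == 0 or np.any(p < 0):
            raise ValidationError("p must be a 1-D vector of non-negative mass")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("probabilities must sum to 1 within 1e-9")
        self.p = p

    @property
    def n_bins(self) -> int:
        return self.p.size

    @property
    def fiber_angles_deg(self) -> np.ndarray:
        return (np.asarray(self.thetas_deg, dtype=float) + 90.0) % 180.0

    def circular_mean_deg(self) -> float:
        """Mean fiber orientation (axial, in [0, 180)), via angle doubling."""
        a = np.radians(2.0 * self.fiber_angles_deg)
        m = math.atan2(float(np.sum(self.p * np.sin(a))), float(np.sum(self.p * np.cos(a))))
        return (math.degrees(m) / 2.0) % 180.0


@dataclass(eq=False)
class EntropyResult:
    """Shannon entropy (bits) of one ROI's angular distribution."""

    entropy_bits: float
    n_bins: int
    fiber_class: str | None = None
    animal_id: str | None = None
    side: str | None = None
    timepoint_weeks: int | str | None = None
    section_index: int | None = None
    replicate_index: int | None = None

    def __post_init__(self) -> None:
        ceiling = math.log2(self.n_bins) if self.n_bins > 0 else 0.0
        if not (-1e-9 <= self.entropy_bits <= ceiling + 1e-9):
            raise ValidationError(
                f"entropy {self.entropy_bits} outside [0, log2({self.n_bins})]"
            )


@dataclass(frozen=True)
class DetectedLine:
    """One accumulator peak, for overlay rendering only."""

    rho: float
    theta_deg: float
    votes: int


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable settings of the fiber-entropy pipeline.

    ``column_stat`` selects how each theta column of the accumulator is
    condensed before normalization: "max" (default) takes the strongest
    single line support at that angle, "energy" sums votes**q over rho.
    ``q`` is the exponent applied to the column statistic ("max") or to
    each cell ("energy"); larger q suppresses the diffuse vote floor that
    every edge pixel spreads across all angles.
    """

    delta_theta_deg: float = 1.0
    delta_rho_px: float = 1.0
    q: float = 4.0
    column_stat: str = "max"
    threshold_mode: str = "otsu"
    fixed_value: float | None = None
    mask_erosion_px: int = 2

    def as_dict(self) -> dict[str, Any]:
        return {
            "delta_theta_deg": self.delta_theta_deg,
            "delta_rho_px": self.delta_rho_px,
            "q": self.q,
            "column_stat": self.column_stat,
            "threshold_mode": self.threshold_mode,
            "fixed_value": self.fixed_value,
            "mask_erosion_px": self.mask_erosion_px,
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def detect_edges(
    gray: np.ndarray | RoiCrop,
    threshold_mode: str = "otsu",
    fixed_value: float | None = None,
    mask: np.ndarray | None = None,
    mask_erosion_px: int = 2,
) -> EdgeMap:
    """Binary gradient-magnitude edges of an ROI-masked raster.

    Sobel magnitude is thresholded either by Otsu's method over in-mask
    values or at a fixed value. The ROI mask is eroded by
    ``mask_erosion_px`` before application so the artificial step at the
    polygon boundary never contributes edges; outside-mask pixels are
    replaced by the in-mask mean before the gradient is taken for the same
    reason. An all-constant raster yields a valid all-zero edge map.
    """
    if isinstance(gray, RoiCrop):
        mask = gray.mask if mask is None else mask
        g = gray.pixels.astype(float)
    else:
        g = np.asarray(gray, dtype=float)
    if g.ndim != 2 or g.size == 0:
        raise ValidationError("detect_edges expects a non-empty 2-D raster")
    if threshold_mode not in ("otsu", "fixed"):
        raise ValidationError(f"unknown threshold_mode {threshold_mode!r}")
    if threshold_mode == "fixed" and fixed_value is None:
        raise ValidationError("fixed threshold_mode requires fixed_value")

    if mask is None:
        work_mask = np.ones(g.shape, dtype=bool)
    else:
        work_mask = np.asarray(mask, dtype=bool)
        if work_mask.shape != g.shape:
            raise ValidationError("mask shape must match the raster")
        if work_mask.any():
            g = g.copy()
            g[~work_mask] = g[work_mask].mean()
    if mask_erosion_px > 0 and mask is not None:
        work_mask = ndimage.binary_erosion(work_mask, iterations=mask_erosion_px)

    params = {
        "detector": "sobel",
        "threshold_mode": threshold_mode,
        "mask_erosion_px": mask_erosion_px,
    }
    if not work_mask.any():
        return EdgeMap(np.zeros(g.shape, dtype=bool), params | {"threshold": None})

    grad = sobel(g)
    vals = grad[work_mask]
    if threshold_mode == "fixed":
        thr = float(fixed_value)
    else:
        if np.ptp(vals) == 0:  # constant gradient (e.g. uniform raster)
            return EdgeMap(np.zeros(g.shape, dtype=bool), params | {"threshold": None})
        thr = float(threshold_otsu(vals))
    edges = (grad >= thr) & (grad > 0) & work_mask
    return EdgeMap(edges, params | {"threshold": thr})


def hough_transform(
    edges: EdgeMap | np.ndarray,
    delta_theta_deg: float = 1.0,
    delta_rho_px: float = 1.0,
) -> HoughAccumulator:
    """Straight-line Hough transform by direct voting.

    Each edge pixel at (x, y) = (col, row) casts one vote per theta bin,
    into the rho bin nearest ``x*cos(theta) + y*sin(theta)``; total votes
    are therefore (number of edge pixels) x (number of theta bins).
    """
    e = edges.pixels if isinstance(edges, EdgeMap) else np.asarray(edges).astype(bool)
    if e.ndim != 2:
        raise ValidationError("edge map must be 2-D")
    if delta_rho_px <= 0:
        raise ValidationError("delta_rho_px must be positive")
    n_theta_f = 180.0 / delta_theta_deg
    n_theta = int(round(n_theta_f))
    if delta_theta_deg <= 0 or abs(n_theta_f - n_theta) > 1e-9:
        raise ValidationError("delta_theta_deg must divide 180 evenly")

    thetas = -90.0 + np.arange(n_theta) * delta_theta_deg
    h, w = e.shape
    rho_max = math.hypot(h - 1, w - 1)
    n_half = int(math.ceil(rho_max / delta_rho_px)) if rho_max > 0 else 1
    rhos = (np.arange(2 * n_half + 1) - n_half) * delta_rho_px

    votes = np.zeros((rhos.size, n_theta), dtype=np.int64)
    ys, xs = np.nonzero(e)
    if xs.size:
        cos = np.cos(np.radians(thetas))
        sin = np.sin(np.radians(thetas))
        for j in range(n_theta):
            r = xs * cos[j] + ys * sin[j]
            k = np.rint(r / delta_rho_px).astype(np.int64) + n_half
            votes[:, j] = np.bincount(k, minlength=rhos.size)
    return HoughAccumulator(
        votes=votes,
        thetas_deg=thetas,
        rhos=rhos,
        delta_theta_deg=float(delta_theta_deg),
        delta_rho_px=float(delta_rho_px),
    )


def extract_lines(
    acc: HoughAccumulator,
    n_peaks: int = 20,
    min_votes_frac: float = 0.3,
    suppression_window: tuple[int, int] = (5, 5),
) -> list[DetectedLine]:
    """Accumulator peaks ("main directions of detected fibers").

    Greedy non-maximum suppression over a (rho, theta) window so one fiber
    yields one line; ties are broken toward the lower theta bin index.
    Rendering-only: the entropy statistic never depends on this step.
    """
    if n_peaks < 1:
        raise ValidationError("n_peaks must be >= 1")
    if not (0.0 < min_votes_frac <= 1.0):
        raise ValidationError("min_votes_frac must be in (0, 1]")
    v = acc.votes
    vmax = v.max() if v.size else 0
    if vmax == 0:
        return []
    thr = min_votes_frac * vmax
    ks, js = np.nonzero(v >= thr)
    order = np.lexsort((ks, js, -v[ks, js]))  # votes desc, then theta, then rho
    half_r = suppression_window[0] // 2
    half_t = suppression_window[1] // 2
    picked: list[tuple[int, int]] = []
    out: list[DetectedLine] = []
    for idx in order:
        k, j = int(ks[idx]), int(js[idx])
        if any(abs(k - pk) <= half_r and abs(j - pj) <= half_t for pk, pj in picked):
            continue
        picked.append((k, j))
        out.append(DetectedLine(float(acc.rhos[k]), float(acc.thetas_deg[j]), int(v[k, j])))
        if len(out) >= n_peaks:
            break
    return out


def angular_distribution(
    acc: HoughAccumulator, q: float = 4.0, column_stat: str = "max"
) -> AngularDistribution:
    """Probability of each angular direction, derived from the accumulator.

    Because a standard Hough transform lets every edge pixel vote once in
    every theta column, the plain column sums are identical by
    construction and carry no orientation signal; the distribution must
    weight *collinear structure* within each column. Two derivations are
    offered:

    * ``column_stat="max"`` (default): the strongest single line support
      at each angle, ``(max_rho votes[rho, j])**q`` — the theta profile of
      detected-line strength;
    * ``column_stat="energy"``: the vote energy ``sum_rho votes**q``.

    The exponent q (default 4) sets how strongly the diffuse background
    vote floor is suppressed relative to aligned structure.
    """
    if acc.votes.sum() == 0:
        raise NoFiberSignalError("no fiber signal in ROI")
    if q <= 0:
        raise ValidationError("q must be positive")
    v = acc.votes.astype(float)
    if column_stat == "max":
        col = v.max(axis=0) ** q
    elif column_stat == "energy":
        col = (v**q).sum(axis=0)
    else:
        raise ValidationError(f"unknown column_stat {column_stat!r}")
    p = col / col.sum()
    p = p / p.sum()  # renormalize away rounding drift
    return AngularDistribution(
        p=p, thetas_deg=acc.thetas_deg.copy(), q=float(q), column_stat=column_stat
    )


def shannon_entropy(
    dist: AngularDistribution,
    fiber_class: str | None = None,
    section: SectionImage | None = None,
) -> EntropyResult:
    """Shannon entropy H = -sum p_i log2 p_i of the angular distribution.

    Zero bins contribute nothing (0 * log 0 := 0); units are bits, so H
    ranges from 0 (a single direction) to log2(n_bins) (isotropy).
    """
    p = dist.p[dist.p > 0]
    h = float(-(p * np.log2(p)).sum())
    h = max(h, 0.0)
    meta = section.metadata() if section is not None else {}
    return EntropyResult(
        entropy_bits=h,
        n_bins=dist.n_bins,
        fiber_class=fiber_class,
        animal_id=meta.get("animal_id"),
        side=meta.get("side"),
        timepoint_weeks=meta.get("timepoint_weeks"),
        section_index=meta.get("section_index"),
        replicate_index=meta.get("replicate_index"),
    )


def fiber_entropy_pipeline(
    section: SectionImage,
    ann: AnnotationSet,
    config: PipelineConfig | None = None,
) -> list[EntropyResult]:
    """Full fiber-organization analysis of one section.

    orient vertically -> red channel -> per labeled PDL ROI: crop ->
    edges -> Hough transform -> angular distribution -> entropy. One
    result per ROI whose fiber_class is "horizontal" or "oblique". Stage
    failures are re-raised with the stage name attached.
    """
    cfg = config or PipelineConfig()
    fiber_rois = [
        r for r in ann.rois if r.compartment == "PDL" and r.fiber_class != "none"
    ]
    if not fiber_rois:
        raise ValidationError("annotation set has no PDL ROI with a fiber class")

    try:
        oriented = orient_vertical(section, ann)
    except NoFiberSignalError:
        raise
    except Exception as exc:
        raise PipelineStageError("orient_vertical", exc) from exc
    red = extract_red_channel(oriented.section)

    results: list[EntropyResult] = []
    for roi in oriented.annotations.rois:
        if roi.compartment != "PDL" or roi.fiber_class == "none":
            continue
        try:
            crop = crop_roi(red, roi)
        except Exception as exc:
            raise PipelineStageError("crop_roi", exc) from exc
        try:
            edges = detect_edges(
                crop,
                threshold_mode=cfg.threshold_mode,
                fixed_value=cfg.fixed_value,
                mask_erosion_px=cfg.mask_erosion_px,
            )
        except Exception as exc:
            raise PipelineStageError("detect_edges", exc) from exc
        try:
            acc = hough_transform(edges, cfg.delta_theta_deg, cfg.delta_rho_px)
            dist = angular_distribution(acc, q=cfg.q, column_stat=cfg.column_stat)
        except NoFiberSignalError:
            raise
        except Exception as exc:
            raise PipelineStageError("hough_transform", exc) from exc
        results.append(
            shannon_entropy(dist, fiber_class=roi.fiber_class, section=oriented.section)
        )
    return results
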