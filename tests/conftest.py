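"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately avoid the implementation's vectorized code
paths: the Hough oracle votes pixel by pixel and bin by bin, polygon
membership is asked of shapely, and aggregation is re-done with plain
Python loops.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from fiberent.preprocess import AnnotationSet, ROIPolygon, SectionImage


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def hough_oracle(edges: np.ndarray, delta_theta_deg: float = 1.0, delta_rho_px: float = 1.0):
    """Exhaustive per-pixel, per-bin Hough voting (pure Python loops)."""
    e = np.asarray(edges).astype(bool)
    h, w = e.shape
    n_theta = round(180.0 / delta_theta_deg)
    rho_max = math.hypot(h - 1, w - 1)
    n_half = math.ceil(rho_max / delta_rho_px) if rho_max > 0 else 1
    votes = np.zeros((2 * n_half + 1, n_theta), dtype=np.int64)
    for y in range(h):
        for x in range(w):
            if not e[y, x]:
                continue
            for j in range(n_theta):
                theta = math.radians(-90.0 + j * delta_theta_deg)
                r = x * math.cos(theta) + y * math.sin(theta)
                votes[round(r / delta_rho_px) + n_half, j] += 1
    return votes


def point_in_polygon_oracle(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pixel-center membership via shapely, one point at a time."""
    poly = Polygon(np.asarray(vertices, dtype=float))
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for r in range(h):
        for c in range(w):
            mask[r, c] = poly.contains(Point(float(c), float(r)))
    return mask


def rayleigh_uniformity_p(angles_deg_axial: np.ndarray) -> float:
    """Rayleigh test p-value for uniformity of axial angles (doubled)."""
    a = np.radians(2.0 * np.asarray(angles_deg_axial, dtype=float))
    n = a.size
    rbar = math.hypot(np.cos(a).mean(), np.sin(a).mean())
    z = n * rbar**2
    p = math.exp(-z) * (1 + (2 * z - z**2) / (4 * n) - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2))
    return min(max(p, 0.0), 1.0)


def circular_distance_deg(a: float, b: float) -> float:
    """Axial angular distance in degrees (orientations mod 180)."""
    d = abs((a - b) % 180.0)
    return min(d, 180.0 - d)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def valid_metadata() -> dict:
    return {
        "animal_id": "M01",
        "side": "experimental",
        "timepoint_weeks": 12,
        "section_index": 1,
        "replicate_index": 1,
    }


@pytest.fixture
def uniform_section(valid_metadata) -> SectionImage:
    px = np.zeros((16, 16, 3), dtype=np.uint8)
    px[..., 0] = 200
    px[..., 1] = 10
    px[..., 2] = 10
    return SectionImage(pixels=px, **valid_metadata)


def make_annotations(
    width: int = 16,
    height: int = 16,
    tangent=None,
    rois=None,
    vessels=None,
    cej=(2.0, 2.0),
    crest=(2.0, 10.0),
) -> AnnotationSet:
    if tangent is None:
        tangent = ((width / 2.0, 0.0), (width / 2.0, height - 1.0))
    return AnnotationSet(
        tangent_a=np.asarray(tangent[0], float),
        tangent_b=np.asarray(tangent[1], float),
        cej_point=np.asarray(cej, float),
        crest_point=np.asarray(crest, float),
        rois=list(rois or []),
        vessels=list(vessels or []),
    )


@pytest.fixture
def annotation_factory():
    return make_annotations


def random_simple_polygon(rng: np.random.Generator, width: int, height: int) -> ROIPolygon:
    """Convex polygon with fractional vertices (no pixel center on an edge)."""
    n = int(rng.integers(3, 7))
    cx = rng.uniform(width * 0.35, width * 0.65)
    cy = rng.uniform(height * 0.35, height * 0.65)
    r_max = min(cx, width - 1.5 - cx, cy, height - 1.5 - cy)
    # well-separated angles keep the star-shaped polygon strictly simple
    angles = np.linspace(0, 2 * math.pi, n, endpoint=False)
    angles = angles + rng.uniform(0.0, 0.7 * 2 * math.pi / n, n)
    radius = rng.uniform(0.4 * r_max, r_max, n)
    verts = np.stack(
        [cx + radius * np.cos(angles) + 0.13, cy + radius * np.sin(angles) + 0.17],
        axis=1,
    )
    return ROIPolygon(vertices=verts, compartment="PDL", fiber_class="oblique")
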