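"""Section loading, orientation against the root tangent, ROI cropping."""

import math

import imageio.v3 as iio
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberent.preprocess import (
    AnnotationSet,
    ROIPolygon,
    SectionImage,
    ValidationError,
    VesselMark,
    crop_roi,
    extract_red_channel,
    load_annotations,
    load_section,
    orient_vertical,
    polygon_mask,
    rotate_points,
    rotation_to_vertical_deg,
    save_annotations,
)
from fiberent.synthetic import FiberFieldParams, generate_fiber_image

from conftest import make_annotations, point_in_polygon_oracle, random_simple_polygon


class TestLoadSection:
    def test_black_png_loads_identically(self, tmp_path, valid_metadata):
        path = tmp_path / "black.png"
        iio.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8))
        sec = load_section(path, valid_metadata)
        assert sec.pixels.shape == (4, 4, 3)
        assert np.all(sec.pixels == 0)

    def test_synthetic_image_write_read_round_trip(self, tmp_path, valid_metadata):
        sec, _, _ = generate_fiber_image(FiberFieldParams(seed=5, image_size=(64, 64), n_fibers=10))
        path = tmp_path / "fibers.png"
        iio.imwrite(path, sec.pixels)
        reloaded = load_section(path, valid_metadata)
        np.testing.assert_array_equal(reloaded.pixels, sec.pixels)

    def test_grayscale_promoted_to_rgb(self, tmp_path, valid_metadata):
        path = tmp_path / "gray.png"
        iio.imwrite(path, np.full((5, 5), 77, dtype=np.uint8))
        sec = load_section(path, valid_metadata)
        assert sec.pixels.shape == (5, 5, 3)
        assert np.all(sec.pixels == 77)

    @pytest.mark.parametrize(
        "field,value",
        [("timepoint_weeks", 3), ("side", "left"), ("replicate_index", 4)],
    )
    def test_invalid_metadata_enum_rejected(self, tmp_path, valid_metadata, field, value):
        path = tmp_path / "img.png"
        iio.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8))
        bad = valid_metadata | {field: value}
        with pytest.raises(ValidationError, match=field.split("_")[0]):
            load_section(path, bad)

    def test_unreadable_file_raises_io_error(self, tmp_path, valid_metadata):
        with pytest.raises(IOError):
            load_section(tmp_path / "missing.png", valid_metadata)

    def test_not_colonized_flag_accepted(self, tmp_path, valid_metadata):
        path = tmp_path / "img.png"
        iio.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8))
        sec = load_section(path, valid_metadata | {"timepoint_weeks": "not_colonized"})
        assert sec.timepoint_weeks == "not_colonized"


class TestOrientVertical:
    def test_vertical_tangent_is_identity(self, uniform_section):
        ann = make_annotations(tangent=((0, 0), (0, 10)))
        res = orient_vertical(uniform_section, ann)
        assert res.angle_deg == 0.0
        np.testing.assert_array_equal(res.section.pixels, uniform_section.pixels)

    def test_horizontal_tangent_rotates_90(self, valid_metadata):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, (8, 12, 3), dtype=np.uint8)
        sec = SectionImage(pixels=px, **valid_metadata)
        ann = make_annotations(tangent=((0, 0), (10, 0)))
        res = orient_vertical(sec, ann)
        assert abs(abs(res.angle_deg) - 90.0) < 1e-9
        assert res.section.pixels.shape[:2] == (12, 8)
        # every pixel must land where the coordinate rotation oracle says
        a = math.radians(res.angle_deg)
        c_in = ((12 - 1) / 2, (8 - 1) / 2)
        c_out = ((8 - 1) / 2, (12 - 1) / 2)
        for (x, y) in [(0, 0), (11, 0), (5, 3), (11, 7)]:
            xr = math.cos(a) * (x - c_in[0]) - math.sin(a) * (y - c_in[1]) + c_out[0]
            yr = math.sin(a) * (x - c_in[0]) + math.cos(a) * (y - c_in[1]) + c_out[1]
            assert res.section.pixels[round(yr), round(xr), 0] == px[y, x, 0]

    def test_annotation_points_follow_rotation_matrix(self, uniform_section):
        roi = ROIPolygon(np.array([[2.0, 2.0], [9.0, 2.0], [6.0, 9.0]]), "PDL", "oblique")
        ann = make_annotations(tangent=((3.0, 1.0), (9.0, 12.0)), rois=[roi])
        res = orient_vertical(uniform_section, ann)
        d = res.annotations.tangent_b - res.annotations.tangent_a
        assert abs(d[0]) < 1e-9  # tangent now vertical

    @pytest.mark.parametrize("theta", [-72.5, -30.0, 10.0, 45.0, 88.0])
    def test_round_trip_recovers_tangent_direction(self, uniform_section, theta):
        # a tangent tilted theta degrees from vertical is restored to vertical
        c = (7.5, 7.5)
        ta = rotate_points(np.array([7.5, 2.0]), theta, c, c)
        tb = rotate_points(np.array([7.5, 13.0]), theta, c, c)
        res = orient_vertical(uniform_section, make_annotations(tangent=(ta, tb)))
        residual = rotation_to_vertical_deg(
            res.annotations.tangent_a, res.annotations.tangent_b
        )
        assert abs(residual) < 0.1

    def test_rigid_transform_preserves_pairwise_distances(self, uniform_section):
        roi = ROIPolygon(np.array([[1.0, 1.0], [12.0, 2.0], [8.0, 13.0]]), "PDL", "horizontal")
        vessel = VesselMark(np.array([5.0, 5.0]), "PDL", 30.0)
        ann = make_annotations(tangent=((2.0, 1.0), (11.0, 13.0)), rois=[roi], vessels=[vessel])
        res = orient_vertical(uniform_section, ann)
        before = np.array(ann.points())
        after = np.array(res.annotations.points())
        d0 = np.linalg.norm(before[:, None] - before[None], axis=-1)
        d1 = np.linalg.norm(after[:, None] - after[None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-6)

    def test_orientation_is_idempotent(self, uniform_section):
        ann = make_annotations(tangent=((2.0, 1.0), (11.0, 13.0)))
        first = orient_vertical(uniform_section, ann)
        second = orient_vertical(first.section, first.annotations)
        assert abs(second.angle_deg) < 0.1

    def test_coincident_tangent_points_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            make_annotations(tangent=((3.0, 3.0), (3.0, 3.0)))


class TestRedChannel:
    def test_uniform_red_dominant_image(self, uniform_section):
        red = extract_red_channel(uniform_section)
        assert red.shape == (16, 16)
        assert np.all(red == 200)

    def test_pure_blue_yields_zero(self, valid_metadata):
        px = np.zeros((6, 6, 3), dtype=np.uint8)
        px[..., 2] = 255
        assert np.all(extract_red_channel(SectionImage(pixels=px, **valid_metadata)) == 0)

    def test_bit_exact_equality_with_r_plane(self, valid_metadata):
        px = np.random.default_rng(1).integers(0, 256, (9, 7, 3), dtype=np.uint8)
        sec = SectionImage(pixels=px, **valid_metadata)
        np.testing.assert_array_equal(extract_red_channel(sec), px[:, :, 0])

    def test_fibers_brighter_than_background_in_red(self):
        sec, _, gt = generate_fiber_image(FiberFieldParams(seed=2))
        red = extract_red_channel(sec).astype(float)
        assert red[gt.fiber_mask].mean() > red[~gt.fiber_mask].mean() + 50


class TestCropRoi:
    def test_full_field_rectangle_is_identity(self):
        g = np.arange(64, dtype=np.uint8).reshape(8, 8)
        roi = ROIPolygon(
            np.array([[-0.5, -0.5], [7.5, -0.5], [7.5, 7.5], [-0.5, 7.5]]), "PDL", "oblique"
        )
        crop = crop_roi(g, roi)
        np.testing.assert_array_equal(crop.pixels, g)
        assert crop.mask.all()

    def test_centered_square_bounding_box(self):
        g = np.full((10, 10), 9, dtype=np.uint8)
        roi = ROIPolygon(
            np.array([[2.5, 2.5], [6.5, 2.5], [6.5, 6.5], [2.5, 6.5]]), "PDL", "oblique"
        )
        crop = crop_roi(g, roi)
        assert crop.pixels.shape == (4, 4)
        assert crop.origin == (3, 3)
        assert crop.mask.all()

    def test_polygon_outside_bounds_rejected(self):
        g = np.zeros((10, 10), dtype=np.uint8)
        roi = ROIPolygon(np.array([[5.0, 5.0], [14.0, 5.0], [9.0, 9.0]]), "PDL", "oblique")
        with pytest.raises(ValidationError, match="bounds"):
            crop_roi(g, roi)

    @pytest.mark.parametrize("seed", range(8))
    def test_mask_matches_point_in_polygon_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = int(rng.integers(12, 64))
        w = int(rng.integers(12, 64))
        g = rng.integers(0, 255, (h, w), dtype=np.uint8)
        roi = random_simple_polygon(rng, w, h)
        crop = crop_roi(g, roi, fill=7)
        oracle = point_in_polygon_oracle(roi.vertices, (h, w))
        r0, c0 = crop.origin
        hh, ww = crop.mask.shape
        np.testing.assert_array_equal(crop.mask, oracle[r0 : r0 + hh, c0 : c0 + ww])
        assert int(crop.mask.sum()) == int(oracle.sum())
        assert np.all(crop.pixels[~crop.mask] == 7)


class TestAnnotationIO:
    def test_json_round_trip(self, tmp_path):
        roi = ROIPolygon(np.array([[1.0, 1.0], [9.0, 1.0], [5.0, 9.0]]), "PDL", "horizontal")
        frame = ROIPolygon(np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 4.0], [0.0, 4.0]]), "cementum_frame")
        vessels = [VesselMark(np.array([3.0, 4.0]), "PDL", 60.0)]
        ann = make_annotations(rois=[roi, frame], vessels=vessels)
        path = tmp_path / "ann.json"
        save_annotations(ann, path)
        back = load_annotations(path)
        np.testing.assert_allclose(back.tangent_a, ann.tangent_a)
        np.testing.assert_allclose(back.rois[0].vertices, roi.vertices)
        assert back.rois[1].compartment == "cementum_frame"
        assert back.vessels[0].diameter_um == 60.0

    def test_fiber_class_requires_pdl(self):
        with pytest.raises(ValidationError, match="PDL"):
            ROIPolygon(np.array([[0, 0], [4, 0], [2, 3]]), "gingiva", "oblique")

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0.0, 0.0], [4.0, 4.0], [4.0, 0.0], [0.0, 4.0]])
        with pytest.raises(ValidationError, match="simple"):
            ROIPolygon(bowtie, "PDL", "oblique")


@settings(deadline=None, max_examples=25)
@given(
    angle=st.floats(-89.0, 89.0),
    x=st.floats(-20.0, 20.0),
    y=st.floats(-20.0, 20.0),
)
def test_rotate_points_preserves_norm(angle, x, y):
    p = np.array([x, y])
    out = rotate_points(p, angle, (0.0, 0.0), (0.0, 0.0))
    assert math.isclose(np.linalg.norm(out), np.linalg.norm(p), abs_tol=1e-9)
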