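"""Edge detection, Hough voting, angular distribution, entropy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberent.fiber_entropy import (
    AngularDistribution,
    NoFiberSignalError,
    PipelineConfig,
    angular_distribution,
    detect_edges,
    extract_lines,
    fiber_entropy_pipeline,
    hough_transform,
    shannon_entropy,
)
from fiberent.preprocess import (
    SectionImage,
    ValidationError,
    crop_roi,
    extract_red_channel,
)
from fiberent.synthetic import FiberFieldParams, full_field_roi, generate_fiber_image
from scipy import ndimage

from conftest import circular_distance_deg, hough_oracle, make_annotations


class TestDetectEdges:
    def test_uniform_raster_gives_no_edges(self):
        edges = detect_edges(np.full((20, 20), 130.0))
        assert edges.n_edges == 0

    def test_single_bright_line_edges_stay_within_one_pixel(self):
        g = np.zeros((21, 21))
        g[:, 10] = 255.0
        edges = detect_edges(g)
        assert edges.n_edges > 0
        ys, xs = np.nonzero(edges.pixels)
        assert np.all(np.abs(xs - 10) <= 1)

    def test_edge_fraction_tracks_fiber_boundary_fraction(self):
        sec, ann, gt = generate_fiber_image(FiberFieldParams(seed=11))
        crop = crop_roi(extract_red_channel(sec), ann.rois[0])
        edges = detect_edges(crop)
        boundary = gt.fiber_mask ^ ndimage.binary_erosion(gt.fiber_mask)
        boundary_frac = boundary.mean()
        edge_frac = edges.pixels.mean()
        assert 0.1 * boundary_frac <= edge_frac <= 10.0 * boundary_frac

    def test_fixed_mode_requires_value(self):
        with pytest.raises(ValidationError, match="fixed_value"):
            detect_edges(np.zeros((5, 5)), threshold_mode="fixed")


class TestHoughTransform:
    def test_single_origin_pixel_votes_in_zero_rho_for_every_theta(self):
        e = np.zeros((5, 5), dtype=bool)
        e[0, 0] = True
        acc = hough_transform(e)
        zero_bin = int(np.argmin(np.abs(acc.rhos)))
        assert np.all(acc.votes[zero_bin, :] == 1)
        assert acc.total_votes == acc.n_theta

    def test_vertical_segment_peak_at_theta_zero_rho_five(self):
        e = np.zeros((11, 11), dtype=bool)
        e[:, 5] = True
        acc = hough_transform(e)
        j0 = int(np.argmin(np.abs(acc.thetas_deg)))  # theta = 0 column
        k5 = int(np.argmin(np.abs(acc.rhos - 5.0)))  # rho = 5 bin
        # all 11 collinear pixels land in one cell, reaching the global
        # maximum (nearby theta bins can tie on so short a segment)
        assert acc.votes[k5, j0] == 11
        assert acc.votes[k5, j0] == acc.votes.max()
        np.testing.assert_array_equal(acc.votes, hough_oracle(e))

    @pytest.mark.parametrize("seed,dt,dr", [(0, 1.0, 1.0), (1, 3.0, 2.0), (2, 1.0, 1.0)])
    def test_matches_exhaustive_voting_oracle(self, seed, dt, dr):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(4, 24)), int(rng.integers(4, 24)))
        e = rng.random(shape) < 0.15
        acc = hough_transform(e, delta_theta_deg=dt, delta_rho_px=dr)
        np.testing.assert_array_equal(acc.votes, hough_oracle(e, dt, dr))

    def test_empty_edge_map_gives_zero_accumulator(self):
        acc = hough_transform(np.zeros((8, 8), dtype=bool))
        assert acc.total_votes == 0

    def test_bad_theta_resolution_rejected(self):
        with pytest.raises(ValidationError, match="180"):
            hough_transform(np.zeros((4, 4), dtype=bool), delta_theta_deg=7.0)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_vote_conservation_edge_pixels_times_theta_bins(self, seed):
        rng = np.random.default_rng(seed)
        e = rng.random((12, 12)) < 0.2
        acc = hough_transform(e)
        assert acc.total_votes == int(e.sum()) * acc.n_theta


class TestExtractLines:
    def test_single_nonzero_cell_returned(self):
        e = np.zeros((9, 9), dtype=bool)
        e[2, :] = True  # horizontal segment: theta=90 is out of range, peak at -90
        acc = hough_transform(e)
        lines = extract_lines(acc, n_peaks=1)
        assert len(lines) == 1
        assert abs(abs(lines[0].theta_deg) - 90.0) < 1.0
        assert abs(abs(lines[0].rho) - 2.0) < 1.0

    def test_two_separated_maxima_tie_broken_by_theta(self):
        acc = hough_transform(np.zeros((9, 9), dtype=bool))
        acc.votes[3, 10] = 5
        acc.votes[20, 100] = 5
        lines = extract_lines(acc, n_peaks=5)
        assert len(lines) == 2
        assert lines[0].theta_deg == acc.thetas_deg[10]  # lower theta bin first
        assert lines[1].theta_deg == acc.thetas_deg[100]

    def test_min_votes_frac_one_keeps_only_global_maxima(self):
        acc = hough_transform(np.zeros((9, 9), dtype=bool))
        acc.votes[3, 10] = 5
        acc.votes[20, 100] = 4
        lines = extract_lines(acc, n_peaks=10, min_votes_frac=1.0)
        assert [l.votes for l in lines] == [5]

    def test_all_zero_accumulator_gives_empty_list(self):
        acc = hough_transform(np.zeros((6, 6), dtype=bool))
        assert extract_lines(acc) == []


class TestAngularDistribution:
    def test_single_column_mass(self):
        acc = hough_transform(np.zeros((6, 6), dtype=bool))
        acc.votes[4, 37] = 3
        acc.votes[7, 37] = 2
        dist = angular_distribution(acc)
        assert dist.p[37] == pytest.approx(1.0)
        assert np.count_nonzero(dist.p) == 1

    def test_blank_roi_raises_no_fiber_signal(self):
        acc = hough_transform(np.zeros((6, 6), dtype=bool))
        with pytest.raises(NoFiberSignalError, match="no fiber signal"):
            angular_distribution(acc)

    def test_vertical_segment_argmax_at_theta_zero(self):
        e = np.zeros((11, 11), dtype=bool)
        e[:, 5] = True
        for column_stat in ("max", "energy"):
            dist = angular_distribution(hough_transform(e), column_stat=column_stat)
            j0 = int(np.argmin(np.abs(dist.thetas_deg)))
            assert dist.p[j0] == dist.p.max()
            # a vertical fiber reads 90 deg from horizontal
            assert dist.fiber_angles_deg[j0] == 90.0

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        e = rng.random((16, 16)) < 0.2
        dist = angular_distribution(hough_transform(e))
        assert dist.p.sum() == pytest.approx(1.0, abs=1e-9)


class TestShannonEntropy:
    def test_uniform_180_bins_reaches_log2_180(self):
        dist = AngularDistribution(
            p=np.full(180, 1 / 180), thetas_deg=np.arange(-90, 90, 1.0), q=1
        )
        assert shannon_entropy(dist).entropy_bits == pytest.approx(math.log2(180), abs=1e-9)

    def test_degenerate_distribution_has_zero_entropy(self):
        p = np.zeros(180)
        p[17] = 1.0
        dist = AngularDistribution(p=p, thetas_deg=np.arange(-90, 90, 1.0), q=1)
        assert shannon_entropy(dist).entropy_bits == 0.0

    def test_two_equal_outcomes_give_one_bit(self):
        p = np.zeros(180)
        p[[10, 20]] = 0.5
        dist = AngularDistribution(p=p, thetas_deg=np.arange(-90, 90, 1.0), q=1)
        assert shannon_entropy(dist).entropy_bits == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 180))
    def test_entropy_bounded_by_log2_n_bins(self, seed, n):
        rng = np.random.default_rng(seed)
        raw = rng.random(n) ** 3
        p = raw / raw.sum()
        dist = AngularDistribution(p=p / p.sum(), thetas_deg=np.linspace(-90, 89, n), q=1)
        h = shannon_entropy(dist).entropy_bits
        assert 0.0 <= h <= math.log2(n) + 1e-9


class TestPipeline:
    def test_same_image_twice_is_bit_identical(self):
        sec, ann, _ = generate_fiber_image(FiberFieldParams(seed=9, image_size=(96, 96), n_fibers=20))
        r1 = fiber_entropy_pipeline(sec, ann)
        r2 = fiber_entropy_pipeline(sec, ann)
        assert [r.entropy_bits for r in r1] == [r.entropy_bits for r in r2]
        assert r1[0].fiber_class == "oblique"

    def test_blank_roi_raises_no_fiber_signal(self, valid_metadata):
        px = np.zeros((48, 48, 3), dtype=np.uint8)
        px[...] = (40, 70, 110)
        sec = SectionImage(pixels=px, **valid_metadata)
        ann = make_annotations(width=48, height=48, rois=[full_field_roi(48, 48)])
        with pytest.raises(NoFiberSignalError):
            fiber_entropy_pipeline(sec, ann)

    def test_annotation_without_fiber_roi_rejected(self, uniform_section):
        ann = make_annotations()
        with pytest.raises(ValidationError, match="fiber class"):
            fiber_entropy_pipeline(uniform_section, ann)

    def test_concentrated_fibers_less_entropic_than_isotropic(self):
        h_conc, h_iso = [], []
        for seed in range(6):
            sec, ann, _ = generate_fiber_image(FiberFieldParams(seed=seed, concentration_kappa=64.0))
            h_conc.append(fiber_entropy_pipeline(sec, ann)[0].entropy_bits)
            sec, ann, _ = generate_fiber_image(FiberFieldParams(seed=seed, concentration_kappa=0.0))
            h_iso.append(fiber_entropy_pipeline(sec, ann)[0].entropy_bits)
        assert np.mean(h_conc) < np.mean(h_iso)

    def test_dominant_direction_peak_follows_mean_direction(self):
        # single rasters can throw up lattice-diagonal artifacts, so the
        # peak is read off the distribution averaged over a few fields
        ps = []
        for seed in range(6):
            sec, ann, _ = generate_fiber_image(
                FiberFieldParams(seed=seed, concentration_kappa=1e6, mean_direction_deg=30.0)
            )
            crop = crop_roi(extract_red_channel(sec), ann.rois[0])
            dist = angular_distribution(hough_transform(detect_edges(crop)))
            ps.append(dist.p)
        pbar = np.mean(ps, axis=0)
        peak = float(dist.fiber_angles_deg[int(np.argmax(pbar))])
        assert circular_distance_deg(peak, 30.0) <= 2.0
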