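"""Particle/vesicle projection, d/D ratios, block typing, randomization null."""

import numpy as np
import pytest
from scipy.stats import chisquare

from psdblocks.align import (
    build_randomization_null,
    classify_blocks,
    fraction_within_range,
    normalized_ratio,
    pair_points,
    point_in_hull,
    project_to_plane,
    psd_domain,
)
from psdblocks.blocks import build_nanoblocks
from psdblocks.errors import DegenerateBlockError, InputError
from psdblocks.stats import ks_2samp
from psdblocks.synthgen import SynthParams, generate_layout
from psdblocks.volio import MembranePlane

from .conftest import blocks_from_truth
from .test_blocks import cloud_of

VS = 1.32
PLANE = MembranePlane(point=[5.0, 50.0, -3.0], normal=[0.1, 0.98, 0.2] / np.linalg.norm([0.1, 0.98, 0.2]))


def rect_block():
    pix = [(u, w) for u in range(5) for w in range(3)]
    return build_nanoblocks(cloud_of(pix), np.zeros(15, int), voxel_size=VS)[0]


class TestProjection:
    def test_point_on_plane_unchanged(self):
        uw = project_to_plane(PLANE.point, PLANE)[0]
        np.testing.assert_allclose(uw, [0.0, 0.0], atol=1e-12)

    def test_normal_displacement_projects_to_foot_point(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            foot = PLANE.point + rng.normal(size=3)
            foot -= PLANE.normal * PLANE.signed_distance(foot)[0]
            displaced = foot + rng.normal() * 7.0 * PLANE.normal
            np.testing.assert_allclose(
                project_to_plane(displaced, PLANE)[0],
                project_to_plane(foot, PLANE)[0],
                atol=1e-9,
            )

    def test_idempotence_and_zero_residual(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(50, 3)) * 30
        uw = project_to_plane(pts, PLANE)
        u_axis, w_axis = PLANE.basis
        back = PLANE.point + uw[:, :1] * u_axis + uw[:, 1:] * w_axis
        assert np.max(np.abs(PLANE.signed_distance(back))) < 1e-9
        np.testing.assert_allclose(project_to_plane(back, PLANE), uw, atol=1e-9)


class TestRatio:
    def test_point_at_centroid_is_zero(self):
        b = rect_block()
        assert normalized_ratio(b.centroid, b).ratio == 0.0

    def test_point_at_farthest_hull_vertex_is_one(self):
        b = rect_block()
        far = max(b.hull, key=lambda v: np.linalg.norm(v - b.centroid))
        assert normalized_ratio(far, b).ratio == pytest.approx(1.0, abs=1e-12)

    def test_rectangle_hand_value_ratio_two(self):
        b = rect_block()
        direction = np.array([1.0, 0.0])
        point = b.centroid + 5.9032 * direction
        rec = normalized_ratio(point, b)
        assert rec.D == pytest.approx(2.9516, abs=1e-4)
        assert rec.ratio == pytest.approx(5.9032 / 2.9516, abs=1e-4)

    def test_degenerate_block_rejected(self):
        b = build_nanoblocks(cloud_of([(0, 0)]), np.zeros(1, int), VS)[0]
        with pytest.raises(DegenerateBlockError):
            normalized_ratio([1.0, 1.0], b)


class TestPairing:
    def test_single_point_single_block_same_in_both_modes(self):
        b = rect_block()
        p = b.centroid + [1.0, 0.5]
        r1 = pair_points([p], [b], mode="nearest_centroid")
        r2 = pair_points([p], [b], mode="all_pairs")
        assert len(r1) == len(r2) == 1
        assert r1[0].ratio == pytest.approx(r2[0].ratio)

    def test_all_pairs_cardinality(self):
        blocks = build_nanoblocks(
            cloud_of([(0, 0), (1, 0), (20, 0), (21, 0), (40, 0), (41, 0)]),
            np.array([0, 0, 1, 1, 2, 2]),
            VS,
        )
        recs = pair_points([[0.0, 0.0], [30.0, 0.0]], blocks, mode="all_pairs")
        assert len(recs) == 6

    def test_planted_assignment_recovered_with_separated_blocks(self):
        params = SynthParams(
            seed=23,
            volume_shape=(260, 80, 260),
            n_blocks=5,
            gap_mean=60.0,
            gap_sd=5.0,
            particle_spec={"particle_A": {"count": 30, "ratio_range": (0.0, 0.5)}},
        )
        truth = generate_layout(params)
        blocks = blocks_from_truth(truth)
        pts = np.array([[p["position"][0], p["position"][2]] for p in truth.particles])
        recs = pair_points(pts, blocks, mode="nearest_centroid")
        assigned = [r.block_id for r in recs]
        planted = [p["block_id"] for p in truth.particles]
        assert assigned == planted

    def test_no_eligible_blocks_warns_and_returns_empty(self):
        b = build_nanoblocks(cloud_of([(0, 0)]), np.zeros(1, int), VS)
        with pytest.warns(UserWarning):
            assert pair_points([[1.0, 1.0]], b) == []


class TestClassification:
    def test_single_a_particle_labels_a(self):
        b = rect_block()
        classify_blocks([b], [b.centroid], ["particle_A"])
        assert b.type_label == "A"

    def test_a_and_b_labels_mixed_and_outside_none(self):
        b = rect_block()
        classify_blocks(
            [b],
            [b.centroid, b.centroid + [0.1, 0.1], b.centroid + [500.0, 0.0]],
            ["particle_A", "particle_B", "particle_B"],
        )
        assert b.type_label == "mixed"
        classify_blocks([b], [b.centroid + [0.1, 0.1]], ["particle_B"])
        assert b.type_label == "B"
        classify_blocks([b], [b.centroid + [500.0, 0.0]], ["particle_B"])
        assert b.type_label == "none"  # far particle is outside the hull
        classify_blocks([b], [], [])
        assert b.type_label == "none"

    def test_particle_on_hull_vertex_counts_inside(self):
        b = rect_block()
        vertex = b.hull[0]
        classify_blocks([b], [vertex], ["particle_A"])
        assert b.type_label == "A"

    def test_point_in_hull_degenerate_segment(self):
        hull = np.array([[0.0, 0.0], [10.0, 0.0]])
        assert point_in_hull([5.0, 0.0], hull)
        assert not point_in_hull([5.0, 1.0], hull)

    def test_reproduces_planted_types_on_exact_hulls(self):
        """classify_blocks (cross-product test) vs the generator's shapely typing."""
        for seed in range(6):
            truth = generate_layout(SynthParams(seed=seed))
            blocks = blocks_from_truth(truth)
            pts = np.array(
                [
                    [p["position"][0], p["position"][2]]
                    for p in truth.particles
                    if p["kind"] in ("particle_A", "particle_B")
                ]
            )
            kinds = [
                p["kind"] for p in truth.particles if p["kind"] in ("particle_A", "particle_B")
            ]
            classify_blocks(blocks, pts, kinds)
            for det, planted in zip(blocks, truth.blocks):
                assert det.type_label == planted.planted_type, (seed, det.id)


class TestRandomizationNull:
    def test_single_pixel_domain_collapses(self):
        b = rect_block()
        domain = np.array([[3, 3]])
        null = build_randomization_null([[0.0, 0.0]], domain, [b], reps=5, seed=0, pixel_size=VS)
        assert null.ratios.shape == (5, 1)
        assert len(np.unique(null.ratios)) == 1

    def test_replicate_cardinality_is_reps_times_points(self):
        truth = generate_layout(SynthParams(seed=2))
        blocks = blocks_from_truth(truth)
        domain = psd_domain(blocks)
        pts = np.zeros((7, 2))
        null = build_randomization_null(pts, domain, blocks, reps=100, seed=1, pixel_size=VS)
        assert null.ratios.shape == (100, 7)
        assert null.pooled().size == 700

    def test_draws_uniform_over_domain_chi_square(self):
        rng_domain = np.random.default_rng(3)
        domain = np.unique(rng_domain.integers(0, 40, size=(80, 2)), axis=0)[:50]
        b = rect_block()
        null = build_randomization_null(
            np.zeros((100, 2)), domain, [b], reps=1000, seed=9, pixel_size=VS
        )
        pos = null.positions.reshape(-1, 2) / VS
        keys = pos[:, 0] * 1000 + pos[:, 1]
        uniq, counts = np.unique(keys, return_counts=True)
        assert len(uniq) == len(domain)
        assert chisquare(counts).pvalue > 0.001

    def test_determinism_given_seed(self):
        truth = generate_layout(SynthParams(seed=2))
        blocks = blocks_from_truth(truth)
        domain = psd_domain(blocks)
        n1 = build_randomization_null(np.zeros((5, 2)), domain, blocks, reps=10, seed=4, pixel_size=VS)
        n2 = build_randomization_null(np.zeros((5, 2)), domain, blocks, reps=10, seed=4, pixel_size=VS)
        np.testing.assert_array_equal(n1.ratios, n2.ratios)

    def test_empty_domain_is_error(self):
        with pytest.raises(InputError):
            build_randomization_null([[0.0, 0.0]], np.empty((0, 2)), [rect_block()], seed=0)

    def test_domain_modes(self):
        truth = generate_layout(SynthParams(seed=2))
        blocks = blocks_from_truth(truth)
        hull_px = psd_domain(blocks, "hull")
        cloud_px = psd_domain(blocks, "pixels")
        assert set(map(tuple, cloud_px)) <= set(map(tuple, hull_px))
        assert len(hull_px) > len(cloud_px)


class TestFractionWithinRange:
    def test_half_within(self):
        assert fraction_within_range(np.array([0.5, 1.5]))[0] == 0.5

    def test_boundary_is_strict(self):
        assert fraction_within_range(np.array([1.0, 1.0, 1.0]))[0] == 0.0

    def test_uniform_ratios_near_half_binomial_ci(self):
        rng = np.random.default_rng(6)
        ratios = rng.uniform(0, 2, size=1000)
        prop, n_in, n = fraction_within_range(ratios)
        assert abs(prop - 0.5) < 2.576 * 0.5 / np.sqrt(1000)

    def test_empty_is_error(self):
        with pytest.raises(InputError):
            fraction_within_range([])


class TestNullCalibrationAndSensitivity:
    def test_null_drawn_experimental_points_rarely_reject(self):
        """Quick 40-rep version of the calibration property (full in acceptance)."""
        truth = generate_layout(SynthParams(seed=77))
        blocks = blocks_from_truth(truth)
        domain = psd_domain(blocks)
        rej = 0
        for r in range(40):
            rng = np.random.default_rng(1000 + r)
            exp = domain[rng.integers(0, len(domain), 50)].astype(float) * VS
            exp_ratios = np.array([rec.ratio for rec in pair_points(exp, blocks)])
            null = build_randomization_null(exp, domain, blocks, reps=100, seed=2000 + r, pixel_size=VS)
            rej += ks_2samp(exp_ratios, null.pooled()).p_value <= 0.05
        assert rej <= 8  # ~5% expected; generous bound for 40 reps

    def test_separated_ratio_laws_detected(self):
        truth = generate_layout(SynthParams(seed=5))
        blocks = blocks_from_truth(truth)
        rng = np.random.default_rng(0)
        a_pts, b_pts = [], []
        for _ in range(150):
            blk = truth.blocks[rng.integers(len(truth.blocks))]
            th = rng.uniform(0, 2 * np.pi)
            a_pts.append(blk.centroid + rng.uniform(0, 0.8) * blk.D * np.array([np.cos(th), np.sin(th)]))
            th = rng.uniform(0, 2 * np.pi)
            b_pts.append(blk.centroid + rng.uniform(0.8, 1.6) * blk.D * np.array([np.cos(th), np.sin(th)]))
        ra = np.array([r.ratio for r in pair_points(np.array(a_pts), blocks)])
        rb = np.array([r.ratio for r in pair_points(np.array(b_pts), blocks)])
        assert ks_2samp(ra, rb).p_value < 0.01
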