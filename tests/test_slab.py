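"""Slab projection, background estimation, thresholding, profiles, peak fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psdblocks.errors import BoundsError, EmptySlabError
from psdblocks.slab import (
    DensityProfile,
    SlabProjection,
    estimate_background,
    extract_slab_projection,
    fit_profile_peaks,
    profile_1d,
    threshold_projection,
)
from psdblocks.synthgen import (
    GroundTruth,
    PlantedBlock,
    SynthParams,
    _footprint_pixels,
    render_volume,
)
from psdblocks.volio import MembranePlane, VolumeGrid

PLANE_Y55 = MembranePlane(point=[0.0, 55.0, 0.0], normal=[0.0, 1.0, 0.0])


def cylinder_phantom(depth_nm: float, width: float = 30.0, sigma: float = 0.0) -> tuple:
    p = SynthParams(
        n_blocks=0,
        noise_sigma=sigma,
        seed=0,
        volume_shape=(60, 80, 60),
        block_profile="cylinder",
    )
    center = np.array([40.0, 40.0])
    pix = _footprint_pixels(center, width, 1.0, depth_nm, p)
    block = PlantedBlock(id=0, center=center, width=width, depth=depth_nm, aspect=1.0, pixels=pix)
    truth = GroundTruth(blocks=[block], particles=[], vesicles=[], params=p)
    return p, truth, render_volume(truth, p)


class TestProjection:
    def test_constant_volume_projects_to_constant(self):
        vol = VolumeGrid(np.full((20, 60, 20), 5.0, np.float32), voxel_size=1.32)
        proj = extract_slab_projection(vol, PLANE_Y55, depth=20.0)
        assert np.nanmax(proj.values) == pytest.approx(5.0)
        assert np.nanmin(proj.values) == pytest.approx(5.0)

    def test_full_depth_cylinder_block_gives_full_contrast(self):
        p, truth, vol = cylinder_phantom(depth_nm=40.0)
        proj = extract_slab_projection(vol, PLANE_Y55, depth=40.0)
        vals = proj.value_at(truth.blocks[0].pixels)
        np.testing.assert_allclose(vals, p.block_contrast, atol=1e-6)

    def test_half_depth_block_gives_half_column_mean(self):
        """20 of 40 nm filled -> exactly half the contrast (15/30 voxels)."""
        p, truth, vol = cylinder_phantom(depth_nm=20.0)
        proj = extract_slab_projection(vol, PLANE_Y55, depth=40.0)
        vals = proj.value_at(truth.blocks[0].pixels)
        np.testing.assert_allclose(vals, p.block_contrast / 2.0, atol=1e-6)
        # brute-force per-column averaging oracle on one pixel
        a, b = truth.blocks[0].pixels[0]
        y = np.arange(80) * 1.32
        col = vol.data[a, (y > 55.0) & (y <= 95.0), b]
        assert vals[0] == pytest.approx(col.mean())

    def test_membrane_voxels_are_excluded(self):
        p = SynthParams(n_blocks=0, noise_sigma=0.0, seed=0, volume_shape=(30, 70, 30))
        vol = render_volume(GroundTruth([], [], [], p), p)
        proj = extract_slab_projection(vol, PLANE_Y55, depth=40.0)
        # the dark membrane band sits at distance <= 0, so the slab is clean
        np.testing.assert_allclose(proj.values[~proj.mask], p.background_gray, atol=1e-9)

    def test_slab_outside_volume_raises(self):
        vol = VolumeGrid(np.zeros((10, 10, 10), np.float32), voxel_size=1.0)
        plane = MembranePlane(point=[0.0, 100.0, 0.0], normal=[0.0, 1.0, 0.0])
        with pytest.raises(EmptySlabError):
            extract_slab_projection(vol, plane, depth=5.0)

    def test_projection_linearity(self):
        rng = np.random.default_rng(2)
        d1 = rng.normal(size=(20, 60, 20)).astype(np.float32)
        d2 = rng.normal(size=(20, 60, 20)).astype(np.float32)
        p1 = extract_slab_projection(VolumeGrid(d1, 1.32), PLANE_Y55, 20.0)
        p2 = extract_slab_projection(VolumeGrid(d2, 1.32), PLANE_Y55, 20.0)
        p12 = extract_slab_projection(VolumeGrid(d1 + d2, 1.32), PLANE_Y55, 20.0)
        good = ~p12.mask
        np.testing.assert_allclose(p12.values[good], (p1.values + p2.values)[good], atol=1e-5)

    def test_integer_translation_equivariance(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(16, 60, 16)).astype(np.float32)
        vol = VolumeGrid(data, 1.32)
        proj = extract_slab_projection(vol, PLANE_Y55, 20.0)
        shift = np.array([3 * 1.32, 0.0, 5 * 1.32])
        vol2 = VolumeGrid(data, 1.32, origin=shift)
        plane2 = MembranePlane(point=np.array([0.0, 55.0, 0.0]) + shift, normal=[0, 1, 0])
        proj2 = extract_slab_projection(vol2, plane2, 20.0)
        np.testing.assert_allclose(proj2.values, proj.values, atol=1e-6)


class TestBackground:
    def test_constant_field(self):
        vol = VolumeGrid(np.full((10, 10, 10), 5.0, np.float32), voxel_size=1.0)
        assert estimate_background(vol, ([0, 0, 0], [9, 9, 9])) == pytest.approx(5.0)

    def test_two_value_box_mean(self):
        data = np.zeros((2, 1, 1), np.float32)
        data[0], data[1] = 4.0, 6.0
        vol = VolumeGrid(data, voxel_size=1.0)
        with pytest.warns(UserWarning, match="noisy"):
            assert estimate_background(vol, ([0, 0, 0], [1, 0, 0])) == pytest.approx(5.0)

    def test_noisy_estimate_within_standard_error_bound(self):
        rng = np.random.default_rng(8)
        vol = VolumeGrid(rng.normal(0, 2.0, size=(25, 20, 20)).astype(np.float32), voxel_size=1.0)
        est = estimate_background(vol, ([0, 0, 0], [24, 19, 19]))
        assert abs(est) < 3 * 2.0 / np.sqrt(10_000)

    def test_box_outside_volume(self):
        vol = VolumeGrid(np.zeros((5, 5, 5), np.float32), voxel_size=1.0)
        with pytest.raises(BoundsError):
            estimate_background(vol, ([50, 50, 50], [60, 60, 60]))


def make_projection(values: np.ndarray) -> SlabProjection:
    values = np.asarray(values, dtype=float)
    return SlabProjection(
        values=values,
        column_counts=np.ones_like(values, dtype=int),
        pixel_size=1.32,
        depth=40.0,
        membrane=PLANE_Y55,
        index_origin=(0, 0),
    )


class TestThreshold:
    def test_hand_enumerated_selection(self):
        """(-4,-3,-1,2), b=0, f=0.5 -> candidates 3, floor(1.5)=1 darkest."""
        proj = make_projection(np.array([[-4.0], [-3.0], [-1.0], [2.0]]))
        cloud = threshold_projection(proj, background=0.0, fraction=0.5)
        assert len(cloud) == 1
        np.testing.assert_array_equal(cloud.pixels, [[0, 0]])
        assert cloud.values[0] == -4.0

    def test_full_fraction_takes_all_below_background(self):
        proj = make_projection(np.array([[-4.0], [-3.0], [-1.0], [2.0]]))
        cloud = threshold_projection(proj, 0.0, 1.0)
        assert len(cloud) == 3

    def test_all_at_background_yields_empty_cloud(self):
        proj = make_projection(np.zeros((4, 4)))
        cloud = threshold_projection(proj, 0.0, 0.25)
        assert len(cloud) == 0 and cloud.empty_reason is not None

    def test_value_ties_broken_lexicographically(self):
        proj = make_projection(np.array([[-1.0, -1.0], [-1.0, 5.0]]))
        cloud = threshold_projection(proj, 0.0, 0.67)  # floor(0.67*3) = 2 of 3
        np.testing.assert_array_equal(cloud.pixels, [[0, 0], [0, 1]])

    def test_global_fraction_mode_ignores_background(self):
        proj = make_projection(np.array([[-4.0], [-3.0], [-1.0], [2.0]]))
        cloud = threshold_projection(proj, float("nan"), 0.5, mode="global_fraction")
        assert len(cloud) == 2  # floor(0.5 * 4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.tuples(st.floats(0.05, 0.95), st.floats(0.05, 0.95)),
    )
    def test_monotone_nesting_in_fraction(self, seed, fracs):
        """PixelCloud(f1) is a subset of PixelCloud(f2) whenever f1 <= f2."""
        f1, f2 = sorted(fracs)
        rng = np.random.default_rng(seed)
        proj = make_projection(rng.normal(size=(12, 9)))
        c1 = threshold_projection(proj, 0.0, f1)
        c2 = threshold_projection(proj, 0.0, f2)
        set1 = set(map(tuple, c1.pixels))
        set2 = set(map(tuple, c2.pixels))
        assert set1 <= set2


class TestProfiles:
    def test_constant_field_gives_flat_profile(self):
        proj = make_projection(np.full((20, 10), 3.0))
        prof = profile_1d(proj)
        np.testing.assert_allclose(prof.values, 3.0)
        assert len(prof.positions) == 20

    def test_single_pixel_band_equals_raw_values(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(15, 6))
        proj = make_projection(vals)
        prof = profile_1d(proj, w_range=(1.32 * 2, 1.32 * 2))
        np.testing.assert_allclose(prof.values, vals[:, 2])

    def test_planted_minima_recovered(self):
        """Five equally spaced dark dips -> five local minima at the planted u."""
        nu = 100
        vals = np.zeros((nu, 8))
        centers = [10, 28, 46, 64, 82]
        u = np.arange(nu)
        for c in centers:
            vals -= 8.0 * np.exp(-0.5 * ((u[:, None] - c) / 3.0) ** 2)
        proj = make_projection(vals)
        prof = profile_1d(proj)
        # brute-force local-minima scan
        v = prof.values
        minima = [i for i in range(1, nu - 1) if v[i] < v[i - 1] and v[i] <= v[i + 1]]
        assert len(minima) == 5
        for found, planted in zip(minima, centers):
            assert abs(found - planted) <= 1

    def test_empty_region_is_bounds_error(self):
        proj = make_projection(np.zeros((10, 10)))
        with pytest.raises(BoundsError):
            profile_1d(proj, u_range=(1e4, 2e4))


class TestPeakFit:
    def test_single_gaussian_dip_recovered(self):
        x = np.arange(0, 100, 1.32)
        y = -6.0 * np.exp(-0.5 * ((x - 50.0) / 8.0) ** 2)
        prof = fit_profile_peaks(DensityProfile(x, y), max_components=4)
        assert len(prof.fitted_peaks) == 1
        center, sd, amp = prof.fitted_peaks[0]
        assert center == pytest.approx(50.0, abs=0.5)
        assert sd == pytest.approx(8.0, rel=0.10)

    def test_flat_profile_prefers_zero_components(self):
        x = np.arange(0, 50, 1.0)
        prof = fit_profile_peaks(DensityProfile(x, np.full_like(x, 2.0)), max_components=3)
        assert prof.fitted_peaks == []

    def test_two_separated_dips_both_recovered(self):
        x = np.arange(0, 120, 1.0)
        y = -5.0 * np.exp(-0.5 * ((x - 30.0) / 5.0) ** 2) - 3.0 * np.exp(
            -0.5 * ((x - 85.0) / 7.0) ** 2
        )
        prof = fit_profile_peaks(DensityProfile(x, y), max_components=4)
        assert len(prof.fitted_peaks) == 2
        centers = [p[0] for p in prof.fitted_peaks]
        assert centers[0] == pytest.approx(30.0, abs=1.0)
        assert centers[1] == pytest.approx(85.0, abs=1.0)
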