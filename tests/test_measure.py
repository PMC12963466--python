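"""Measurement algorithm: ROI fitting, thresholding, Feret, full protocol."""

import itertools

import numpy as np
import pytest

from stonewin import (
    PhantomSpec,
    RoiCircle,
    WindowSetting,
    half_value_max_semiauto,
    max_feret_diameter,
    measure_stone,
    render_phantom,
)
from stonewin.errors import EmptyRoiError, NotAStoneError
from stonewin.measure import (
    Measurement,
    circle_stats,
    fit_enclosing_roi,
    fit_inner_roi,
    threshold_mask,
)
from stonewin.phantom import Slab


def make_slab(data, spacing=(1.0, 1.0), origin=(0.0, 0.0)):
    return Slab(np.asarray(data, dtype=float), spacing, origin, "axial", 0, (0, 1))


def disk_slab(radius_px, n=41, inside=800.0, outside=0.0, spacing=1.0):
    c = (n - 1) / 2
    i, j = np.mgrid[0:n, 0:n]
    data = np.where((i - c) ** 2 + (j - c) ** 2 <= radius_px**2, inside, outside)
    return make_slab(data, (spacing, spacing))


def brute_feret(mask, spacing):
    """Independent oracle: exhaustive all-pairs over boundary pixel centers."""
    from scipy import ndimage

    inner = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(2, 1))
    pts = np.argwhere(mask & ~inner).astype(float) * np.asarray(spacing)
    if len(pts) < 2:
        return 0.0
    return max(
        float(np.hypot(*(p - q)))
        for p, q in itertools.combinations(pts, 2)
    )


class TestCircleStats:
    def test_uniform_slab(self):
        slab = make_slab(np.full((20, 20), 55.0))
        roi = RoiCircle("axial", 0, (10.0, 10.0), 4.2)
        mean, mx, n = circle_stats(slab, roi)
        assert (mean, mx) == (55.0, 55.0)
        assert n > 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        slab = make_slab(rng.normal(100, 50, (30, 30)), (0.7, 0.5))
        roi = RoiCircle("axial", 0, (9.1, 7.3), 4.0)
        mean, mx, n = circle_stats(slab, roi)
        # oracle: explicit loop over every pixel center
        vals = [
            slab.data[i, j]
            for i in range(30)
            for j in range(30)
            if (i * 0.7 - 9.1) ** 2 + (j * 0.5 - 7.3) ** 2 < 16.0
        ]
        assert n == len(vals)
        assert mean == pytest.approx(np.mean(vals))
        assert mx == pytest.approx(np.max(vals))

    def test_empty_circle_raises(self):
        slab = make_slab(np.zeros((10, 10)))
        with pytest.raises(EmptyRoiError):
            circle_stats(slab, RoiCircle("axial", 0, (3.5, 3.5), 0.4))

    def test_enclosing_max_is_global_max_of_stone(self, sphere_volume, sphere_seed_point):
        vol, _ = sphere_volume
        from stonewin.phantom import mpr_slab

        slab = mpr_slab(vol, "axial", 3.0, 2)
        roi = fit_enclosing_roi(slab, sphere_seed_point[:2])
        _, mx, _ = circle_stats(slab, roi)
        assert mx == pytest.approx(slab.data.max())


class TestRoiFitting:
    def test_inner_circle_matches_brute_force_inscribed(self):
        slab = disk_slab(radius_px=10)
        roi = fit_inner_roi(slab, (20, 20))
        # oracle: largest centroid-centered circle with every interior pixel
        # supra-threshold, by radius scan
        comp = slab.data >= 250.0
        c = np.array([20.0, 20.0])
        best = 0.0
        for r in np.arange(0.5, 15, 0.05):
            i, j = np.mgrid[0:41, 0:41]
            inside = (i - c[0]) ** 2 + (j - c[1]) ** 2 < r**2
            if np.all(comp[inside]):
                best = r
        assert roi.center == pytest.approx((20.0, 20.0))
        assert abs(roi.radius - (best - 1.0)) <= 1.0  # one-pixel erosion margin

    def test_enclosing_circle_matches_brute_force(self):
        slab = disk_slab(radius_px=8)
        roi = fit_enclosing_roi(slab, (20, 20))
        comp = np.argwhere(slab.data >= 250.0).astype(float)
        d_max = np.sqrt(((comp - [20.0, 20.0]) ** 2).sum(axis=1)).max()
        assert roi.radius == pytest.approx(d_max + 1.0)
        inside = _all_component_pixels_inside(slab, roi)
        assert inside

    def test_enclosing_max_geq_inner_max(self):
        rng = np.random.default_rng(3)
        data = np.zeros((41, 41))
        data[14:27, 14:27] = 800 + rng.normal(0, 30, (13, 13))
        slab = make_slab(data)
        inner = fit_inner_roi(slab, (20, 20))
        outer = fit_enclosing_roi(slab, (20, 20))
        assert circle_stats(slab, outer)[1] >= circle_stats(slab, inner)[1]

    def test_tiny_object_falls_back_to_brightest_pixel(self):
        data = np.zeros((15, 15))
        data[7, 7] = 700.0
        data[7, 8] = 650.0
        slab = make_slab(data)
        roi = fit_inner_roi(slab, (7, 7))
        assert roi.center == (7.0, 7.0)
        _, mx, n = circle_stats(slab, roi)
        assert (mx, n) == (700.0, 1)
        outer = fit_enclosing_roi(slab, (7, 7))
        assert circle_stats(slab, outer)[1] == 700.0

    def test_seed_in_background_raises(self):
        slab = disk_slab(radius_px=5)
        with pytest.raises(NotAStoneError):
            fit_inner_roi(slab, (2, 2))


def _all_component_pixels_inside(slab, roi):
    comp = np.argwhere(slab.data >= 250.0).astype(float)
    d = np.sqrt(((comp - np.asarray(roi.center)) ** 2).sum(axis=1))
    return bool((d < roi.radius).all())


class TestThresholdMask:
    def test_center_above_max_gives_empty_mask(self):
        slab = disk_slab(radius_px=5)
        mask = threshold_mask(slab, WindowSetting(900.0, 0.0))
        assert not mask.any()

    def test_center_below_min_gives_full_component(self):
        slab = disk_slab(radius_px=5)
        mask = threshold_mask(slab, WindowSetting(-100.0, 0.0), (20, 20))
        assert mask.all()

    def test_half_max_area_matches_circle(self, sphere_volume, sphere_seed_point):
        """Thresholding a blurred 6 mm sphere slab at half max yields
        approximately the true pi*3^2 cross-section."""
        vol, _ = sphere_volume
        from stonewin.phantom import mpr_slab

        slab = mpr_slab(vol, "axial", 0.2, 35)  # thin slice through the equator
        mask = threshold_mask(slab, WindowSetting(400.0, 0.0), sphere_seed_point[:2])
        area = mask.sum() * 0.2 * 0.2
        assert area == pytest.approx(np.pi * 9.0, rel=0.05)

    def test_other_components_discarded(self):
        data = np.zeros((30, 30))
        data[5:8, 5:8] = 800.0
        data[20:26, 20:26] = 800.0
        slab = make_slab(data)
        mask = threshold_mask(slab, WindowSetting(400.0, 0.0), (6, 6))
        assert mask[6, 6] and not mask[22, 22]
        assert mask.sum() == 9


class TestFeret:
    def test_two_pixel_distance(self):
        mask = np.zeros((12, 20), dtype=bool)
        mask[5, 4] = mask[5, 14] = True
        assert max_feret_diameter(mask, (0.5, 0.5)) == pytest.approx(5.0)

    def test_single_pixel_is_zero(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert max_feret_diameter(mask, (1.0, 1.0)) == 0.0
        assert max_feret_diameter(np.zeros((5, 5), dtype=bool), (1.0, 1.0)) == 0.0

    def test_disk_diameter(self):
        slab = disk_slab(radius_px=12, spacing=0.25)
        mask = slab.data >= 400
        d = max_feret_diameter(mask, (0.25, 0.25))
        assert d == pytest.approx(2 * 12 * 0.25, abs=0.25 * np.sqrt(2))

    def test_rotation_robustness(self):
        """A rasterized ellipse rotated 30 deg keeps its Feret within one
        pixel diagonal."""
        i, j = np.mgrid[0:60, 0:60]
        th = np.deg2rad(30)
        x, y = i - 30.0, j - 30.0
        u = x * np.cos(th) + y * np.sin(th)
        v = -x * np.sin(th) + y * np.cos(th)
        ell_rot = (u / 20) ** 2 + (v / 8) ** 2 <= 1
        ell = (x / 20) ** 2 + (y / 8) ** 2 <= 1
        d0 = max_feret_diameter(ell, (1.0, 1.0))
        d1 = max_feret_diameter(ell_rot, (1.0, 1.0))
        assert abs(d0 - d1) <= np.sqrt(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_all_pairs(self, seed):
        """Convex-hull implementation equals the all-pairs oracle on random
        masks up to 40x40 (anisotropic spacing included)."""
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        mask = rng.random((n, n)) > 0.6
        spacing = tuple(rng.uniform(0.2, 1.5, size=2))
        assert max_feret_diameter(mask, spacing) == pytest.approx(
            brute_feret(mask, spacing)
        )


class TestMeasureStone:
    def test_half_value_max_recovers_sphere(self, sphere_volume, sphere_seed_point):
        """Half-value MAX on a thin-slice protocol recovers the 6 mm sphere
        within 0.2 mm; low thresholds overestimate (blooming) and
        near-peak thresholds underestimate."""
        vol, _ = sphere_volume
        m = measure_stone(vol, sphere_seed_point, "half_value_max", slab_thickness=0.2)
        assert m.largest_diameter == pytest.approx(6.0, abs=0.2)
        # soft-tissue window read at its lower level: blooming overestimate
        m_low = measure_stone(vol, sphere_seed_point, "soft_tissue",
                              edge_fraction=0.0, slab_thickness=0.2)
        assert m_low.largest_diameter > 6.0
        # bone window read near the stone's peak (700 HU): underestimate
        frac = (700.0 + 260.0) / 1120.0
        m_high = measure_stone(vol, sphere_seed_point, "bone",
                               edge_fraction=frac, slab_thickness=0.2)
        assert 0 < m_high.largest_diameter < 6.0

    def test_threshold_monotonicity(self, sphere_volume, sphere_seed_point):
        """Raising the zero-width threshold never increases the Feret size."""
        vol, _ = sphere_volume
        from stonewin.phantom import mpr_slab

        slab = mpr_slab(vol, "axial", 3.0, 2)
        sizes = []
        for thr in np.linspace(100, 750, 14):
            mask = threshold_mask(slab, WindowSetting(thr, 0.0), sphere_seed_point[:2])
            sizes.append(max_feret_diameter(mask, slab.spacing))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    @pytest.mark.parametrize("fwhm", [0.4, 0.8, 1.2])
    def test_window_size_ordering(self, fwhm):
        """Soft-tissue >= half-value MEAN >= half-value MAX measured size on
        noiseless phantoms, for a grid of PSF widths."""
        spec = PhantomSpec(
            semi_axes=(3.0, 2.6, 2.8), center=(8.0, 8.0, 8.0), stone_hu=800.0,
            psf_fwhm=fwhm, voxel_spacing=(0.4, 0.4, 0.4), volume_shape=(41, 41, 41),
        )
        vol, _ = render_phantom(spec)
        seed = (20, 20, 20)
        d = {
            mode: measure_stone(vol, seed, mode).largest_diameter
            for mode in ("soft_tissue", "half_value_mean", "half_value_max")
        }
        assert d["soft_tissue"] >= d["half_value_mean"] >= d["half_value_max"] > 0

    def test_largest_is_max_over_planes(self, coarse_sphere_volume):
        _, vol, _ = coarse_sphere_volume
        m = measure_stone(vol, (16, 16, 16), "half_value_max")
        assert m.largest_diameter == max(m.per_plane_diameter)
        assert m.plane_of_largest in ("axial", "coronal", "sagittal")

    def test_invalid_measurement_rejected(self):
        with pytest.raises(ValueError):
            Measurement("s", "o", "w", (1.0, 2.0, 3.0), 2.5, 100.0, 200.0, "axial")
        with pytest.raises(ValueError):
            Measurement("s", "o", "w", (1.0, 2.0, 3.0), 3.0, 300.0, 200.0, "axial")

    def test_semiauto_deterministic_and_seed_invariant(self, coarse_sphere_volume):
        """Identical repeat calls, and any seed inside the same connected
        component, give identical measurements."""
        _, vol, _ = coarse_sphere_volume
        m1 = half_value_max_semiauto(vol, (16, 16, 16))
        m2 = half_value_max_semiauto(vol, (16, 16, 16))
        assert m1 == m2
        m3 = half_value_max_semiauto(vol, (18, 15, 16))  # off-center, still inside
        assert m3.largest_diameter == m1.largest_diameter

    def test_seed_in_background_raises(self, coarse_sphere_volume):
        _, vol, _ = coarse_sphere_volume
        with pytest.raises(NotAStoneError):
            half_value_max_semiauto(vol, (2, 2, 2))
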