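"""Half-contour splitting and the six contour-shape parameters."""

import numpy as np
import pytest

from halfcontour.features import (
    AngleSeries,
    close_and_measure,
    feature_vector,
    nrl_features,
    radial_profile,
    sdd,
    split_half_contour,
    tumor_circularity,
    vertex_angles,
)
from halfcontour.phantom import EchoSpec, ShapeSpec, make_shape_mask, render_phantom
from halfcontour.segmentation import segment
from tests.conftest import contour_of


class TestSplitHalfContour:
    def test_circle_splits_into_symmetric_halves(self, disk_contour):
        h = split_half_contour(disk_contour)
        n = len(disk_contour.points)
        assert abs(len(h.arc) - n / 2) <= 0.1 * n
        assert abs(h.p_left[1] - 128) <= 1 and abs(h.p_right[1] - 128) <= 1

    def test_upper_arc_is_returned(self, disk_contour):
        h = split_half_contour(disk_contour)
        assert h.arc[:, 1].mean() < 128  # above the center row
        assert tuple(h.arc[0]) == h.p_left and tuple(h.arc[-1]) == h.p_right

    def test_exclusion_moves_left_endpoint_to_boundary(self, disk_contour):
        xs = disk_contour.points[:, 0]
        cutoff = xs.min() + 20
        h = split_half_contour(disk_contour, exclusion=(0, cutoff))
        assert h.p_left[0] == cutoff + 1  # first non-excluded column on the contour

    def test_full_exclusion_raises(self, disk_contour):
        with pytest.raises(ValueError, match="exclusion"):
            split_half_contour(disk_contour, exclusion=(0, 256))


class TestCloseAndMeasure:
    def test_4x4_square(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:6, 2:6] = 1
        m = close_and_measure(contour_of(mask))
        assert (m.perimeter_px, m.area_px) == (12, 16)

    def test_disk_area_close_to_analytic(self):
        spec = ShapeSpec(base_radius_px=20.0, center=(32.0, 32.0), rng_seed=0)
        m = close_and_measure(contour_of(make_shape_mask(spec, (64, 64))))
        assert m.area_px == pytest.approx(np.pi * 400, rel=0.03)

    def test_star_area_equals_flood_fill_oracle(self, star_mask, star_contour):
        from scipy import ndimage as ndi

        m = close_and_measure(star_contour)
        # oracle: flood the outside from the border, count the complement
        boundary = np.zeros_like(star_mask, dtype=bool)
        boundary[star_contour.points[:, 1], star_contour.points[:, 0]] = True
        outside = np.ones_like(boundary)
        outside &= ~boundary
        labels, _ = ndi.label(outside, structure=ndi.generate_binary_structure(2, 1))
        border_labels = set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(labels[:, -1])
        border_labels.discard(0)
        enclosed = (labels > 0) & ~np.isin(labels, list(border_labels))
        assert m.area_px == int(enclosed.sum() + boundary.sum())

    def test_half_contour_measures_chord_closed_region(self, disk_contour):
        h = split_half_contour(disk_contour)
        m = close_and_measure(h)
        full = close_and_measure(disk_contour)
        assert m.area_px < full.area_px
        assert m.area_px == pytest.approx(full.area_px / 2, rel=0.1)


class TestTumorCircularity:
    def test_hand_values(self):
        from halfcontour.features import ClosedRegionMetrics

        assert tumor_circularity(ClosedRegionMetrics(16, 16)) == pytest.approx(16.0)
        assert tumor_circularity(ClosedRegionMetrics(40, 100)) == pytest.approx(16.0)

    def test_disk_below_star_at_equal_area(self, disk_contour, star_contour):
        tc_disk = tumor_circularity(close_and_measure(disk_contour))
        tc_star = tumor_circularity(close_and_measure(star_contour))
        assert tc_disk < tc_star


class TestRadialProfile:
    def test_circle_profile_is_nearly_constant(self, disk_contour):
        p = radial_profile(disk_contour)
        assert p.d_hat.max() == 1.0
        assert p.d_hat.min() >= 0.9

    def test_hand_normalization(self):
        d = np.array([3.0, 4.0, 5.0])
        assert np.allclose(d / d.max(), [0.6, 0.8, 1.0])

    def test_max_is_exactly_one(self, star_contour):
        p = radial_profile(star_contour)
        assert p.d_hat.max() == 1.0
        assert (p.d_hat > 0).all()


class TestNrlFeatures:
    def test_hand_arithmetic_full_mode(self):
        nrl_m, nrl_std, ar, ri = nrl_features(np.array([0.6, 0.8, 1.0]), closed=True)
        assert nrl_m == pytest.approx(0.8)
        assert nrl_std == pytest.approx(0.2)
        assert ar == pytest.approx(0.2 / (0.8 * 3))
        assert ri == pytest.approx((0.2 + 0.2 + 0.4) / 3)

    def test_constant_profile_degenerates(self):
        assert nrl_features(np.ones(10)) == pytest.approx((1.0, 0.0, 0.0, 0.0))

    def test_matches_naive_loop_oracle(self, rng):
        d = rng.uniform(0.3, 1.0, size=200)
        d[rng.integers(0, 200)] = 1.0
        nrl_m, nrl_std, ar, ri = nrl_features(d, closed=True)
        n = len(d)
        mean = sum(d) / n
        std = (sum((x - mean) ** 2 for x in d) / (n - 1)) ** 0.5
        ar_o = sum((x - mean) for x in d if x > mean) / (mean * n)
        ri_o = sum(abs(d[i] - d[(i + 1) % n]) for i in range(n)) / n
        assert nrl_m == pytest.approx(mean, abs=1e-12)
        assert nrl_std == pytest.approx(std, abs=1e-12)
        assert ar == pytest.approx(ar_o, abs=1e-12)
        assert ri == pytest.approx(ri_o, abs=1e-12)

    def test_open_arc_roughness_normalizes_by_gaps(self):
        d = np.array([1.0, 0.5, 1.0, 0.5])
        *_, ri = nrl_features(d, closed=False)
        assert ri == pytest.approx(1.5 / 3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            nrl_features(np.array([1.0, 0.9]))


class TestVertexAngles:
    def test_equilateral_triangle_all_sixty(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        theta = vertex_angles(pts, k=1, closed=True).theta
        assert np.allclose(theta, 60.0)

    def test_collinear_points_are_straight(self):
        pts = np.array([[float(i), 0.0] for i in range(7)])
        theta = vertex_angles(pts, k=2, closed=False).theta
        assert np.allclose(theta, 180.0)

    def test_circle_mean_angle_matches_inscribed_angle(self, disk_contour):
        k = 5
        n = len(disk_contour.points)
        theta = vertex_angles(disk_contour.points, k=k, closed=True).theta
        analytic = 180.0 - k / n * 360.0
        assert abs(theta.mean() - analytic) < 5.0

    def test_open_mode_skips_ends(self):
        pts = np.array([[float(i), float(i % 2)] for i in range(20)])
        series = vertex_angles(pts, k=3, closed=False)
        assert len(series.theta) == 20 - 6

    def test_coincident_points_skipped_with_warning(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [2.0, 1.0], [3.0, 0.0]])
        with pytest.warns(UserWarning):
            series = vertex_angles(pts, k=1, closed=True)
        assert np.isfinite(series.theta).all()


class TestSdd:
    def test_equal_angles_zero(self):
        assert sdd(np.full(10, 123.4)) == pytest.approx(0.0, abs=1e-6)

    def test_two_values(self):
        assert sdd(np.array([60.0, 90.0])) == pytest.approx(15.0)

    def test_matches_two_pass_oracle(self, rng):
        theta = rng.uniform(0, 180, size=500)
        mean = sum(theta) / len(theta)
        oracle = (sum((t - mean) ** 2 for t in theta) / len(theta)) ** 0.5
        assert sdd(theta) == pytest.approx(oracle, abs=1e-12)

    def test_single_angle_rejected(self):
        with pytest.raises(ValueError):
            sdd(np.array([90.0]))


class TestFeatureVector:
    def test_smooth_disk_is_regular(self, disk_contour):
        fv = feature_vector(disk_contour, mode="full")
        assert fv.sdd < 10.0
        assert fv.nrl_std < 0.05
        assert fv.ar < 0.02

    @pytest.mark.parametrize("k", [3, 5, 9])
    def test_star_exceeds_disk_in_every_irregularity_measure(
        self, disk_contour, star_contour, k
    ):
        fv_d = feature_vector(disk_contour, mode="full", k=k)
        fv_s = feature_vector(star_contour, mode="full", k=k)
        for name in ("tc", "nrl_std", "ar", "ri", "sdd"):
            assert getattr(fv_s, name) > getattr(fv_d, name), name

    def test_half_tc_consistent_with_symmetric_split(self):
        """For an up-down symmetric lesion the chord-closed half contour has
        half the area and half the arc plus the chord, so its circularity is
        predictable from the full-contour measurements."""
        spec = ShapeSpec(base_radius_px=40.0, center=(128.0, 120.0), rng_seed=3)
        mask = make_shape_mask(spec, (256, 256))
        img = render_phantom(mask, EchoSpec(), rng_seed=3)
        _, contour = segment(img, seed=(128, 120))
        full = close_and_measure(contour)
        h = split_half_contour(contour)
        chord_len = len(h.chord)
        predicted = (0.5 * full.perimeter_px + chord_len) ** 2 / (0.5 * full.area_px)
        tc_half = feature_vector(contour, "half").tc
        assert tc_half == pytest.approx(predicted, rel=0.15)

    def test_translation_invariance_exact(self, star_mask):
        big = np.zeros((320, 320), dtype=np.uint8)
        big[: star_mask.shape[0], : star_mask.shape[1]] = star_mask
        moved = np.roll(np.roll(big, 37, axis=0), 21, axis=1)
        fv_a = feature_vector(contour_of(big), mode="full")
        fv_b = feature_vector(contour_of(moved), mode="full")
        for name in ("tc", "nrl_m", "nrl_std", "ar", "ri", "sdd"):
            assert getattr(fv_a, name) == pytest.approx(getattr(fv_b, name), abs=1e-9)

    def test_scale_invariance_within_ten_percent(self):
        vals = {}
        for r in (30.0, 60.0):
            spec = ShapeSpec(
                base_radius_px=r,
                spiculation_amplitude=0.2,
                spiculation_lobes=8,
                center=(100.0, 100.0),
                rng_seed=5,
            )
            contour = contour_of(make_shape_mask(spec, (200, 200)))
            # keep the angle offset proportional to contour length so the
            # vertex-angle scale matches between sizes
            k = max(3, round(len(contour.points) / 45))
            vals[r] = feature_vector(contour, mode="full", k=k)
        for name in ("tc", "nrl_m", "nrl_std", "ar", "sdd"):
            a, b = getattr(vals[30.0], name), getattr(vals[60.0], name)
            assert abs(a - b) / max(a, b) < 0.10, name

    @pytest.mark.parametrize("k", [3, 5, 9])
    def test_irregularity_monotone_in_spiculation(self, k):
        amps = (0.0, 0.1, 0.2, 0.3)
        means = {name: [] for name in ("sdd", "ri", "nrl_std")}
        for a in amps:
            acc = {name: 0.0 for name in means}
            for seed in range(10):
                spec = ShapeSpec(
                    base_radius_px=40.0,
                    spiculation_amplitude=a,
                    spiculation_lobes=10,
                    center=(128.0, 128.0),
                    rng_seed=seed,
                )
                fv = feature_vector(
                    contour_of(make_shape_mask(spec, (256, 256))), mode="full", k=k
                )
                for name in means:
                    acc[name] += getattr(fv, name)
            for name in means:
                means[name].append(acc[name] / 10)
        tol = 1e-9
        for name, series in means.items():
            assert all(
                b >= a - tol for a, b in zip(series, series[1:])
            ), f"{name} not non-decreasing: {series}"

    def test_half_mode_bounds(self, star_contour):
        fv = feature_vector(star_contour, mode="half")
        assert 0 < fv.nrl_m <= 1
        assert fv.ar >= 0 and fv.ri >= 0
        assert 0 <= fv.sdd <= 180


class TestPasRobustness:
    def test_half_features_deviate_less_under_shadowing(self):
        """The package's core claim: shadowing corrupts full-contour features
        more than half-contour features."""
        from halfcontour.phantom import PasSpec, apply_pas

        rel_dev = {"full": [], "half": []}
        for seed in range(10):
            spec = ShapeSpec(
                base_radius_px=36.0,
                spiculation_amplitude=0.15,
                spiculation_lobes=9,
                center=(128.0, 100.0),
                rng_seed=seed,
            )
            mask = make_shape_mask(spec, (400, 256))
            clean = render_phantom(mask, EchoSpec(), rng_seed=seed)
            shadowed = apply_pas(clean, mask, PasSpec(0.4, 0.7, 0.999))
            feats = {}
            for name, img in (("clean", clean), ("pas", shadowed)):
                _, contour = segment(img, seed=(128, 100))
                feats[name] = {
                    mode: feature_vector(contour, mode=mode) for mode in ("full", "half")
                }
            for mode in ("full", "half"):
                a, b = feats["clean"][mode], feats["pas"][mode]
                dev = np.mean(
                    [
                        abs(getattr(b, f) - getattr(a, f)) / (abs(getattr(a, f)) + 1e-9)
                        for f in ("tc", "nrl_std", "ar", "ri", "sdd")
                    ]
                )
                rel_dev[mode].append(dev)
        assert np.median(rel_dev["half"]) < np.median(rel_dev["full"])
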