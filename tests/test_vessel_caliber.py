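"""Caliber pipeline: geometry, normalization, profiles, widths, metrics."""

import numpy as np
import pytest

from retphen import synthetic_data as sd
from retphen import vessel_caliber as vc


def _trace(points, cls="arteriole", vid="t0"):
    return vc.VesselTrace(id=vid, vessel_class=cls, points=np.asarray(points, float))


class TestThinCenterline:
    def test_horizontal_segment(self):
        chain = vc.thin_centerline(_trace([(0, 0), (10, 0)]))
        assert len(chain) == 11
        assert np.array_equal(chain[:, 1], np.zeros(11))
        assert np.array_equal(chain[:, 0], np.arange(11))

    def test_diagonal_segment(self):
        chain = vc.thin_centerline(_trace([(0, 0), (3, 3)]))
        assert len(chain) == 4
        assert np.array_equal(chain, [[0, 0], [1, 1], [2, 2], [3, 3]])

    def test_chain_stays_near_continuous_polyline(self):
        rng = np.random.default_rng(0)
        x = np.linspace(5, 95, 12)
        y = 50 + 20 * np.sin(x / 15) + rng.normal(0, 1, x.size)
        pts = np.column_stack([x, y])
        chain = vc.thin_centerline(_trace(pts))
        # dense sampling of the polyline as the distance oracle
        dense = np.concatenate(
            [
                np.linspace(pts[i], pts[i + 1], 400)
                for i in range(len(pts) - 1)
            ]
        )
        for p in chain:
            d = np.min(np.hypot(dense[:, 0] - p[0], dense[:, 1] - p[1]))
            assert d <= 0.71

    def test_degenerate_trace_rejected(self):
        tr = _trace([(2.1, 2.2), (1.9, 2.0)])  # both round to (2, 2)
        with pytest.raises(vc.VesselMeasurementError, match="degenerate"):
            vc.thin_centerline(tr)


class TestDilateCenterline:
    def test_radius_zero_is_identity(self):
        chain = vc.thin_centerline(_trace([(2, 5), (8, 5)]))
        mask = vc.dilate_centerline(chain, 0.0, (10, 12))
        assert mask.sum() == len(chain)
        assert mask[5, 2:9].all()

    def test_horizontal_chain_radius_three(self):
        chain = vc.thin_centerline(_trace([(5, 10), (25, 10)]))
        mask = vc.dilate_centerline(chain, 3.0, (21, 31))
        assert mask[:, 15].sum() == 7  # 3 above + center + 3 below

    def test_tube_area_close_to_analytic(self):
        length, r = 150, 6.0
        chain = vc.thin_centerline(_trace([(20, 100), (20 + length, 100)]))
        mask = vc.dilate_centerline(chain, r, (200, 200))
        analytic = length * 2 * r + np.pi * r**2
        assert mask.sum() == pytest.approx(analytic, rel=0.10)


class TestNormalizeBrightness:
    def test_two_valued_image_maps_to_unit_interval(self):
        img = np.full((20, 20), 10.0)
        img[8:12, :] = 200.0
        mask = np.ones_like(img, bool)
        scaled, (bg, vessel) = vc.normalize_brightness(img, mask)
        assert (bg, vessel) == (10.0, 200.0)
        assert set(np.unique(scaled)) == {0.0, 1.0}

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(2)
        img = np.full((30, 30), 100.0) + rng.normal(0, 2, (30, 30))
        img[12:18, :] += 80.0
        mask = np.ones_like(img, bool)
        a, _ = vc.normalize_brightness(img, mask)
        b, _ = vc.normalize_brightness(img + 50.0, mask)
        assert np.allclose(a, b, atol=1e-9)

    def test_levels_recovered_on_synthetic_vessel(self, straight_vessel_spec):
        spec = straight_vessel_spec(width_um=30.0, peak=80.0)
        img, _ = sd.generate_vessel_image(spec)
        chain = vc.thin_centerline(sd.vessel_traces(spec)[0])
        mask = vc.dilate_centerline(chain, 16.0, img.shape)
        _, (bg, vessel) = vc.normalize_brightness(img, mask)
        assert bg == pytest.approx(100.0, abs=1.0)
        assert vessel == pytest.approx(180.0, abs=1.0)

    def test_no_contrast_rejected(self):
        img = np.full((10, 10), 7.0)
        with pytest.raises(ValueError, match="contrast"):
            vc.normalize_brightness(img, np.ones_like(img, bool))


class TestEstimateTangents:
    def test_straight_line(self):
        chain = vc.thin_centerline(_trace([(0, 3), (30, 3)]))
        t = vc.estimate_tangents(chain)
        assert np.allclose(t, [[1.0, 0.0]] * len(chain))

    def test_circle_tangent_perpendicular_to_radius(self):
        theta = np.linspace(0, np.pi, 200)
        pts = np.column_stack([100 + 50 * np.cos(theta), 100 + 50 * np.sin(theta)])
        chain = vc.thin_centerline(_trace(pts))
        tangents = vc.estimate_tangents(chain)
        radial = chain - np.array([100.0, 100.0])
        radial = radial / np.linalg.norm(radial, axis=1, keepdims=True)
        dots = np.abs(np.sum(tangents * radial, axis=1))
        assert dots.max() < 0.05

    def test_sine_curve_matches_analytic_derivative(self):
        x = np.arange(0, 200, 1.0)
        pts = np.column_stack([x, 100 + 15 * np.sin(x / 25)])
        chain = vc.thin_centerline(_trace(pts))
        tangents = vc.estimate_tangents(chain)
        # analytic oracle, ends excluded (one-sided differences there)
        slope = 15 / 25 * np.cos(chain[:, 0] / 25)
        analytic = np.column_stack([np.ones_like(slope), slope])
        analytic /= np.linalg.norm(analytic, axis=1, keepdims=True)
        ang = np.degrees(
            np.arccos(np.clip(np.sum(tangents * analytic, axis=1), -1, 1))
        )
        assert np.max(ang[8:-8]) < 3.0


class TestPerpendicularSlices:
    def test_constant_image_gives_constant_profiles(self):
        img = np.full((50, 50), 42.0)
        chain = vc.thin_centerline(_trace([(10, 25), (40, 25)]))
        t = vc.estimate_tangents(chain)
        prof, offsets, kept = vc.extract_perpendicular_slices(img, chain, t, 10.0)
        assert np.allclose(prof, 42.0)
        assert offsets[0] == -10.0 and offsets[-1] == 10.0

    def test_aligned_rectangular_vessel_plateau(self, straight_vessel_spec):
        spec = straight_vessel_spec(width_um=20.0)  # 10 px wide
        img, _ = sd.generate_vessel_image(spec)
        chain = vc.thin_centerline(sd.vessel_traces(spec)[0])
        t = vc.estimate_tangents(chain)
        prof, offsets, _ = vc.extract_perpendicular_slices(img, chain, t, 15.0)
        inner = np.abs(offsets) <= 4.0
        outer = np.abs(offsets) >= 7.0
        assert np.allclose(prof[:, inner], 180.0, atol=1e-6)
        assert np.allclose(prof[:, outer], 100.0, atol=1e-6)

    def test_out_of_image_profiles_dropped(self):
        img = np.full((30, 30), 5.0)
        # diagonal chain: end-point normals leave the image, central ones fit
        chain = vc.thin_centerline(_trace([(2, 2), (27, 27)]))
        t = vc.estimate_tangents(chain)
        prof, _, kept = vc.extract_perpendicular_slices(img, chain, t, 6.0)
        assert 0 < kept.size < len(chain)
        assert prof.shape[0] == kept.size

    def test_all_profiles_outside_raises(self):
        img = np.full((30, 30), 5.0)
        chain = vc.thin_centerline(_trace([(1, 15), (28, 15)]))
        t = vc.estimate_tangents(chain)
        with pytest.raises(ValueError, match="leave the image"):
            vc.extract_perpendicular_slices(img, chain, t, 20.0)


class TestClipToCircle:
    def test_reference_circle_diameter_in_pixels(self):
        # 1.72 mm circle at 2 um/px -> radius 430 px
        circle = vc.ReferenceCircle((500.0, 500.0), 1720.0, 2.0)
        assert circle.radius_px == 430.0
        chain = np.column_stack(
            [np.arange(0, 1000), np.full(1000, 500)]
        )
        inside = vc.clip_to_circle(chain, circle)
        xs = chain[inside, 0]
        assert xs.min() == 71 and xs.max() == 929  # |x-500| < 430, strict

    def test_tiny_circle_keeps_only_nearest_point(self):
        circle = vc.ReferenceCircle((10.2, 5.0), 1.0, 1.0)
        chain = np.column_stack([np.arange(20), np.full(20, 5)])
        inside = vc.clip_to_circle(chain, circle)
        assert list(chain[inside, 0]) == [10]

    def test_fully_outside_raises(self):
        circle = vc.ReferenceCircle((1000.0, 1000.0), 10.0, 1.0)
        chain = np.column_stack([np.arange(20), np.full(20, 5)])
        with pytest.raises(ValueError, match="outside reference circle"):
            vc.clip_to_circle(chain, circle)


class TestEnsembleAverage:
    def test_identical_profiles_idempotent(self):
        p = np.tile(np.array([0.0, 0.5, 1.0, 0.5, 0.0]), (25, 1))
        assert np.array_equal(vc.ensemble_average(p), p[0])

    def test_side_branch_contamination_diluted(self):
        rng = np.random.default_rng(4)
        base = np.exp(-0.5 * (np.linspace(-5, 5, 41)) ** 2)
        profiles = np.tile(base, (120, 1))
        corrupt = rng.choice(120, size=5, replace=False)  # ~4% of slices
        branch = np.zeros(41)
        branch[30:] = 1.0  # bright side branch, amplitude 1
        profiles[corrupt] += branch
        ens = vc.ensemble_average(profiles)
        assert np.max(np.abs(ens - base)) < 0.05 * 1.0

    def test_linearity_of_subpopulation_means(self):
        rng = np.random.default_rng(5)
        a = rng.random((30, 11))
        b = rng.random((50, 11))
        both = vc.ensemble_average(np.vstack([a, b]))
        weighted = (30 * vc.ensemble_average(a) + 50 * vc.ensemble_average(b)) / 80
        assert np.allclose(both, weighted, atol=1e-12)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError, match="slices"):
            vc.ensemble_average(np.ones((5, 9)), min_slices=20)


class TestWidthAtMidbrightness:
    def test_rectangular_plateau(self):
        offsets = np.arange(-20, 20.25, 0.25)
        prof = np.where(np.abs(offsets) <= 5.0, 1.0, 0.0)
        res = vc.width_at_midbrightness(prof, offsets, 2.0)
        assert res.width_px == pytest.approx(10.0, abs=0.25)
        assert res.width_um == pytest.approx(res.width_px * 2.0)

    def test_linear_interpolation_arithmetic(self):
        prof = np.array([0, 0, 0, 0.2, 0.8, 1, 1, 0.8, 0.2, 0, 0, 0], float)
        offsets = np.arange(12, dtype=float)
        res = vc.width_at_midbrightness(prof, offsets, 1.0, background_fraction=0.34)
        assert res.width_px == pytest.approx(4.0, abs=1e-9)

    def test_multiple_lobes_warns_and_uses_peak_lobe(self):
        offsets = np.arange(-20, 20.25, 0.25)
        prof = np.where(np.abs(offsets) <= 3.0, 1.0, 0.0)
        prof += np.where(np.abs(offsets - 12) <= 1.0, 0.8, 0.0)
        with pytest.warns(UserWarning, match="lobe"):
            res = vc.width_at_midbrightness(prof, offsets, 1.0)
        assert res.width_px == pytest.approx(6.0, abs=0.5)

    def test_unenclosed_profile_rejected(self):
        offsets = np.arange(-10, 10.25, 0.25)
        prof = np.where(offsets >= 0, 1.0, 0.0)  # no crossing on the right
        with pytest.raises(ValueError, match="not enclosed"):
            vc.width_at_midbrightness(prof, offsets, 1.0)


class TestMeasureVessel:
    def test_noiseless_width_recovery(self, straight_vessel_spec):
        spec = straight_vessel_spec(width_um=30.0)
        img, _ = sd.generate_vessel_image(spec)
        res = vc.measure_vessel(
            img, sd.vessel_traces(spec)[0], spec.reference_circle,
            vc.VesselConfig(nominal_radius_px=8),
        )
        assert res.width_um == pytest.approx(30.0, abs=0.5)

    def test_rotation_changes_estimate_less_than_2pct(self, straight_vessel_spec):
        widths = {}
        for ang in (0.0, 45.0):
            spec = straight_vessel_spec(width_um=30.0, angle_deg=ang)
            img, _ = sd.generate_vessel_image(spec)
            res = vc.measure_vessel(
                img, sd.vessel_traces(spec)[0], spec.reference_circle,
                vc.VesselConfig(nominal_radius_px=8),
            )
            widths[ang] = res.width_um
        assert abs(widths[45.0] - widths[0.0]) / widths[0.0] < 0.02

    def test_noisy_width_within_5pct(self, straight_vessel_spec):
        # noise sd = 10% of the vessel contrast
        spec = straight_vessel_spec(width_um=30.0, peak=80.0, noise_sd=8.0, seed=11)
        img, _ = sd.generate_vessel_image(spec)
        res = vc.measure_vessel(
            img, sd.vessel_traces(spec)[0], spec.reference_circle,
            vc.VesselConfig(nominal_radius_px=8),
        )
        assert res.width_um == pytest.approx(30.0, rel=0.05)

    def test_error_carries_vessel_id(self, straight_vessel_spec):
        spec = straight_vessel_spec()
        img, _ = sd.generate_vessel_image(spec)
        trace = vc.VesselTrace(
            id="offcenter", vessel_class="venule",
            points=np.array([[0.0, 0.0], [10.0, 0.0]]),
        )
        tiny = vc.ReferenceCircle((100.0, 100.0), 10.0, 2.0)
        with pytest.raises(vc.VesselMeasurementError, match="offcenter"):
            vc.measure_vessel(img, trace, tiny)


class TestPipelineProperties:
    def test_scale_equivariance(self, straight_vessel_spec):
        # same pixel geometry, doubled micron scale: width_px fixed, um doubled
        res = {}
        for scale in (2.0, 4.0):
            spec = straight_vessel_spec(width_um=15.0 * scale, scale=scale)
            img, _ = sd.generate_vessel_image(spec)
            res[scale] = vc.measure_vessel(
                img, sd.vessel_traces(spec)[0], spec.reference_circle,
                vc.VesselConfig(nominal_radius_px=8),
            )
        assert res[2.0].width_px == pytest.approx(res[4.0].width_px, abs=1e-9)
        assert res[4.0].width_um == pytest.approx(2 * res[2.0].width_um, abs=1e-6)

    def test_power_of_two_gain_is_bit_stable(self, straight_vessel_spec):
        spec = straight_vessel_spec(width_um=30.0, noise_sd=4.0, seed=3)
        img, _ = sd.generate_vessel_image(spec)
        cfg = vc.VesselConfig(nominal_radius_px=8)
        tr = sd.vessel_traces(spec)[0]
        a = vc.measure_vessel(img, tr, spec.reference_circle, cfg)
        b = vc.measure_vessel(img * 2.0, tr, spec.reference_circle, cfg)
        assert a.width_px == b.width_px  # exact: binary scaling commutes

    def test_general_affine_gain_offset_invariance(self, straight_vessel_spec):
        spec = straight_vessel_spec(width_um=30.0, noise_sd=4.0, seed=3)
        img, _ = sd.generate_vessel_image(spec)
        cfg = vc.VesselConfig(nominal_radius_px=8)
        tr = sd.vessel_traces(spec)[0]
        a = vc.measure_vessel(img, tr, spec.reference_circle, cfg)
        b = vc.measure_vessel(1.3 * img + 17.0, tr, spec.reference_circle, cfg)
        assert b.width_px == pytest.approx(a.width_px, rel=1e-9)

    def test_gaussian_width_monotone_in_true_fwhm(self, straight_vessel_spec):
        est = []
        for w in (16.0, 22.0, 28.0, 34.0):
            spec = straight_vessel_spec(width_um=w, profile="gaussian")
            img, _ = sd.generate_vessel_image(spec)
            res = vc.measure_vessel(
                img, sd.vessel_traces(spec)[0], spec.reference_circle,
                vc.VesselConfig(nominal_radius_px=10),
            )
            est.append(res.width_um)
        assert np.all(np.diff(est) > 0)

    def test_shrinking_circle_never_increases_slices(self, straight_vessel_spec):
        spec = straight_vessel_spec(width_um=30.0)
        img, _ = sd.generate_vessel_image(spec)
        tr = sd.vessel_traces(spec)[0]
        cfg = vc.VesselConfig(nominal_radius_px=8)
        n = []
        for diam in (280.0, 200.0, 120.0):
            circle = vc.ReferenceCircle((99.5, 99.5), diam, 2.0)
            n.append(vc.measure_vessel(img, tr, circle, cfg).n_slices)
        assert n[0] >= n[1] >= n[2]


class TestSummaries:
    def _per_vessel(self, rows):
        import pandas as pd

        return pd.DataFrame(
            rows, columns=["vessel_id", "vessel_class", "n_slices", "width_px", "width_um"]
        )

    def test_per_class_means_and_counts(self):
        df = self._per_vessel(
            [
                ("a1", "arteriole", 30, 5, 10.0),
                ("a2", "arteriole", 30, 6, 12.0),
                ("v1", "venule", 30, 10, 20.0),
            ]
        )
        s = vc.summarize_retina(df).set_index("vessel_class")
        assert s.loc["arteriole", "mean_width_um"] == 11.0
        assert s.loc["arteriole", "vessel_count"] == 2
        assert s.loc["venule", "mean_width_um"] == 20.0
        assert s.loc["venule", "vessel_count"] == 1

    def test_mouse_mean_of_two_retinas(self):
        r1 = vc.summarize_retina(self._per_vessel([("v1", "venule", 30, 9, 18.0)]))
        r2 = vc.summarize_retina(self._per_vessel([("v2", "venule", 30, 11, 22.0)]))
        m = vc.summarize_mouse([r1, r2]).set_index("vessel_class")
        assert m.loc["venule", "mean_width_um"] == 20.0

    def test_empty_class_has_absent_mean(self):
        s = vc.summarize_retina(
            self._per_vessel([("a1", "arteriole", 30, 5, 10.0)])
        ).set_index("vessel_class")
        assert s.loc["venule", "vessel_count"] == 0
        assert np.isnan(s.loc["venule", "mean_width_um"])


class TestTortuosity:
    def test_straight_segment_is_one(self):
        assert vc.tortuosity(np.array([[0, 0], [10, 0], [30, 0]])) == 1.0

    def test_semicircle(self):
        theta = np.linspace(0, np.pi, 2000)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        assert vc.tortuosity(pts) == pytest.approx(np.pi / 2, rel=1e-5)

    def test_sine_matches_quadrature(self):
        from scipy.integrate import quad

        x = np.linspace(0, 40 * np.pi, 20000)
        pts = np.column_stack([x, 10 * np.sin(x / 20)])
        arc, _ = quad(lambda u: np.hypot(1, 0.5 * np.cos(u / 20)), 0, 40 * np.pi)
        expected = arc / (40 * np.pi)
        assert vc.tortuosity(pts) == pytest.approx(expected, rel=0.005)

    def test_closed_curve_rejected(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        with pytest.raises(ValueError, match="chord"):
            vc.tortuosity(square)


class TestFractalDimension:
    def test_straight_line_dimension_one(self):
        mask = np.zeros((200, 200), bool)
        mask[100, 10:190] = True
        assert vc.fractal_dimension(mask) == pytest.approx(1.0, abs=0.05)

    def test_filled_square_dimension_two(self):
        mask = np.zeros((200, 200), bool)
        mask[20:180, 20:180] = True
        assert vc.fractal_dimension(mask) == pytest.approx(2.0, abs=0.05)

    def test_matches_dense_box_count_oracle_on_tree(self):
        # synthetic branching tree mask
        mask = np.zeros((256, 256), bool)

        def branch(x, y, ang, length, depth):
            if depth == 0 or length < 4:
                return
            for t in np.linspace(0, length, int(length * 3)):
                px, py = int(x + t * np.cos(ang)), int(y + t * np.sin(ang))
                if 0 <= px < 256 and 0 <= py < 256:
                    mask[py, px] = True
            x2, y2 = x + length * np.cos(ang), y + length * np.sin(ang)
            branch(x2, y2, ang + 0.5, length * 0.7, depth - 1)
            branch(x2, y2, ang - 0.5, length * 0.7, depth - 1)

        branch(128, 250, -np.pi / 2, 80, 7)

        # independent counting route: 2-D histogram of occupied cells
        ys, xs = np.nonzero(mask)
        y0, x0 = ys.min(), xs.min()
        span = max(ys.max() - y0 + 1, xs.max() - x0 + 1)
        sizes, s = [], 1
        while s <= span / 4:
            sizes.append(s)
            s *= 2
        counts = []
        for s in sizes:
            nb_y = int(np.ceil((ys.max() - y0 + 1) / s))
            nb_x = int(np.ceil((xs.max() - x0 + 1) / s))
            hist, _, _ = np.histogram2d(
                ys - y0, xs - x0, bins=[nb_y, nb_x],
                range=[[0, nb_y * s], [0, nb_x * s]],
            )
            counts.append(int((hist > 0).sum()))
        slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, float)), np.log(counts), 1)
        assert vc.fractal_dimension(mask) == pytest.approx(slope, abs=0.02)

    def test_small_mask_rejected(self):
        mask = np.zeros((8, 8), bool)
        mask[4, 2:6] = True
        with pytest.raises(ValueError, match="octaves"):
            vc.fractal_dimension(mask)
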