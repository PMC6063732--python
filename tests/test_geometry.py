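"""Embryo orientation, circle/ring fitting and the ingression axis."""

import math

import numpy as np
import pytest

from ringflow import geometry as geo
from ringflow import synthetic as syn


def brute_force_circle(points, grid_um=0.05, span_um=1.0):
    """Independent oracle: exhaustive center search on a coarse grid."""
    pts = np.asarray(points, dtype=float)
    c0 = pts.mean(axis=0)
    best = None
    for cx in np.arange(c0[0] - span_um, c0[0] + span_um + 1e-9, grid_um):
        for cy in np.arange(c0[1] - span_um, c0[1] + span_um + 1e-9, grid_um):
            d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
            r = d.mean()
            ssr = float(np.sum((d - r) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, cx, cy, r)
    return best


class TestCircleFit:
    def test_exact_on_circle_points(self):
        phi = np.linspace(0, 2 * np.pi, 17)[:-1]
        pts = np.column_stack([3.0 + 5.0 * np.cos(phi), -2.0 + 5.0 * np.sin(phi)])
        cx, cy, r, rms = geo.fit_circle(pts)
        assert (cx, cy, r) == pytest.approx((3.0, -2.0, 5.0), abs=1e-9)
        assert rms < 1e-9

    def test_beats_brute_force_grid_search(self):
        rng = np.random.default_rng(1)
        phi = rng.uniform(0, 2 * np.pi, 15)
        pts = np.column_stack([2 + 4 * np.cos(phi), 1 + 4 * np.sin(phi)])
        pts += rng.normal(0, 0.15, pts.shape)
        cx, cy, r, rms = geo.fit_circle(pts)
        ssr_fit = float(np.sum((np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r) ** 2))
        ssr_grid = brute_force_circle(pts)[0]
        assert ssr_fit <= ssr_grid + 1e-9

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(2)
        phi = rng.uniform(0, 2 * np.pi, 12)
        pts = np.column_stack([2 + 4 * np.cos(phi), 1 + 4 * np.sin(phi)])
        pts += rng.normal(0, 0.05, pts.shape)
        cx, cy, r, _ = geo.fit_circle(pts)
        rot = pts @ np.array([[0.0, -1.0], [1.0, 0.0]]).T  # 90° rotation
        cx2, cy2, r2, _ = geo.fit_circle(rot)
        assert (cx2, cy2) == pytest.approx((-cy, cx), abs=1e-6)
        assert r2 == pytest.approx(r, abs=1e-6)


class TestOrientation:
    def test_unrotated_embryo(self):
        spec = syn.EmbryoSpec(seed=21)
        stack = syn.render_embryo_stack(spec, rotation_deg=0.0)
        pose = geo.orient_embryo(stack, pixel_size=0.1)
        ang = pose.rotation_angle if pose.rotation_angle < 180 else pose.rotation_angle - 360
        assert abs(ang) < 1.0
        assert pose.anterior_end == "top"

    def test_recovers_rotation_within_one_degree(self):
        spec = syn.EmbryoSpec(seed=22)
        stack = syn.render_embryo_stack(spec, rotation_deg=37.0)
        pose = geo.orient_embryo(stack, pixel_size=0.1)
        assert pose.rotation_angle == pytest.approx(37.0, abs=1.0)

    def test_segmentation_failure_when_area_window_excludes_mask(self):
        spec = syn.EmbryoSpec(seed=23)
        stack = syn.render_embryo_stack(spec)
        with pytest.raises(geo.SegmentationError):
            geo.orient_embryo(stack, pixel_size=0.1, expected_area_px2=(500.0, 100.0))


class TestEmbryoCircle:
    def test_radius_recovery_across_seeds(self):
        errs = []
        for seed in range(5):
            spec = syn.EmbryoSpec(seed=100 + seed)
            rot = 15.0 + 30.0 * seed
            stack = syn.render_embryo_stack(spec, rotation_deg=rot)
            pose = geo.orient_embryo(stack, pixel_size=0.1)
            pose = geo.fit_embryo_circle(stack, pose, pixel_size=0.1, dz_um=2.0)
            errs.append(pose.embryo_radius_um - spec.embryo_radius)
        # sub-pixel boundary interpolation keeps the radius within half a
        # pixel (0.05 µm at 0.1 µm/px) of truth on average
        assert abs(np.mean(errs)) < 0.1
        assert np.max(np.abs(errs)) < 0.25


class TestRingFit:
    def _stack_with_ring(self, radius=7.0, offset=(0.7, 0.7), noise=0.05, seed=31):
        spec = syn.EmbryoSpec(seed=seed, noise_sd=noise)
        ring = geo.RingFit(
            time=0.0,
            radius=radius,
            center=(0.0, float(np.hypot(*offset))),
            rbar=radius / spec.embryo_radius,
            center_end_on=offset,
        )
        return spec, ring, syn.render_division_plane_stack(spec, ring)

    def test_noiseless_ring_recovered(self):
        spec, ring, stack = self._stack_with_ring(noise=0.0)
        pose = geo.EmbryoPose(
            rotation_angle=0.0, embryo_radius_um=spec.embryo_radius, pixel_size=spec.pixel_size
        )
        fit = geo.fit_ring(stack, pose, pixel_size=spec.pixel_size, dz_um=0.5)
        assert fit.radius == pytest.approx(7.0, abs=0.05)
        # rendered center offsets are relative to the image center
        assert fit.center_end_on[0] == pytest.approx(36.0 / 2 + 0.7, abs=0.1)
        assert fit.center_end_on[1] == pytest.approx(40 * 0.5 / 2 + 0.7, abs=0.1)

    def test_translation_equivariance(self):
        spec, _, stack_a = self._stack_with_ring(offset=(0.0, 0.0), noise=0.0)
        _, _, stack_b = self._stack_with_ring(offset=(1.5, -1.0), noise=0.0)
        pose = geo.EmbryoPose(rotation_angle=0.0, pixel_size=spec.pixel_size)
        fa = geo.fit_ring(stack_a, pose, pixel_size=spec.pixel_size, dz_um=0.5)
        fb = geo.fit_ring(stack_b, pose, pixel_size=spec.pixel_size, dz_um=0.5)
        assert fb.center_end_on[0] - fa.center_end_on[0] == pytest.approx(1.5, abs=0.1)
        assert fb.center_end_on[1] - fa.center_end_on[1] == pytest.approx(-1.0, abs=0.1)
        assert fb.radius == pytest.approx(fa.radius, abs=0.05)

    def test_ring_not_found_on_empty_stack(self):
        rng = np.random.default_rng(0)
        stack = rng.normal(100.0, 1.0, (10, 60, 60))
        pose = geo.EmbryoPose(rotation_angle=0.0, pixel_size=0.16)
        with pytest.raises(geo.RingNotFoundError):
            geo.fit_ring(stack, pose, pixel_size=0.16, dz_um=0.5)


class TestIngressionAxis:
    @staticmethod
    def _ring(t, rbar, center):
        return geo.RingFit(
            time=t, radius=rbar * 14.7, center=(0.0, float(np.hypot(*center))),
            rbar=rbar, center_end_on=center,
        )

    def test_collinear_centers_exact(self):
        ang = math.radians(30.0)
        u = (math.sin(ang), math.cos(ang))
        rings = [
            self._ring(t, rb, (d * u[0], d * u[1]))
            for t, rb, d in [(0, 0.9, 2.0), (36, 0.7, 1.0), (72, 0.5, 0.0), (108, 0.35, -1.0)]
        ]
        axis = geo.initial_ingression_axis(rings)
        assert axis.angle == pytest.approx(30.0, abs=1e-6)
        assert axis.fit_rms < 1e-9

    def test_small_rings_excluded(self):
        ang = math.radians(30.0)
        u = (math.sin(ang), math.cos(ang))
        rings = [
            self._ring(t, rb, (d * u[0], d * u[1]))
            for t, rb, d in [(0, 0.9, 2.0), (36, 0.7, 1.0), (72, 0.5, 0.0)]
        ]
        # a wildly off-axis center that must be ignored (rbar below 0.3)
        rings.append(self._ring(108, 0.2, (5.0, -5.0)))
        axis = geo.initial_ingression_axis(rings)
        assert axis.angle == pytest.approx(30.0, abs=1e-6)

    def test_generator_axis_recovered_across_seeds(self):
        errs = []
        for seed in range(10):
            pop = syn.make_population(1, seed=200 + seed)
            spec, gt = pop[0]
            rings = syn.make_ring_trajectory(spec, gt.params, noise_sd_um=0.2)
            axis = geo.initial_ingression_axis(rings)
            d = (axis.angle - spec.ingression_axis_angle) % 360.0
            errs.append(min(d, 360.0 - d))
        assert np.median(errs) < 3.0

    def test_too_few_rings_raises(self):
        rings = [self._ring(0, 0.2, (1.0, 0.0)), self._ring(36, 0.15, (0.5, 0.0))]
        with pytest.raises(geo.UndefinedAxisError):
            geo.initial_ingression_axis(rings)
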