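"""Predicted velocity profiles and the surface-area budget."""

import math

import numpy as np
import pytest

from ringflow import alignment as al
from ringflow import flowmap as fl
from ringflow import kinematics as kin
from ringflow import synthetic as syn


class TestPredictedProfiles:
    def test_zero_gain_zero_velocity(self):
        xs = np.linspace(-12, 12, 25)
        v = kin.predicted_profile(kin.SurfaceGainSpec.behind_ring(u=0.0), xs)
        assert np.allclose(v, 0.0)

    def test_polar_gain_constant_profile(self):
        xs = np.linspace(-12, 12, 25)
        v = kin.predicted_profile(kin.SurfaceGainSpec.polar(c=0.07, u=0.01), xs)
        assert np.allclose(v, 0.08)

    def test_uniform_gain_linear_profile(self):
        xs = np.linspace(-12, 12, 25)
        v = kin.predicted_profile(kin.SurfaceGainSpec.uniform(c=0.02, u=0.005), xs)
        assert np.allclose(v, 0.02 * xs + 0.005, atol=1e-6)


def _constant_map(f: float, r_emb: float = 14.7, t_ck: float = 200.0) -> fl.FlowMap:
    """Map with dimensionless AP speed f toward the plane on both sides."""
    t_edges = fl.DEFAULT_THAT_EDGES
    x_edges = fl.DEFAULT_X_EDGES
    th_edges = fl.DEFAULT_THETA_EDGES
    shape = (len(t_edges) - 1, len(x_edges) - 1, len(th_edges) - 1)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    fx = np.broadcast_to(
        (-np.sign(xc) * f)[None, :, None], shape
    ).copy()
    return fl.FlowMap(
        t_hat_edges=t_edges,
        x_edges=x_edges,
        theta_edges=th_edges,
        fx=fx,
        ftheta=np.zeros(shape),
        count=np.full(shape, 10, dtype=int),
        r_emb=r_emb,
        t_ck=t_ck,
    )


class TestInflowRate:
    def test_zero_map(self):
        fmap = _constant_map(0.0)
        assert kin.inflow_rate(fmap, 0.5) == (0.0, 0.0, 0.0)

    def test_uniform_speed_closed_form(self):
        # both sides flowing in at dimensionless speed f: the closed-form
        # oracle is 2 sides x (2 pi R_emb) x (f R_emb) per unit t_hat
        f = 0.03
        fmap = _constant_map(f)
        ant, post, total = kin.inflow_rate(fmap, 0.5)
        expected = 2.0 * (2.0 * math.pi * 14.7) * f * 14.7
        assert total == pytest.approx(expected, rel=1e-9)
        assert ant == pytest.approx(post)

    def test_default_abscissae_are_seven_microns(self):
        import inspect

        sig = inspect.signature(kin.inflow_rate)
        assert sig.parameters["x0_pair"].default == (-7.0, 7.0)


def _linear_curve() -> al.AverageRingCurve:
    grid = np.arange(-0.3, 1.1, 0.01)
    rbar = np.clip(1.0 - grid, 0.0, 1.1)
    return al.AverageRingCurve(t_hat=grid, rbar=rbar, count=np.full_like(grid, 10))


class TestSurfaceBudget:
    def test_zero_flow_frozen_ring_all_zero(self):
        fmap = _constant_map(0.0)
        curve = al.AverageRingCurve(
            t_hat=np.arange(-0.3, 1.1, 0.01),
            rbar=np.full(140, 0.8),
            count=np.full(140, 10),
        )
        b = kin.surface_budget(fmap, curve)
        assert np.allclose(b.a_surf, 0.0)
        assert np.allclose(b.a_div, 0.0)
        assert np.allclose(b.a_comp, 0.0)

    def test_budget_identity_exact(self):
        fmap = _constant_map(0.02)
        b = kin.surface_budget(fmap, _linear_curve())
        assert np.array_equal(b.a_comp, b.a_surf - b.a_div)

    def test_out_of_coverage_start_raises(self):
        fmap = _constant_map(0.02)
        with pytest.raises(ValueError):
            kin.surface_budget(fmap, _linear_curve(), t_hat0=-0.9)

    def test_pull_only_world_has_no_compression(self):
        # flank speed exactly feeds division-plane growth (gain behind the
        # ring only): A_surf tracks A_div within integration error
        r_emb, t_ck = 14.7, 200.0
        curve = _linear_curve()
        t_edges = fl.DEFAULT_THAT_EDGES
        tc = 0.5 * (t_edges[:-1] + t_edges[1:])
        shape = (len(t_edges) - 1, len(fl.DEFAULT_X_EDGES) - 1, len(fl.DEFAULT_THETA_EDGES) - 1)
        fx = np.zeros(shape)
        xc = 0.5 * (fl.DEFAULT_X_EDGES[:-1] + fl.DEFAULT_X_EDGES[1:])
        for i, th in enumerate(tc):
            rb = float(np.interp(th, curve.t_hat, curve.rbar))
            drdt = -1.0  # dRbar/dt_hat of the linear curve
            f_pull = max(-rb * drdt, 0.0)  # dimensionless per side
            fx[i] = (-np.sign(xc) * f_pull)[:, None]
        fmap = fl.FlowMap(
            t_hat_edges=t_edges,
            x_edges=fl.DEFAULT_X_EDGES,
            theta_edges=fl.DEFAULT_THETA_EDGES,
            fx=fx,
            ftheta=np.zeros(shape),
            count=np.full(shape, 10, dtype=int),
            r_emb=r_emb,
            t_ck=t_ck,
        )
        b = kin.surface_budget(fmap, curve, t_hat0=0.0, t_hat_end=0.9)
        assert b.a_surf[-1] == pytest.approx(b.a_div[-1], rel=0.02)

    def test_generator_world_compresses_throughout(self, small_population):
        embryos = []
        for spec, gt in small_population:
            times = np.arange(
                gt.frame.t0 - 0.28 * gt.frame.t_ck, gt.frame.t0 + 1.0 * gt.frame.t_ck, 12.0
            )
            fields = [syn.make_flow_field(spec, gt.params, t) for t in times]
            embryos.append(
                {
                    "t0": gt.frame.t0,
                    "t_ck": gt.frame.t_ck,
                    "r_emb": spec.embryo_radius,
                    "times": times,
                    "fields": fields,
                }
            )
        fmap = fl.normalize_and_average(embryos)
        grid = np.arange(-0.3, 1.05, 0.01)
        rbar = np.array(
            [np.mean([float(gt.rbar(gt.frame.t0 + t * gt.frame.t_ck)) for _, gt in small_population]) for t in grid]
        )
        curve = al.AverageRingCurve(t_hat=grid, rbar=rbar, count=np.full_like(grid, 10))
        b = kin.surface_budget(fmap, curve, t_hat0=-0.2, t_hat_end=0.9)
        assert np.all(b.a_surf[1:] >= b.a_div[1:])
        pos = b.rate_div > 0.05 * b.rate_div.max()
        assert np.all(b.rate_surf[pos] / b.rate_div[pos] > 1.0)


class TestCompressionZone:
    def test_constant_profile_flagged_no_zone(self):
        xs = np.arange(-14.5, 15, 1.0)
        prof = -np.sign(xs) * 0.5
        zone = kin.compression_zone_width(xs, prof)
        assert zone.no_zone

    def test_generator_zone_width_recovered(self, small_population):
        embryos = []
        for spec, gt in small_population:
            t = gt.frame.t0 - 0.28 * gt.frame.t_ck
            fields = [syn.make_flow_field(spec, gt.params, t, noise_sd=0.05)]
            embryos.append(
                {
                    "t0": gt.frame.t0,
                    "t_ck": gt.frame.t_ck,
                    "r_emb": spec.embryo_radius,
                    "times": np.array([t]),
                    "fields": fields,
                }
            )
        fmap = fl.normalize_and_average(embryos)
        xc, prof, _ = fl.ap_velocity_profile(fmap, -0.28, band=(0.0, 180.0))
        zone = kin.compression_zone_width(xc, prof)
        assert not zone.no_zone
        assert zone.width == pytest.approx(10.0, abs=0.5)
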