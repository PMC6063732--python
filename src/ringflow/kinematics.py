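"""Surface-flow predictions and the cortical surface-area budget.

Given a pattern of cortical surface gain g(x) (1/s per µm) and a ring-motion
velocity u, the expected AP velocity profile is ``v(x) = ∫0^x g + u``; the
three canonical patterns (uniform, polar, behind-the-ring gain) predict a
linear gradient, a constant, and zero/constant velocity respectively.

From an averaged dimensionless flow map, the rate at which cortical surface
enters the division plane is measured at x0 = ±7 µm; integrating it in time
and comparing with the division-plane area increase (two surfaces,
``2π(<R>²(t̂0) − <R>²(t̂))``) yields the area compressed within the ring:
``A_comp = A_surf − A_div`` identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .alignment import AverageRingCurve
from .flowmap import FlowMap, ap_velocity_profile

__all__ = [
    "SurfaceGainSpec",
    "SurfaceBudget",
    "CompressionZone",
    "predicted_profile",
    "inflow_rate",
    "surface_budget",
    "compression_zone_width",
]


@dataclass(frozen=True)
class SurfaceGainSpec:
    """A candidate cortical surface-gain pattern.

    ``gain`` maps x (µm) to local gain density (1/s); ``u`` is the velocity
    of asymmetric ring movement (µm/s).
    """

    gain: Callable[[np.ndarray], np.ndarray]
    u: float = 0.0

    @classmethod
    def uniform(cls, c: float, u: float = 0.0) -> "SurfaceGainSpec":
        """Uniform gain: predicts v(x) = C·x + u (linear gradient)."""
        return cls(gain=lambda x: np.full_like(np.asarray(x, dtype=float), c), u=u)

    @classmethod
    def polar(cls, c: float, u: float = 0.0) -> "SurfaceGainSpec":
        """Gain at the poles only: v(x) = C + u, constant in the map region."""
        return cls(gain=lambda x: np.zeros_like(np.asarray(x, dtype=float)), u=c + u)

    @classmethod
    def behind_ring(cls, u: float = 0.0) -> "SurfaceGainSpec":
        """Gain immediately behind the ring: v(x) = u (0 for symmetric furrowing)."""
        return cls(gain=lambda x: np.zeros_like(np.asarray(x, dtype=float)), u=u)


def predicted_profile(spec: SurfaceGainSpec, xs: Sequence[float]) -> np.ndarray:
    """Expected AP velocity profile ``v(x) = ∫0^x g(x')dx' + u``."""
    xs = np.asarray(xs, dtype=float)
    out = np.empty_like(xs)
    for i, x in enumerate(xs):
        grid = np.linspace(0.0, x, 201)
        if grid.size < 2 or x == 0.0:
            out[i] = spec.u
            continue
        g = spec.gain(grid)
        out[i] = np.trapezoid(g, grid) + spec.u
    return out


def inflow_rate(
    fmap: FlowMap,
    t_hat: float,
    x0_pair: Tuple[float, float] = (-7.0, 7.0),
) -> Tuple[float, float, float]:
    """Rate of cortical surface flow into the division plane, µm² per unit t̂.

    ``dA/dt̂ = 2 R_emb² ∫0^π <f̄>_AP dθ`` at each measurement abscissa (the
    factor 2 restores the mirrored half-domain); anterior and posterior
    rates are reported separately (positive = toward the plane) along with
    the sum.  Low-coverage cells trigger a warning; missing cells are
    excluded from the angular mean.
    """
    import warnings

    it = fmap.t_index(t_hat)
    dtheta = math.radians(float(np.mean(np.diff(fmap.theta_edges))))
    rates = []
    for x0 in x0_pair:
        ix = int(np.searchsorted(fmap.x_edges, x0, side="right")) - 1
        ix = min(max(ix, 0), fmap.fx.shape[1] - 1)
        col = fmap.fx[it, ix]
        cnt = fmap.count[it, ix]
        good = np.isfinite(col)
        if not np.any(good):
            rates.append(np.nan)
            continue
        if np.any(cnt[good] < fmap.low_coverage_threshold):
            warnings.warn(f"low coverage at x0={x0} µm, t_hat={t_hat:.2f}")
        mean_f = float(np.mean(col[good]))
        integral = mean_f * math.pi  # ∫0^π over the folded half-domain
        toward_plane = -np.sign(x0) * integral
        rates.append(2.0 * fmap.r_emb**2 * toward_plane)
    total = float(np.nansum(rates))
    return float(rates[0]), float(rates[1]), total


@dataclass
class SurfaceBudget:
    """Time series of the cortical surface-area bookkeeping (µm²)."""

    t_hat: np.ndarray
    a_surf: np.ndarray
    a_div: np.ndarray
    a_comp: np.ndarray
    rate_surf: np.ndarray
    rate_div: np.ndarray
    rate_comp: np.ndarray
    per_unit_length_compression: np.ndarray  # µm²·s⁻¹ per µm of ring

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_hat": self.t_hat,
                "a_surf_um2": self.a_surf,
                "a_div_um2": self.a_div,
                "a_comp_um2": self.a_comp,
                "rate_surf": self.rate_surf,
                "rate_div": self.rate_div,
                "rate_comp": self.rate_comp,
                "per_unit_length_compression": self.per_unit_length_compression,
            }
        )


def surface_budget(
    fmap: FlowMap,
    curve: AverageRingCurve,
    t_hat0: float = -0.2,
    t_hat_end: float | None = None,
) -> SurfaceBudget:
    """Integrate the flow map into the surface-area budget from ``t_hat0``.

    ``A_surf`` is the trapezoidal time integral of the summed inflow rate;
    ``A_div = 2π(<R>²(t̂0) − <R>²(t̂))`` counts both new surfaces;
    ``A_comp = A_surf − A_div`` by definition.  The per-unit-length
    compression rate divides the compression rate (converted to per second
    with the population-mean t_CK) by the ring perimeter ``2π<R>(t̂)``.
    """
    centers = fmap.t_hat_centers
    if t_hat0 < fmap.t_hat_edges[0] or t_hat0 > fmap.t_hat_edges[-1]:
        raise ValueError(f"t_hat0={t_hat0} outside map coverage")
    sel = centers >= t_hat0
    if t_hat_end is not None:
        sel &= centers <= t_hat_end
    th = centers[sel]
    if th.size == 0 or th[0] > t_hat0:
        # start the integration exactly at t_hat0 (rate from its bin)
        th = np.concatenate(([t_hat0], th))
    rate_surf = np.array([inflow_rate(fmap, t)[2] for t in th])
    a_surf = np.concatenate(([0.0], cumulative_trapezoid(rate_surf, th)))

    r_mean = fmap.r_emb * curve(th)
    r0 = fmap.r_emb * float(curve(t_hat0))
    r_eff = np.minimum(r_mean, r0)
    a_div = 2.0 * math.pi * (r0**2 - r_eff**2)
    a_comp = a_surf - a_div

    rate_div = np.gradient(a_div, th)
    rate_comp = rate_surf - rate_div
    perim = 2.0 * math.pi * np.maximum(r_mean, 1e-6)
    per_len = rate_comp / perim / fmap.t_ck  # per second
    return SurfaceBudget(
        t_hat=th,
        a_surf=a_surf,
        a_div=a_div,
        a_comp=a_comp,
        rate_surf=rate_surf,
        rate_div=rate_div,
        rate_comp=rate_comp,
        per_unit_length_compression=per_len,
    )


@dataclass
class CompressionZone:
    """Constant-ramp-constant template fit to an AP velocity profile."""

    width: float            # ramp (zone) full width, µm
    center: float           # zone center, µm
    flank_speed_anterior: float
    flank_speed_posterior: float
    residual_rms: float
    no_zone: bool = False


def compression_zone_width(
    xs: Sequence[float],
    profile: Sequence[float],
    exclude_um: float = 2.0,
    max_width: float = 25.0,
) -> CompressionZone:
    """Fit a constant-ramp-constant template and return the ramp width.

    The template is ``v = V_a`` for ``x <= c − w/2``, ``v = −V_p`` for
    ``x >= c + w/2`` and linear in between — a uniform compression zone of
    width ``w`` between two constant-velocity flanks.  Points with
    ``|x| < exclude_um`` are excluded (projection artifact near the plane),
    as are missing values.  A fit whose residual exceeds 20% of the mean
    flank speed is flagged ``no_zone``, as is a ramp narrow enough to hide
    inside the excluded gap (width ≤ 2*exclude_um + one sample spacing) —
    such a "zone" is indistinguishable from a plain velocity jump at the
    division plane.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(profile, dtype=float)
    good = np.isfinite(ys) & (np.abs(xs) >= exclude_um)
    x, y = xs[good], ys[good]
    if x.size < 6:
        raise ValueError("too few profile points to fit the template")

    va0 = float(np.mean(y[x < 0])) if np.any(x < 0) else float(np.max(y))
    vp0 = float(-np.mean(y[x > 0])) if np.any(x > 0) else va0

    def template(p):
        va, vp, w, c = p
        lo, hi = c - w / 2.0, c + w / 2.0
        out = np.where(
            x <= lo,
            va,
            np.where(x >= hi, -vp, va + (x - lo) / max(hi - lo, 1e-9) * (-vp - va)),
        )
        return out

    def resid(p):
        return template(p) - y

    sol = least_squares(
        resid,
        [abs(va0), abs(vp0), 8.0, 0.0],
        bounds=([0.0, 0.0, 0.0, -10.0], [np.inf, np.inf, max_width, 10.0]),
        method="trf",
    )
    va, vp, w, c = sol.x
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    flank = 0.5 * (va + vp)
    spacing = float(np.median(np.diff(np.unique(x)))) if x.size > 1 else 0.0
    no_zone = w <= 2.0 * exclude_um + spacing + 1e-6 or (
        flank > 0 and rms > 0.2 * flank
    )
    return CompressionZone(
        width=float(w),
        center=float(c),
        flank_speed_anterior=float(va),
        flank_speed_posterior=float(vp),
        residual_rms=rms,
        no_zone=bool(no_zone),
    )
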