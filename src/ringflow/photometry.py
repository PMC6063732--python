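"""Depth-attenuation correction and ring-component quantification.

Fluorescence collected from deeper z-planes of the division-plane stack is
dimmer; the decay is well described by ``I = I0 * exp(-z / z_att)`` with a
characteristic depth shared across embryos.  After correcting for it (and
subtracting background), per-unit-length amounts of ring components are
measured in 30° arcs of an annular band around the fitted ring, referenced
to the initial ingression axis.  The photobleach (pulse-chase) analysis
differences a control and an after-bleach per-unit-length curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .geometry import RingFit, IngressionAxis

__all__ = [
    "AttenuationModel",
    "RingIntensityProfile",
    "AttenuationFitError",
    "fit_attenuation",
    "correct_attenuation",
    "apply_attenuation",
    "ring_intensity",
    "bleach_difference",
]


class AttenuationFitError(RuntimeError):
    """Profiles do not decay; no attenuation model can be fitted."""


@dataclass
class AttenuationModel:
    """Shared-depth exponential attenuation, per-embryo surface amplitude."""

    z_att: float                 # µm
    i0: Tuple[float, ...] = ()   # per-embryo surface intensities, a.u.

    def __post_init__(self) -> None:
        if not self.z_att > 0:
            raise ValueError("z_att must be positive")
        if any(i <= 0 for i in self.i0):
            raise ValueError("surface intensities must be positive")


def fit_attenuation(
    profiles: Sequence[Tuple[np.ndarray, np.ndarray]],
) -> AttenuationModel:
    """Joint exponential fit of z-profiles with one shared depth.

    Each profile is ``(z_um, intensity)`` with background already
    subtracted.  Per-profile amplitudes ``I0_i`` and a single ``z_att`` are
    estimated by nonlinear least squares; residuals are scaled per profile
    so bright embryos do not dominate.  Raises
    :class:`AttenuationFitError` when the pooled profiles do not decay.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    zs = [np.asarray(z, dtype=float) for z, _ in profiles]
    ys = [np.asarray(y, dtype=float) for _, y in profiles]

    # initialization from a pooled log-linear regression
    z_all = np.concatenate(zs)
    y_all = np.concatenate(ys)
    pos = y_all > 0
    slope, _ = np.polyfit(z_all[pos], np.log(y_all[pos]), 1)
    if slope >= 0:
        raise AttenuationFitError("profiles do not decay with depth")
    z0 = -1.0 / slope

    scales = [max(float(np.sqrt(np.mean(y**2))), 1e-12) for y in ys]

    def unpack(p):
        return p[:-1], p[-1]

    def resid(p):
        log_i0, z_att = unpack(p)
        blocks = []
        for z, y, li, s in zip(zs, ys, log_i0, scales):
            blocks.append((y - np.exp(li) * np.exp(-z / z_att)) / s)
        return np.concatenate(blocks)

    p0 = [math.log(max(float(y[0]), 1e-6)) for y in ys] + [z0]
    lo = [-30.0] * len(ys) + [0.1]
    hi = [30.0] * len(ys) + [1e4]
    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
    log_i0, z_att = unpack(sol.x)
    return AttenuationModel(z_att=float(z_att), i0=tuple(float(np.exp(v)) for v in log_i0))


def correct_attenuation(
    stack: np.ndarray, model: AttenuationModel, dz_um: float, z0_um: float = 0.0
) -> np.ndarray:
    """Multiply each plane by ``exp(+z/z_att)`` to undo depth attenuation."""
    stack = np.asarray(stack, dtype=float)
    z = z0_um + np.arange(stack.shape[0]) * dz_um
    return stack * np.exp(z / model.z_att)[:, None, None]


def apply_attenuation(
    stack: np.ndarray, model: AttenuationModel, dz_um: float, z0_um: float = 0.0
) -> np.ndarray:
    """Inverse of :func:`correct_attenuation` (exact round trip)."""
    stack = np.asarray(stack, dtype=float)
    z = z0_um + np.arange(stack.shape[0]) * dz_um
    return stack * np.exp(-z / model.z_att)[:, None, None]


@dataclass
class RingIntensityProfile:
    """Per-unit-length ring fluorescence in 30° arcs (a.u./µm)."""

    t_hat: float
    arc_deg: float
    per_unit_length: np.ndarray    # one value per arc, index 0 at the axis
    total: float                   # a.u., integral around the perimeter
    background: float              # a.u. per pixel, subtracted estimate
    partial: bool = False          # ring/band clipped by the stack border

    @property
    def mean_per_unit_length(self) -> float:
        return float(np.nanmean(self.per_unit_length))


def ring_intensity(
    stack: np.ndarray,
    ring: RingFit,
    axis: IngressionAxis,
    model: AttenuationModel,
    pixel_size: float,
    dz_um: float,
    band_half_width_um: float = 0.5,
    arc_deg: float = 30.0,
    t_hat: float = float("nan"),
    background_box_um: float = 11.0,
    background_gap_um: float = 2.0,
) -> RingIntensityProfile:
    """Quantify per-unit-length ring fluorescence from a division-plane stack.

    The stack (axes z, lateral, AP) is background-subtracted per plane —
    the estimate comes from two ``background_box_um``-square boxes offset
    ``background_gap_um`` from the division plane on either side — then
    attenuation-corrected, and the intensity inside an annular band of
    half-width ``band_half_width_um`` around the fitted circle in the
    end-on (lateral, depth) plane is summed per ``arc_deg`` arc.  Arc sums
    are divided by arc length; the total is the sum of all arc contents.
    Arc index 0 starts at the ingression axis, increasing clockwise.
    """
    stack = np.asarray(stack, dtype=float)
    nz, ny, nx = stack.shape

    # per-plane background from boxes flanking the division plane (AP axis);
    # subtracted before the attenuation correction so the camera offset is
    # not amplified with depth
    box_px = max(1, int(round(background_box_um / pixel_size)))
    gap_px = int(round(background_gap_um / pixel_size))
    x_plane = nx // 2
    y0 = max(0, ny // 2 - box_px // 2)
    y1 = min(ny, ny // 2 + box_px // 2)
    left = slice(max(0, x_plane - gap_px - box_px), max(0, x_plane - gap_px))
    right = slice(min(nx, x_plane + gap_px), min(nx, x_plane + gap_px + box_px))
    regions = [stack[:, y0:y1, sl] for sl in (left, right) if sl.stop > sl.start]
    if regions:
        per_plane_bg = np.mean(
            [r.reshape(nz, -1).mean(axis=1) for r in regions], axis=0
        )
    else:
        per_plane_bg = np.zeros(nz)
    background = float(per_plane_bg.mean())
    stack = stack - per_plane_bg[:, None, None]
    stack = correct_attenuation(stack, model, dz_um)

    # end-on image: sum over a thin AP window about the division plane
    win = max(1, int(round(1.0 / pixel_size)))
    end_on = stack[:, :, x_plane - win: x_plane + win + 1].sum(axis=2)
    bg_per_px = 0.0

    cy, cz = ring.center_end_on if ring.center_end_on else (ny * pixel_size / 2.0, nz * dz_um / 2.0)
    # centers stored as offsets from the image center for rendered stacks
    cy = ny * pixel_size / 2.0 + (ring.center_end_on[0] if ring.center_end_on else 0.0)
    cz = nz * dz_um / 2.0 + (ring.center_end_on[1] if ring.center_end_on else 0.0)

    Z, Y = np.meshgrid(np.arange(nz) * dz_um, np.arange(ny) * pixel_size, indexing="ij")
    dist = np.hypot(Y - cy, Z - cz)
    in_band = np.abs(dist - ring.radius) <= band_half_width_um
    # angle measured from the ingression axis, clockwise
    phi = (np.degrees(np.arctan2(Y - cy, -(Z - cz))) - axis.angle) % 360.0

    n_arcs = int(round(360.0 / arc_deg))
    per_len = np.zeros(n_arcs)
    arc_len = ring.radius * math.radians(arc_deg)
    for a in range(n_arcs):
        sel = in_band & (phi >= a * arc_deg) & (phi < (a + 1) * arc_deg)
        per_len[a] = (end_on[sel] - bg_per_px).sum() / arc_len

    partial = bool(
        (cz - ring.radius - band_half_width_um < 0)
        or (cz + ring.radius + band_half_width_um > nz * dz_um)
        or (cy - ring.radius - band_half_width_um < 0)
        or (cy + ring.radius + band_half_width_um > ny * pixel_size)
    )
    total = float(per_len.sum() * arc_len)
    return RingIntensityProfile(
        t_hat=t_hat,
        arc_deg=arc_deg,
        per_unit_length=per_len,
        total=total,
        background=background,
        partial=partial,
    )


def bleach_difference(
    control: Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]],
    bleached: Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-unit-length amount of bleached (dark) subunits in the ring.

    Both inputs are ``(t_hat, per_unit_length, sd_or_None)``.  The curves
    are linearly interpolated onto the overlap of their time ranges and
    differenced pointwise; uncertainties (when given, SDs of the averaged
    curves) combine in quadrature, matching an SEM-of-the-difference
    convention.  Disjoint time ranges raise ``ValueError``.
    """
    tc, yc, sc = control
    tb, yb, sb = bleached
    tc = np.asarray(tc, dtype=float)
    tb = np.asarray(tb, dtype=float)
    lo = max(tc.min(), tb.min())
    hi = min(tc.max(), tb.max())
    if not lo < hi:
        raise ValueError("control and bleached curves do not overlap in time")
    grid = np.union1d(tc[(tc >= lo) & (tc <= hi)], tb[(tb >= lo) & (tb <= hi)])
    yci = np.interp(grid, tc, np.asarray(yc, dtype=float))
    ybi = np.interp(grid, tb, np.asarray(yb, dtype=float))
    diff = yci - ybi
    if sc is not None and sb is not None:
        sci = np.interp(grid, tc, np.asarray(sc, dtype=float))
        sbi = np.interp(grid, tb, np.asarray(sb, dtype=float))
        err = np.sqrt(sci**2 + sbi**2)
    else:
        err = np.full_like(diff, np.nan)
    return grid, diff, err
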