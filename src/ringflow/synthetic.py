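"""Synthetic embryos with known ground truth.

Every downstream stage (geometry, alignment, flow mapping, surface-area
bookkeeping, photometry, model fitting) is exercised on data produced here,
so the generator encodes the study conditions explicitly: embryo radius
14.7 ± 0.7 µm, cytokinesis duration 200 ± 30 s, a 10 µm wide uniform
cortical-compression zone (half-width w = 5 µm), exponential depth
attenuation with characteristic depth 15 µm, asymmetric ring closure along
a random ingression axis, and the compression-feedback closed forms for the
ring trajectory, the cortical flow speed and per-unit-length component
amounts.  All randomness flows from one seeded generator per embryo, so a
fixed seed reproduces every artifact bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import model as fm
from .alignment import fit_t0_tck_line
from .flowmap import FlowField
from .geometry import RingFit

__all__ = [
    "EmbryoSpec",
    "GroundTruth",
    "tau_for_duration",
    "default_model_params",
    "make_ring_trajectory",
    "make_flow_field",
    "render_cortex_movie",
    "render_division_plane_stack",
    "render_embryo_stack",
    "make_attenuation_profiles",
    "make_population",
    "trajectory_frame",
]


@dataclass(frozen=True)
class EmbryoSpec:
    """Ground-truth description of one synthetic embryo.

    Defaults are the population means of the one-cell *C. elegans* embryo:
    radius 14.7 µm, cytokinesis duration 200 s, compression-zone full width
    2w = 10 µm, attenuation depth 15 µm.
    """

    embryo_radius: float = 14.7          # µm
    cytokinesis_duration: float = 200.0  # s
    onset_time: float = 60.0             # s, absolute time of cytokinesis onset
    ingression_axis_angle: float = 0.0   # degrees in [0, 360)
    zone_half_width: float = 5.0         # w, µm
    attenuation_depth: float = 15.0      # z_att, µm
    pixel_size: float = 0.16             # µm/px (cortex / division-plane camera)
    foci_density: float = 0.3            # myosin puncta per µm²
    noise_sd: float = 0.05               # fractional intensity noise
    seed: int = 0
    half_length: float = 25.0            # µm, embryo half-length along AP
    center_drift: float = 0.3            # asymmetric-closure drift amplitude, ×(R_emb − R)
    flow_asymmetry: float = 0.3          # top/bottom flow modulation amplitude

    def __post_init__(self) -> None:
        if min(self.embryo_radius, self.cytokinesis_duration, self.zone_half_width,
               self.pixel_size, self.attenuation_depth) <= 0:
            raise ValueError("lengths, durations and depths must be positive")
        if not 0.0 <= self.ingression_axis_angle < 360.0:
            raise ValueError("ingression_axis_angle must lie in [0, 360)")
        if self.noise_sd < 0 or self.foci_density < 0:
            raise ValueError("noise_sd and foci_density must be non-negative")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), salt]))


@lru_cache(maxsize=32)
def _tck_per_tau(rbar_ini: float = 1.1) -> Tuple[float, float]:
    """(t_CK/tau, tbar of onset) implied by the line-fit time definition.

    The generator defines t0 and t_CK exactly the way the alignment stage
    measures them: a line through the closed-form trajectory between 30% and
    80% closure, extrapolated to Rbar = 1 and 0.
    """
    params = fm.ModelParams.from_timescale(1.0, rbar_ini=rbar_ini)
    tbar = np.linspace(-3.0, 1.6, 4000)
    rbar = fm.ring_size_closed_form(params, tbar)
    frame = fit_t0_tck_line(tbar, rbar)
    return frame.t_ck, frame.t0


def tau_for_duration(t_ck: float, rbar_ini: float = 1.1) -> float:
    """Feedback timescale tau giving a line-fit cytokinesis duration t_CK."""
    span, _ = _tck_per_tau(rbar_ini)
    return t_ck / span


def default_model_params(spec: EmbryoSpec, alpha_over_beta: float = 10.0) -> fm.ModelParams:
    """Model parameters matched to the embryo's cytokinesis duration."""
    return fm.ModelParams.from_timescale(
        tau_for_duration(spec.cytokinesis_duration),
        alpha_over_beta=alpha_over_beta,
        zone_half_width=spec.zone_half_width,
    )


@dataclass
class TrajectoryFrame:
    """Absolute-time bookkeeping linking t (s), t_hat and tbar."""

    tau: float
    t_half: float   # absolute time of half closure, s
    t0: float       # absolute onset, s
    t_ck: float

    def tbar(self, t) -> np.ndarray:
        return (np.asarray(t, dtype=float) - self.t_half) / self.tau

    def t_hat(self, t) -> np.ndarray:
        return (np.asarray(t, dtype=float) - self.t0) / self.t_ck


def trajectory_frame(spec: EmbryoSpec, params: fm.ModelParams) -> TrajectoryFrame:
    span, tbar0 = _tck_per_tau(params.rbar_ini)
    tau = params.tau
    t_half = spec.onset_time - tau * tbar0
    return TrajectoryFrame(tau=tau, t_half=t_half, t0=spec.onset_time, t_ck=tau * span)


@dataclass
class GroundTruth:
    """Generator-side truth for one embryo: trajectory, flow, intensities."""

    spec: EmbryoSpec
    params: fm.ModelParams
    frame: TrajectoryFrame = field(init=False)
    anillin: fm.ComponentParams = field(init=False)

    def __post_init__(self) -> None:
        self.frame = trajectory_frame(self.spec, self.params)
        # generic second component: loaded at half the myosin concentration
        # with a non-exponential baseline
        c_rho = 0.5 * self.params.m_rho
        amp = self.params.alpha * c_rho / self.params.beta * math.log(2 * self.params.rbar_ini)
        self.anillin = fm.ComponentParams(c_rho=c_rho, c0_ring=1.0 + amp)

    # -- trajectory -------------------------------------------------------
    def rbar(self, t, clamp: bool = True) -> np.ndarray:
        r = fm.ring_size_closed_form(self.params, self.frame.tbar(t))
        return np.minimum(r, 1.0) if clamp else r

    def radius(self, t, clamp: bool = True) -> np.ndarray:
        return self.spec.embryo_radius * self.rbar(t, clamp=clamp)

    def center_offset(self, t) -> np.ndarray:
        """Signed in-plane ring-center offset along the ingression axis (µm).

        The offset grows with ingression depth, points toward the side that
        furrows first, and crosses the embryo axis at the closure midpoint.
        """
        t_hat = self.frame.t_hat(t)
        depth = self.spec.embryo_radius - self.radius(t)
        return self.spec.center_drift * depth * (1.0 - 2.0 * np.clip(t_hat, 0.0, 1.0))

    # -- model observables ------------------------------------------------
    def mring(self, t) -> np.ndarray:
        return fm.mring_closed_form(self.params, np.asarray(t) - self.frame.t_half)

    def vflow(self, t) -> np.ndarray:
        """Per-side compression-driven inflow speed alpha*M_ring/2, µm/s."""
        return self.params.alpha * self.mring(t) / 2.0

    def vpull(self, t) -> np.ndarray:
        """Per-side flank speed feeding division-plane growth, µm/s.

        Equal to Rbar·(−dR/dt) so that 4π R_emb v_pull matches the growth
        rate of the (two-sided) division-plane area; zero before ingression.
        """
        t = np.asarray(t, dtype=float)
        rb = self.rbar(t, clamp=False)
        rate = fm.per_length_constriction_rate(self.params, self.frame.tbar(t)) / self.params.tau
        v = rb**2 * self.spec.embryo_radius * rate
        return np.where(rb < 1.0, v, 0.0)

    def constriction_rate_series(self, t) -> np.ndarray:
        """Per-unit-length constriction rate −(1/R)dR/dt, 1/s."""
        return fm.per_length_constriction_rate(self.params, self.frame.tbar(t)) / self.params.tau

    def compression_rate_series(self, t) -> np.ndarray:
        """Per-unit-length cortical compression rate alpha*M_ring = 2 v_flow, µm/s."""
        return self.params.alpha * self.mring(t)

    def myosin_series(self, t) -> np.ndarray:
        return self.mring(t)

    def anillin_series(self, t) -> np.ndarray:
        return fm.component_closed_form(self.params, self.anillin, self.frame.tbar(t))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def make_ring_trajectory(
    spec: EmbryoSpec,
    params: Optional[fm.ModelParams] = None,
    times: Optional[Sequence[float]] = None,
    clamp: bool = True,
    noise_sd_um: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> List[RingFit]:
    """Closed-form asymmetric ring trajectory sampled at ``times``.

    ``R(t) = R_emb * Rbar_ini * (2 Rbar_ini)^(−exp(tbar))`` with ``tbar``
    referenced to the half-closure point implied by the embryo's onset time
    and duration; radii are clamped at the embryo radius before ingression.
    The ring center drifts linearly along the ingression axis (see
    :meth:`GroundTruth.center_offset`).  Optional additive Gaussian noise
    (sd ``noise_sd_um``) perturbs radius and center, emulating boundary
    measurement error.
    """
    params = params or default_model_params(spec)
    gt = GroundTruth(spec, params)
    if times is None:
        times = np.arange(spec.onset_time - 36.0, gt.frame.t0 + gt.frame.t_ck + 1.0, 36.0)
    times = np.asarray(times, dtype=float)
    if params.tau <= 0 or params.rbar_ini <= 0.5:
        raise fm.InvalidParameterError("invalid trajectory parameters")

    rng = rng or spec.rng(salt=1)
    radii = gt.radius(times, clamp=clamp)
    offsets = gt.center_offset(times)
    if noise_sd_um > 0:
        radii = radii + rng.normal(0.0, noise_sd_um, radii.shape)
        offsets = offsets + rng.normal(0.0, noise_sd_um, offsets.shape)
    ang = math.radians(spec.ingression_axis_angle)
    u = np.array([math.sin(ang), math.cos(ang)])  # (lateral, depth)
    out = []
    for t, r, d in zip(times, radii, offsets):
        rb = float(np.clip(r / spec.embryo_radius, 0.0, 1.2))
        if rb <= 0:
            continue
        out.append(
            RingFit(
                time=float(t),
                radius=float(max(r, 1e-6)),
                center=(0.0, float(d)),
                rbar=rb,
                residual=abs(noise_sd_um),
                center_end_on=(float(d * u[0]), float(d * u[1])),
            )
        )
    return out


def trajectory_table(rings: Sequence[RingFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": [r.time for r in rings],
            "radius_um": [r.radius for r in rings],
            "center_x_um": [r.center_end_on[0] for r in rings],
            "center_y_um": [r.center_end_on[1] for r in rings],
            "rbar": [r.rbar for r in rings],
        }
    )


# ---------------------------------------------------------------------------
# flow fields
# ---------------------------------------------------------------------------

def make_flow_field(
    spec: EmbryoSpec,
    params: Optional[fm.ModelParams] = None,
    t: float = 0.0,
    x: Optional[np.ndarray] = None,
    theta: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> FlowField:
    """Cortical velocity field at absolute time ``t``.

    AP profile per side: constant flank speed ``v_pull + v_flow`` outside
    the compression zone, a linear ramp through zero across ``|x| <= w``
    (uniform compression, strain rate −v_flow/w), and a linear taper to zero
    over the polar cap (``|x| > 0.75 * half_length``) where surface is
    gained.  The top/bottom asymmetry follows the ring-center drift:
    vectors scale with ``1 + a*(1 − 2 t_hat)*cos(theta)``.  Optional
    Gaussian vector noise has sd ``noise_sd * (v_pull + v_flow)``.
    """
    params = params or default_model_params(spec)
    gt = GroundTruth(spec, params)
    if x is None:
        x = np.arange(-14.5, 14.5 + 1e-9, 1.0)
    if theta is None:
        theta = np.arange(5.0, 360.0, 10.0)
    X, TH = np.meshgrid(np.asarray(x, dtype=float), np.asarray(theta, dtype=float), indexing="ij")

    v_flow = float(gt.vflow(t))
    v_pull = float(gt.vpull(t))
    w = spec.zone_half_width
    pol = 0.75 * spec.half_length
    ax = np.abs(X)
    mag = np.where(
        ax <= w,
        v_pull + v_flow * ax / w,
        np.where(
            ax <= pol,
            v_pull + v_flow,
            (v_pull + v_flow) * np.clip((spec.half_length - ax) / (spec.half_length - pol), 0.0, 1.0),
        ),
    )
    # inside the zone the pull component also ramps (cortex at the furrow tip
    # moves with the ring edge); keep the spec'd uniform strain −v_flow/w by
    # ramping only the compression part
    t_hat = float(gt.frame.t_hat(t))
    asym = 1.0 + spec.flow_asymmetry * np.clip(1.0 - 2.0 * t_hat, -1.0, 1.0) * np.cos(
        np.radians(TH - spec.ingression_axis_angle)
    )
    vx = -np.sign(X) * mag * asym
    vtheta = np.zeros_like(vx)
    if noise_sd > 0:
        rng = rng or spec.rng(salt=2)
        scale = noise_sd * max(v_pull + v_flow, 1e-12)
        vx = vx + rng.normal(0.0, scale, vx.shape)
        vtheta = vtheta + rng.normal(0.0, scale, vtheta.shape)
    return FlowField(x=X.ravel(), theta=TH.ravel(), vx=vx.ravel(), vtheta=vtheta.ravel())


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _stamp_gaussian(img: np.ndarray, y: float, x: float, amp: float, sigma_px: float) -> None:
    """Add a unit-integral Gaussian spot scaled by ``amp`` at (y, x) px."""
    r = max(2, int(math.ceil(4.0 * sigma_px)))
    iy, ix = int(round(y)), int(round(x))
    y0, y1 = iy - r, iy + r + 1
    x0, x1 = ix - r, ix + r + 1
    if y1 <= 0 or x1 <= 0 or y0 >= img.shape[0] or x0 >= img.shape[1]:
        return
    yy_full = np.arange(y0, y1)
    xx_full = np.arange(x0, x1)
    g = np.exp(
        -((yy_full[:, None] - y) ** 2 + (xx_full[None, :] - x) ** 2)
        / (2.0 * sigma_px**2)
    )
    g *= amp / g.sum()  # discrete normalization: stamped mass equals amp
    ys = slice(max(0, -y0), g.shape[0] - max(0, y1 - img.shape[0]))
    xs = slice(max(0, -x0), g.shape[1] - max(0, x1 - img.shape[1]))
    img[max(y0, 0): min(y1, img.shape[0]), max(x0, 0): min(x1, img.shape[1])] += g[ys, xs]


def render_cortex_movie(
    spec: EmbryoSpec,
    vx_of_xt: Callable[[np.ndarray, float], np.ndarray],
    t_start: float,
    t_end: float,
    patch_um: Tuple[float, float] = (15.0, 30.0),
    sigma_um: float = 0.3,
    frame_interval: float = 2.0,
    frames_per_burst: int = 15,
    burst_period: float = 36.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, List[np.ndarray], int]:
    """Movie of myosin foci advected by the AP flow on a cortical patch.

    Frames come in bursts of ``frames_per_burst`` at ``frame_interval`` s,
    repeating every ``burst_period`` s — i.e. an ~6 s gap in every burst
    cycle while the division-plane z-stack is acquired.  Foci are seeded
    from a Poisson process at ``spec.foci_density`` and advected with the
    field; foci leaving the patch are dropped and counted.  Gaussian pixel
    noise has fractional sd ``spec.noise_sd``.

    Returns ``(frame_times, frames, n_dropped)``.
    """
    if spec.foci_density <= 0:
        raise ValueError("foci_density must be positive to render a movie")
    rng = rng or spec.rng(salt=3)
    h_um, w_um = patch_um
    px = spec.pixel_size
    ny, nx = int(round(h_um / px)), int(round(w_um / px))
    area = h_um * w_um
    n_foci = rng.poisson(spec.foci_density * area)
    xs = rng.uniform(-w_um / 2.0, w_um / 2.0, n_foci)  # AP position, plane at 0
    ys = rng.uniform(0.0, h_um, n_foci)
    amps = rng.uniform(800.0, 1600.0, n_foci)

    times = []
    t = t_start
    while t <= t_end + 1e-9:
        burst_t = (t - t_start) % burst_period
        if burst_t < frames_per_burst * frame_interval - 1e-9:
            times.append(t)
        t += frame_interval
    times = np.asarray(times)

    frames = []
    dropped = 0
    t_prev = times[0]
    for t in times:
        # advect in sub-steps across the gap as well
        n_sub = max(1, int(round((t - t_prev) / 0.5)))
        for _ in range(n_sub):
            dt = (t - t_prev) / n_sub
            if dt > 0:
                xs = xs + vx_of_xt(xs, t) * dt
        t_prev = t
        inside = (xs > -w_um / 2) & (xs < w_um / 2)
        dropped += int((~inside).sum())
        xs, ys, amps = xs[inside], ys[inside], amps[inside]
        img = np.zeros((ny, nx))
        for xf, yf, af in zip(xs, ys, amps):
            _stamp_gaussian(img, yf / px, (xf + w_um / 2) / px, af, sigma_um / px)
        img = img * (1.0 + rng.normal(0.0, spec.noise_sd, img.shape)) + 100.0
        frames.append(np.rint(np.clip(img, 0, 65535)).astype(np.uint16))
    return times, frames, dropped


def render_division_plane_stack(
    spec: EmbryoSpec,
    ring: RingFit,
    intensity_per_length: float = 500.0,
    n_planes: int = 40,
    dz_um: float = 0.5,
    sigma_um: float = 0.2,
    background: float = 100.0,
    image_um: Tuple[float, float] = (36.0, 40.0),
    apply_attenuation: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """End-on z-stack of the contractile ring with depth attenuation.

    The ring is a circle in the (lateral, depth) plane centered on the
    embryo axis plus the ring's in-plane offset; each z-plane receives the
    two circle intersections as Gaussian spots whose integrals equal the
    fluorophore content of the circle arc inside the plane's depth slab
    (``intensity_per_length`` a.u./µm).  Plane intensities are multiplied by
    ``exp(-z/z_att)``; a constant background offset and multiplicative
    Gaussian noise (sd ``spec.noise_sd``) are added.  Deterministic for a
    given spec seed.
    """
    if ring.radius >= spec.embryo_radius + 1e-9:
        raise ValueError("ring radius must be smaller than the embryo radius")
    rng = rng or spec.rng(salt=4)
    px = spec.pixel_size
    h_um, w_um = image_um
    ny, nx = int(round(h_um / px)), int(round(w_um / px))
    x_plane = nx / 2.0
    cy_um = h_um / 2.0 + (ring.center_end_on[0] if ring.center_end_on else 0.0)
    cz_um = n_planes * dz_um / 2.0 + (ring.center_end_on[1] if ring.center_end_on else 0.0)
    R = ring.radius

    stack = np.zeros((n_planes, ny, nx))
    for k in range(n_planes):
        z = k * dz_um
        u0 = np.clip((z - dz_um / 2.0 - cz_um) / R, -1.0, 1.0)
        u1 = np.clip((z + dz_um / 2.0 - cz_um) / R, -1.0, 1.0)
        arc = R * (math.asin(u1) - math.asin(u0))  # per side, µm in this slab
        if arc <= 0:
            continue
        disc = R**2 - (z - cz_um) ** 2
        half = math.sqrt(max(disc, 0.0))
        for sgn in (-1.0, 1.0):
            y_um = cy_um + sgn * half
            _stamp_gaussian(
                stack[k], y_um / px, x_plane, intensity_per_length * arc, sigma_um / px
            )
        if half < 2 * sigma_um:  # near-tangent planes: the two spots merge
            pass
    if apply_attenuation:
        z = (np.arange(n_planes) * dz_um)[:, None, None]
        stack = stack * np.exp(-z / spec.attenuation_depth)
    stack = stack * (1.0 + rng.normal(0.0, spec.noise_sd, stack.shape)) + background
    return np.rint(np.clip(stack, 0, 65535)).astype(np.uint16)


def render_embryo_stack(
    spec: EmbryoSpec,
    rotation_deg: float = 0.0,
    pixel_size: float = 0.1,
    n_planes: int = 15,
    dz_um: float = 2.0,
    interior: float = 300.0,
    exterior: float = 50.0,
    rim_um: float = 1.0,
    rim_boost: Tuple[float, float] = (0.3, 0.15),
    margin_um: float = 6.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Whole-embryo z-stack: a cylinder with spherical caps, rotated in-plane.

    The interior is uniformly bright against a dim exterior; a thin cortical
    rim is brighter on the anterior half (``rim_boost[0]``×interior) than
    the posterior (``rim_boost[1]``) so orientation can identify the
    anterior pole.  At the default 0.1 µm/px a mean-size embryo's mid-plane
    mask covers ~115,000 px², inside the expected-area acceptance window.
    Multiplicative Gaussian noise has sd ``spec.noise_sd``.
    """
    rng = rng or spec.rng(salt=5)
    Rc = spec.embryo_radius
    L = spec.half_length
    # square frame so the embryo fits at any in-plane rotation
    h_um = w_um = 2 * (L + margin_um)
    ny, nx = int(round(h_um / pixel_size)), int(round(w_um / pixel_size))
    yy = (np.arange(ny) - ny / 2.0 + 0.5) * pixel_size
    xx = (np.arange(nx) - nx / 2.0 + 0.5) * pixel_size
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    a = math.radians(rotation_deg)
    # de-rotate: at rotation 0 the AP axis is vertical with anterior at top
    ap = math.cos(a) * Y + math.sin(a) * X
    lat = -math.sin(a) * Y + math.cos(a) * X

    Lc = L - Rc  # cylinder half-length
    axial = np.maximum(np.abs(ap) - Lc, 0.0)
    stack = np.empty((n_planes, ny, nx))
    for k in range(n_planes):
        z = (k - (n_planes - 1) / 2.0) * dz_um
        rr = np.sqrt(lat**2 + axial**2 + z**2)
        dist_to_boundary = Rc - rr
        inside = dist_to_boundary >= 0
        img = np.full((ny, nx), exterior)
        img[inside] = interior
        rim = inside & (dist_to_boundary <= rim_um)
        boost = np.where(ap < 0, rim_boost[0], rim_boost[1]) * interior
        img[rim] += boost[rim]
        stack[k] = img
    stack = stack * (1.0 + rng.normal(0.0, spec.noise_sd, stack.shape))
    return np.rint(np.clip(stack, 0, 65535)).astype(np.uint16)


def make_attenuation_profiles(
    n: int = 13,
    depth_um: float = 15.0,
    z_um: Optional[np.ndarray] = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Synthetic division-plane z-intensity profiles, ``I = I0 e^(−z/z_att)``.

    Each profile gets its own surface amplitude (uniform in 200-1000 a.u.)
    and multiplicative Gaussian noise of fractional sd ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    z = np.arange(0.0, 20.0, 0.5) if z_um is None else np.asarray(z_um, dtype=float)
    out = []
    for _ in range(n):
        i0 = rng.uniform(200.0, 1000.0)
        profile = i0 * np.exp(-z / depth_um)
        profile = profile * (1.0 + rng.normal(0.0, noise_sd, z.shape))
        out.append((z.copy(), profile))
    return out


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def make_population(
    n: int,
    spec_means: Optional[EmbryoSpec] = None,
    cv: Optional[float] = None,
    seed: int = 0,
    radius_sd: float = 0.7,
    duration_sd: float = 30.0,
    onset_sd: float = 10.0,
) -> List[Tuple[EmbryoSpec, GroundTruth]]:
    """Draw a reproducible population of synthetic embryos.

    Radii and durations are normal around the means of ``spec_means`` with
    the observed population SDs (0.7 µm and 30 s) by default; a numeric
    ``cv`` replaces both SDs with ``cv * mean``.  Onset times are normal
    (sd 10 s); ingression-axis angles are uniform on [0, 360).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if cv is not None and cv < 0:
        raise ValueError("cv must be non-negative")
    spec_means = spec_means or EmbryoSpec()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1000]))
    if cv is not None:
        radius_sd = cv * spec_means.embryo_radius
        duration_sd = cv * spec_means.cytokinesis_duration
        onset_sd = cv * max(abs(spec_means.onset_time), 1.0)
    child_seeds = np.random.SeedSequence([int(seed), 2000]).generate_state(n) % (2**31)

    out = []
    for i in range(n):
        radius = float(np.clip(rng.normal(spec_means.embryo_radius, radius_sd), 5.0, None))
        duration = float(np.clip(rng.normal(spec_means.cytokinesis_duration, duration_sd), 60.0, None))
        onset = float(rng.normal(spec_means.onset_time, onset_sd))
        angle = float(rng.uniform(0.0, 360.0))
        spec = EmbryoSpec(
            embryo_radius=radius,
            cytokinesis_duration=duration,
            onset_time=onset,
            ingression_axis_angle=angle,
            zone_half_width=spec_means.zone_half_width,
            attenuation_depth=spec_means.attenuation_depth,
            pixel_size=spec_means.pixel_size,
            foci_density=spec_means.foci_density,
            noise_sd=spec_means.noise_sd,
            seed=int(child_seeds[i]),
            half_length=spec_means.half_length * radius / spec_means.embryo_radius,
            center_drift=spec_means.center_drift,
            flow_asymmetry=spec_means.flow_asymmetry,
        )
        out.append((spec, GroundTruth(spec, default_model_params(spec))))
    return out


def ground_truth_sidecar(spec: EmbryoSpec, gt: GroundTruth) -> str:
    """JSON sidecar with the embryo's ground truth (for written artifacts)."""
    payload = {
        "spec": asdict(spec),
        "tau_s": gt.frame.tau,
        "t0_s": gt.frame.t0,
        "t_ck_s": gt.frame.t_ck,
        "t_half_s": gt.frame.t_half,
        "alpha": gt.params.alpha,
        "beta": gt.params.beta,
        "m_rho": gt.params.m_rho,
        "rbar_ini": gt.params.rbar_ini,
    }
    return json.dumps(payload, indent=2)
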