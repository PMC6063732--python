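"""Averaged dimensionless 4-D cortical flow maps.

A flow field is a set of velocity vectors sampled on the visible cortex,
indexed by AP position ``x`` (µm from the division plane, negative =
anterior) and angular position ``theta`` (degrees from the initial
ingression axis).  Per-embryo fields are normalized by embryo size and
cytokinesis rate (``fbar = (t_CK / R_emb) * f``), mirror-folded onto
``theta in [0, 180]`` to remove the transient rotational component, and
averaged across embryos on a fixed ``(t_hat, x, theta)`` grid with coverage
counts.  Cells never visited stay missing (NaN) rather than zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
from skimage.feature import match_template

__all__ = [
    "FlowField",
    "FlowMap",
    "estimate_flow",
    "mirror_fold",
    "normalize_and_average",
    "ap_velocity_profile",
    "DEFAULT_X_EDGES",
    "DEFAULT_THETA_EDGES",
    "DEFAULT_THAT_EDGES",
]

DEFAULT_X_EDGES = np.arange(-15.0, 15.0 + 1e-9, 1.0)
DEFAULT_THETA_EDGES = np.arange(0.0, 180.0 + 1e-9, 10.0)
DEFAULT_THAT_EDGES = np.arange(-0.3, 1.1 + 1e-9, 0.05)


@dataclass
class FlowField:
    """Sampled cortical velocity vectors at one time point.

    ``vx`` is the AP component (µm/s, positive toward the posterior) and
    ``vtheta`` the angular component; dimensionless fields reuse the same
    container after scaling.
    """

    x: np.ndarray
    theta: np.ndarray
    vx: np.ndarray
    vtheta: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.vx = np.atleast_1d(np.asarray(self.vx, dtype=float))
        self.vtheta = np.atleast_1d(np.asarray(self.vtheta, dtype=float))
        n = self.x.size
        if not (self.theta.size == self.vx.size == self.vtheta.size == n):
            raise ValueError("all sample arrays must have equal length")
        if not np.all(np.isfinite(self.vx)) or not np.all(np.isfinite(self.vtheta)):
            raise ValueError("flow vectors must be finite")

    def scaled(self, factor: float) -> "FlowField":
        return FlowField(self.x, self.theta, self.vx * factor, self.vtheta * factor)


def mirror_fold(field: FlowField) -> FlowField:
    """Fold angular positions above 180° onto [0, 180].

    ``theta > 180`` maps to ``360 - theta`` with the angular velocity
    component negated; the AP component is unchanged.  Averaging a field
    with its fold removes any rigid rotational flow, which is why the early
    rotational transient needs no separate detrending.  Idempotent.
    """
    theta = np.mod(field.theta, 360.0)
    flip = theta > 180.0
    new_theta = np.where(flip, 360.0 - theta, theta)
    new_vtheta = np.where(flip, -field.vtheta, field.vtheta)
    return FlowField(field.x, new_theta, field.vx, new_vtheta)


@dataclass
class FlowMap:
    """Population-average dimensionless flow on a ``(t_hat, x, theta)`` grid."""

    t_hat_edges: np.ndarray
    x_edges: np.ndarray
    theta_edges: np.ndarray
    fx: np.ndarray        # (nt, nx, ntheta) mean dimensionless AP component
    ftheta: np.ndarray
    count: np.ndarray     # embryos contributing per cell
    r_emb: float = float("nan")   # population mean embryo radius, µm
    t_ck: float = float("nan")    # population mean cytokinesis time, s
    low_coverage_threshold: int = 5

    @property
    def t_hat_centers(self) -> np.ndarray:
        return 0.5 * (self.t_hat_edges[:-1] + self.t_hat_edges[1:])

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    @property
    def low_coverage(self) -> np.ndarray:
        return (self.count > 0) & (self.count < self.low_coverage_threshold)

    def t_index(self, t_hat: float) -> int:
        i = int(np.searchsorted(self.t_hat_edges, t_hat, side="right")) - 1
        if not 0 <= i < self.fx.shape[0]:
            raise ValueError(f"t_hat={t_hat} outside map coverage")
        return i


def _bin_embryo(
    times_hat: np.ndarray,
    fields: Sequence[FlowField],
    t_edges: np.ndarray,
    x_edges: np.ndarray,
    th_edges: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean folded field of one embryo on the grid; NaN where unsampled."""
    shape = (len(t_edges) - 1, len(x_edges) - 1, len(th_edges) - 1)
    acc_x = np.zeros(shape)
    acc_t = np.zeros(shape)
    cnt = np.zeros(shape)
    for t_hat, f in zip(times_hat, fields):
        it = np.searchsorted(t_edges, t_hat, side="right") - 1
        if not 0 <= it < shape[0]:
            continue
        ff = mirror_fold(f)
        ix = np.searchsorted(x_edges, ff.x, side="right") - 1
        ith = np.searchsorted(th_edges, np.clip(ff.theta, 0, th_edges[-1] - 1e-9), side="right") - 1
        ok = (ix >= 0) & (ix < shape[1]) & (ith >= 0) & (ith < shape[2])
        np.add.at(acc_x, (it, ix[ok], ith[ok]), ff.vx[ok])
        np.add.at(acc_t, (it, ix[ok], ith[ok]), ff.vtheta[ok])
        np.add.at(cnt, (it, ix[ok], ith[ok]), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = acc_x / cnt
        mean_t = acc_t / cnt
    return mean_x, mean_t, cnt > 0


def normalize_and_average(
    embryos: Iterable[Mapping],
    x_edges: np.ndarray | None = None,
    theta_edges: np.ndarray | None = None,
    t_hat_edges: np.ndarray | None = None,
    gap_threshold_s: float = 4.0,
) -> FlowMap:
    """Combine per-embryo flow fields into the average dimensionless map.

    Each embryo is a mapping with keys ``t0`` and ``t_ck`` (s), ``r_emb``
    (µm), ``times`` (s) and ``fields`` (list of :class:`FlowField` at those
    times).  Vectors are scaled by ``t_CK / R_emb``; fields are linearly
    interpolated onto t-bin centers when the bracketing frames are no more
    than ``gap_threshold_s`` apart (the periodic ~6 s z-stack acquisition
    gaps are left missing); each embryo contributes its own cell means,
    which are then averaged with equal embryo weight and counted.

    Embryos lacking alignment (``t_ck`` missing/non-positive) are excluded
    with a warning.
    """
    import warnings

    x_edges = DEFAULT_X_EDGES if x_edges is None else np.asarray(x_edges, dtype=float)
    theta_edges = (
        DEFAULT_THETA_EDGES if theta_edges is None else np.asarray(theta_edges, dtype=float)
    )
    t_hat_edges = (
        DEFAULT_THAT_EDGES if t_hat_edges is None else np.asarray(t_hat_edges, dtype=float)
    )
    shape = (len(t_hat_edges) - 1, len(x_edges) - 1, len(theta_edges) - 1)
    total_x = np.zeros(shape)
    total_t = np.zeros(shape)
    count = np.zeros(shape, dtype=int)
    r_embs, t_cks = [], []

    for emb in embryos:
        t0 = emb.get("t0")
        t_ck = emb.get("t_ck")
        r_emb = emb.get("r_emb")
        if t_ck is None or not np.isfinite(t_ck) or t_ck <= 0:
            warnings.warn("embryo lacking alignment excluded from flow map")
            continue
        r_embs.append(r_emb)
        t_cks.append(t_ck)
        times = np.asarray(emb["times"], dtype=float)
        fields = [f.scaled(t_ck / r_emb) for f in emb["fields"]]
        order = np.argsort(times)
        times = times[order]
        fields = [fields[i] for i in order]

        # interpolate within closely spaced frame runs onto t-bin centers
        samp_times = list(times)
        samp_fields = list(fields)
        centers_s = (0.5 * (t_hat_edges[:-1] + t_hat_edges[1:])) * t_ck + t0
        for tc in centers_s:
            j = np.searchsorted(times, tc)
            if j == 0 or j == times.size:
                continue
            ta, tb = times[j - 1], times[j]
            if tb - ta <= gap_threshold_s and not math.isclose(tb, ta):
                fa, fb = fields[j - 1], fields[j]
                if fa.x.shape == fb.x.shape and np.allclose(fa.x, fb.x) and np.allclose(
                    fa.theta, fb.theta
                ):
                    wgt = (tc - ta) / (tb - ta)
                    samp_times.append(tc)
                    samp_fields.append(
                        FlowField(
                            fa.x,
                            fa.theta,
                            (1 - wgt) * fa.vx + wgt * fb.vx,
                            (1 - wgt) * fa.vtheta + wgt * fb.vtheta,
                        )
                    )
        t_hats = (np.asarray(samp_times) - t0) / t_ck
        mean_x, mean_t, seen = _bin_embryo(t_hats, samp_fields, t_hat_edges, x_edges, theta_edges)
        total_x[seen] += mean_x[seen]
        total_t[seen] += mean_t[seen]
        count[seen] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        fx = np.where(count > 0, total_x / np.maximum(count, 1), np.nan)
        ftheta = np.where(count > 0, total_t / np.maximum(count, 1), np.nan)
    return FlowMap(
        t_hat_edges=t_hat_edges,
        x_edges=x_edges,
        theta_edges=theta_edges,
        fx=fx,
        ftheta=ftheta,
        count=count,
        r_emb=float(np.mean(r_embs)) if r_embs else float("nan"),
        t_ck=float(np.mean(t_cks)) if t_cks else float("nan"),
    )


def ap_velocity_profile(
    fmap: FlowMap,
    t_hat: float,
    band: Tuple[float, float] = (150.0, 180.0),
    mask_artifact_um: float = 2.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean dimensionless AP velocity vs x over an angular band.

    Returns ``(x_centers, profile, artifact_mask)``.  Cells without coverage
    are excluded from the band mean (NaN where the whole band is missing).
    ``artifact_mask`` flags ``|x| < mask_artifact_um`` where the apparent
    gradient is a projection artifact of the cortex turning into the furrow;
    the values are returned, not deleted.
    """
    lo, hi = band
    if not (0.0 <= lo < hi <= 180.0):
        raise ValueError("band must be a non-empty interval within [0, 180]")
    centers = fmap.theta_centers
    sel = (centers >= lo) & (centers <= hi)
    if not np.any(sel):
        raise ValueError("empty angular band for this grid")
    it = fmap.t_index(t_hat)
    block = fmap.fx[it][:, sel]
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(block, axis=1)
    xc = fmap.x_centers
    return xc, profile, np.abs(xc) < mask_artifact_um


# ---------------------------------------------------------------------------
# block-correlation flow estimation
# ---------------------------------------------------------------------------

def _intensity_ratio_threshold(frame: np.ndarray, box_hw: Tuple[int, int]) -> float:
    """Threshold maximizing in-box/out-box total intensity ratio.

    The box (default 200 x 350 px in full-size images) is centered in the
    frame; candidate thresholds are intensity percentiles.
    """
    ny, nx = frame.shape
    bh = min(box_hw[0], int(0.8 * ny))
    bw = min(box_hw[1], int(0.8 * nx))
    y0 = (ny - bh) // 2
    x0 = (nx - bw) // 2
    inside = np.zeros_like(frame, dtype=bool)
    inside[y0: y0 + bh, x0: x0 + bw] = True
    best_thr, best_ratio = float(np.min(frame)), -np.inf
    for q in np.linspace(5, 95, 19):
        thr = float(np.percentile(frame, q))
        fg = frame > thr
        s_in = float(frame[fg & inside].sum())
        s_out = float(frame[fg & ~inside].sum())
        ratio = s_in / (s_out + 1e-9)
        if ratio > best_ratio and s_in > 0:
            best_ratio, best_thr = ratio, thr
    return best_thr


def estimate_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window_px: int = 30,
    dt_s: float = 2.0,
    pixel_size: float = 0.16,
    search_px: int = 6,
    stride_px: int | None = None,
    min_corr: float = 0.3,
    threshold_box_px: Tuple[int, int] = (350, 200),
    plane_x_px: float | None = None,
    theta_deg: float = 165.0,
) -> FlowField:
    """Dense block-matching flow between two frames ``dt_s`` apart.

    For each ``window_px`` block on the thresholded foreground, the block is
    cross-correlated (normalized) against a search neighbourhood in the
    second frame; the correlation peak, refined to sub-pixel by parabolic
    interpolation, gives the displacement.  Vectors whose peak correlation
    falls below ``min_corr`` are dropped.  Default stride is half a window.

    ``plane_x_px`` sets the AP pixel coordinate of the division plane so the
    returned ``x`` values are µm from the plane (image x-axis = AP axis);
    ``theta_deg`` labels the angular position of the imaged cortex patch.
    """
    from scipy import ndimage

    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have equal shape")
    # the foreground mask separates embryo from exterior; smooth first so
    # sparse myosin puncta dilate into a contiguous region
    a_sm = ndimage.gaussian_filter(a, max(2.0, window_px / 6.0))
    thr = _intensity_ratio_threshold(a_sm, threshold_box_px)
    fg = a_sm > thr
    stride = stride_px or window_px // 2
    half = window_px // 2
    ny, nx = a.shape
    xs, thetas, vxs, vts = [], [], [], []
    x0 = plane_x_px if plane_x_px is not None else nx / 2.0
    for cy in range(half + search_px, ny - half - search_px, stride):
        for cx in range(half + search_px, nx - half - search_px, stride):
            block_fg = fg[cy - half: cy + half, cx - half: cx + half]
            if block_fg.mean() < 0.05:
                continue
            tmpl = a[cy - half: cy + half, cx - half: cx + half]
            if tmpl.std() == 0:
                continue
            region = b[
                cy - half - search_px: cy + half + search_px,
                cx - half - search_px: cx + half + search_px,
            ]
            cc = match_template(region, tmpl)
            peak = np.unravel_index(np.argmax(cc), cc.shape)
            if cc[peak] < min_corr:
                continue
            dy = float(peak[0] - search_px)
            dx = float(peak[1] - search_px)
            # parabolic sub-pixel refinement
            for axis, d in ((0, dy), (1, dx)):
                p = list(peak)
                if 0 < peak[axis] < cc.shape[axis] - 1:
                    p[axis] = peak[axis] - 1
                    cm = cc[tuple(p)]
                    p[axis] = peak[axis] + 1
                    cp = cc[tuple(p)]
                    c0 = cc[peak]
                    denom = cm - 2 * c0 + cp
                    if denom < 0:
                        off = 0.5 * (cm - cp) / denom
                        if axis == 0:
                            dy += off
                        else:
                            dx += off
            xs.append((cx - x0) * pixel_size)
            thetas.append(theta_deg)
            vxs.append(dx * pixel_size / dt_s)
            vts.append(dy * pixel_size / dt_s)
    return FlowField(
        x=np.asarray(xs),
        theta=np.asarray(thetas),
        vx=np.asarray(vxs),
        vtheta=np.asarray(vts),
    )
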