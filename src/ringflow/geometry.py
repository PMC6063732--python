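"""Embryo pose, embryo radius, contractile-ring and ingression-axis fitting.

Works on single-channel fluorescence z-stacks (axis order ``(z, y, x)``).
Conventions: after orientation the anterior-posterior (AP) axis is vertical
with the anterior at the top of the image; the end-on plane has coordinates
(lateral, depth) in µm; the angular coordinate used downstream is measured
in degrees from the initial ingression axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.signal import argrelmin
from skimage.measure import label, regionprops

__all__ = [
    "EmbryoPose",
    "RingFit",
    "IngressionAxis",
    "SegmentationError",
    "RingNotFoundError",
    "UndefinedAxisError",
    "fit_circle",
    "orient_embryo",
    "apply_pose",
    "fit_embryo_circle",
    "fit_ring",
    "initial_ingression_axis",
]


class SegmentationError(RuntimeError):
    """No threshold produced a mask of acceptable area."""


class RingNotFoundError(RuntimeError):
    """Too few candidate ring points to fit a circle."""


class UndefinedAxisError(RuntimeError):
    """Fewer than two sufficiently open rings to define the ingression axis."""


@dataclass
class EmbryoPose:
    """Orientation and size of one embryo.

    ``rotation_angle`` is the embryo's in-image rotation (degrees,
    counter-clockwise from the anterior-at-top reference); rotating the
    image by its negative places the anterior end at the top.  ``center_lateral_um`` and
    ``center_depth_um`` locate the embryo's central axis in the end-on plane.
    """

    rotation_angle: float
    anterior_end: str = "top"
    center_lateral_um: float = float("nan")
    center_depth_um: float = float("nan")
    embryo_radius_um: float = float("nan")
    threshold: float = float("nan")
    pixel_size: float = float("nan")

    def __post_init__(self) -> None:
        if self.anterior_end not in ("top", "bottom"):
            raise ValueError("anterior_end must be 'top' or 'bottom'")


@dataclass
class RingFit:
    """A fitted contractile ring at one time point.

    ``center`` is (AP position µm from the division plane, in-plane offset µm
    along the end-on lateral/depth coordinates collapsed onto the ingression
    axis frame).  ``rbar`` is the radius normalized by the embryo radius.
    """

    time: float
    radius: float
    center: Tuple[float, float]
    rbar: float
    residual: float = 0.0
    center_end_on: Tuple[float, float] | None = None  # (lateral, depth) µm

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be non-negative")
        if not (-0.05 <= self.rbar <= 1.2):
            raise ValueError(f"rbar={self.rbar:g} outside the plausible [0, 1.2] band")


@dataclass
class IngressionAxis:
    """Initial furrow-ingression direction in the end-on plane."""

    angle: float  # degrees in [0, 360), from vertical (depth axis)
    fit_rms: float

    def __post_init__(self) -> None:
        self.angle = float(self.angle) % 360.0


# ---------------------------------------------------------------------------
# circle fitting
# ---------------------------------------------------------------------------

def fit_circle(points: np.ndarray) -> Tuple[float, float, float, float]:
    """Fit a circle to ``(n, 2)`` points.

    Kåsa's algebraic fit provides the initial estimate; a geometric
    Levenberg-Marquardt refinement minimizes the orthogonal residuals.
    Returns ``(cx, cy, r, rms_residual)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least three 2-D points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    r = math.sqrt(max(c + cx**2 + cy**2, 1e-300))

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    sol = least_squares(resid, [cx, cy, r], method="lm", max_nfev=2000)
    cx, cy, r = sol.x
    rms = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return float(cx), float(cy), float(abs(r)), rms


# ---------------------------------------------------------------------------
# embryo orientation
# ---------------------------------------------------------------------------

def _histogram_threshold(
    image: np.ndarray,
    area_window: Tuple[float, float],
    hist_bins: int = 256,
) -> Tuple[float, np.ndarray]:
    """Threshold at a local minimum of the smoothed intensity histogram.

    Accepts the first minimum whose largest connected foreground component
    has an area inside ``area_window`` (px²); among several acceptable
    minima, the one closest to the midpoint of the flanking histogram modes
    is preferred, which stabilizes the choice in a wide, flat valley.
    """
    counts, edges = np.histogram(image, bins=hist_bins)
    smooth = ndimage.gaussian_filter1d(counts.astype(float), sigma=3.0)
    minima = argrelmin(smooth, order=3)[0]
    if minima.size == 0:
        raise SegmentationError("intensity histogram has no local minimum")
    lo_mode = edges[np.argmax(smooth[: max(minima[0], 1)])]
    hi_start = minima[-1]
    hi_mode = edges[hi_start + np.argmax(smooth[hi_start:])]
    midpoint = 0.5 * (lo_mode + hi_mode)

    accepted = []
    for idx in minima:
        thr = 0.5 * (edges[idx] + edges[idx + 1])
        mask = image > thr
        lab = label(mask)
        if lab.max() == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        area = sizes.max()
        if area_window[0] <= area <= area_window[1]:
            accepted.append((abs(thr - midpoint), thr, lab == (np.argmax(sizes) + 1)))
    if not accepted:
        raise SegmentationError(
            f"no histogram-minimum threshold gave a mask within {area_window} px²"
        )
    _, thr, mask = min(accepted, key=lambda t: t[0])
    return float(thr), mask


def orient_embryo(
    stack: np.ndarray,
    pixel_size: float,
    smooth_sigma_px: float = 10.0,
    expected_area_px2: Tuple[float, float] = (120_000.0, 50_000.0),
) -> EmbryoPose:
    """Determine the rotation placing the embryo anterior at the top.

    The middle z-plane is Gaussian-smoothed, thresholded at an intensity
    histogram minimum (accepted only when the mask area falls in the
    expected window, default 120,000 ± 50,000 px²), and an ellipse is fitted
    to the mask to find the AP axis.  The half with the brighter cortex is
    labeled anterior.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    mid = stack[stack.shape[0] // 2]
    sm = ndimage.gaussian_filter(mid, smooth_sigma_px)
    mean, half = expected_area_px2
    thr, mask = _histogram_threshold(sm, (mean - half, mean + half))

    props = regionprops(mask.astype(int))[0]
    # regionprops orientation: angle of major axis from the row (vertical) axis
    correction = -math.degrees(props.orientation)

    # rotate mask+image so the major axis is vertical and decide anterior half
    rot_im = ndimage.rotate(sm, correction, reshape=False, order=1)
    rot_mask = ndimage.rotate(mask.astype(float), correction, reshape=False, order=0) > 0.5
    rows = np.where(rot_mask.any(axis=1))[0]
    r_mid = (rows[0] + rows[-1]) // 2
    top = rot_im[rows[0]: r_mid][rot_mask[rows[0]: r_mid]]
    bottom = rot_im[r_mid: rows[-1] + 1][rot_mask[r_mid: rows[-1] + 1]]
    if bottom.mean() > top.mean():
        correction += 180.0
    return EmbryoPose(
        rotation_angle=(-correction) % 360.0,
        anterior_end="top",
        threshold=thr,
        pixel_size=pixel_size,
    )


def apply_pose(stack: np.ndarray, pose: EmbryoPose) -> np.ndarray:
    """Rotate every plane of ``stack`` so the anterior ends up at the top."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    return np.stack(
        [ndimage.rotate(p, -pose.rotation_angle, reshape=False, order=1) for p in stack]
    )


# ---------------------------------------------------------------------------
# embryo radius
# ---------------------------------------------------------------------------

def _edge_crossings(profile: np.ndarray, thr: float) -> Tuple[float, float] | None:
    """Sub-pixel first/last crossing of ``thr`` along a 1-D profile."""
    above = profile > thr
    idx = np.where(above)[0]
    if idx.size < 2:
        return None
    i0, i1 = idx[0], idx[-1]
    left = float(i0)
    if i0 > 0:
        d = profile[i0] - profile[i0 - 1]
        if d > 0:
            left = i0 - (profile[i0] - thr) / d
    right = float(i1)
    if i1 < profile.size - 1:
        d = profile[i1] - profile[i1 + 1]
        if d > 0:
            right = i1 + (profile[i1] - thr) / d
    return left, right


def fit_embryo_circle(
    stack: np.ndarray,
    pose: EmbryoPose,
    pixel_size: float,
    dz_um: float,
    n_lines: int = 10,
    line_step_px: int = 10,
    smooth_sigma_px: float = 2.0,
) -> EmbryoPose:
    """Measure the embryo's central axis and radius from an oriented stack.

    Starting from the AP midpoint, ``n_lines`` horizontal lines spaced
    ``line_step_px`` toward the anterior are scanned; on each z-plane the
    first and last above-threshold points along the line are collected,
    projected end-on (lateral, depth), and fitted with a circle.  Planes
    yielding fewer than the two edge points are skipped; lines with fewer
    than three boundary points are skipped with a warning.  The reported
    center and radius are the means over the line fits.
    """
    import warnings

    oriented = apply_pose(stack, pose)
    sm = np.stack([ndimage.gaussian_filter(p, smooth_sigma_px) for p in oriented])
    thr = pose.threshold
    if not np.isfinite(thr):
        thr, _ = _histogram_threshold(
            ndimage.gaussian_filter(oriented[oriented.shape[0] // 2], 10.0),
            (0, np.inf),
        )
    mid_mask = sm[sm.shape[0] // 2] > thr
    rows = np.where(mid_mask.any(axis=1))[0]
    if rows.size == 0:
        raise SegmentationError("no foreground after orientation")
    r_mid = (rows[0] + rows[-1]) // 2

    centers, depths, radii = [], [], []
    for i in range(n_lines):
        row = r_mid - i * line_step_px
        if row < 0:
            break
        pts = []
        for k in range(sm.shape[0]):
            cross = _edge_crossings(sm[k, row], thr)
            if cross is None:
                continue
            for c in cross:
                pts.append((c * pixel_size, k * dz_um))
        if len(pts) < 3:
            warnings.warn(f"line at row {row}: fewer than 3 boundary points; skipped")
            continue
        cx, cz, r, _ = fit_circle(np.asarray(pts))
        centers.append(cx)
        depths.append(cz)
        radii.append(r)
    if not radii:
        raise SegmentationError("no usable boundary lines")
    pose.center_lateral_um = float(np.mean(centers))
    pose.center_depth_um = float(np.mean(depths))
    pose.embryo_radius_um = float(np.mean(radii))
    return pose


# ---------------------------------------------------------------------------
# ring fitting
# ---------------------------------------------------------------------------

def fit_ring(
    stack: np.ndarray,
    pose: EmbryoPose,
    pixel_size: float,
    dz_um: float,
    time: float = 0.0,
    previous: Optional[RingFit] = None,
    pair_max_dx_px: int = 20,
    refine_window_px: int = 5,
    inplane_tolerance: float = 0.25,
) -> RingFit:
    """Fit the contractile ring from a division-plane z-stack.

    Per z-plane the brightest points on the two opposite (top/bottom) edges
    of the embryo are paired — accepted only when their horizontal (AP)
    separation is at most ``pair_max_dx_px`` pixels and they sit within
    ``inplane_tolerance`` of the embryo diameter from the middle — projected
    end-on as (lateral, depth) points and fitted with a circle.  The fit is
    refined by searching intensity maxima within ``refine_window_px`` of the
    predicted ring position.  With ``previous`` given, the AP position is
    constrained to ±20 px of the previous ring and the radius is initialized
    assuming a constant closure rate.
    """
    stack = np.asarray(stack, dtype=float)
    nz, ny, nx = stack.shape
    sm = np.stack([ndimage.gaussian_filter(p, 1.0) for p in stack])
    bg = float(np.median(sm))
    noise = float(np.median(np.abs(sm - bg))) * 1.4826
    floor = bg + max(4.0 * noise, 0.05 * (sm.max() - bg))

    if previous is not None:
        x_pred_px = previous.center[0] / pixel_size + nx / 2.0
        x_lo = int(max(0, x_pred_px - pair_max_dx_px))
        x_hi = int(min(nx, x_pred_px + pair_max_dx_px + 1))
    else:
        x_lo, x_hi = 0, nx
    y_mid = ny // 2
    band = int(max(1, inplane_tolerance * ny))

    pts = []  # (lateral µm, depth µm, ap µm)
    x_origin = nx / 2.0
    for k in range(nz):
        plane = sm[k, :, x_lo:x_hi]
        top_region = plane[max(0, y_mid - 2 * band): y_mid]
        bot_region = plane[y_mid: min(ny, y_mid + 2 * band)]
        if top_region.size == 0 or bot_region.size == 0:
            continue
        ti = np.unravel_index(np.argmax(top_region), top_region.shape)
        bi = np.unravel_index(np.argmax(bot_region), bot_region.shape)
        tval = top_region[ti]
        bval = bot_region[bi]
        if tval < floor or bval < floor:
            continue
        ty = ti[0] + max(0, y_mid - 2 * band)
        by = bi[0] + y_mid
        tx = ti[1] + x_lo
        bx = bi[1] + x_lo
        if abs(tx - bx) > pair_max_dx_px:
            continue
        pts.append((ty * pixel_size, k * dz_um, (tx - x_origin) * pixel_size))
        pts.append((by * pixel_size, k * dz_um, (bx - x_origin) * pixel_size))

    if len(pts) < 5:
        raise RingNotFoundError(f"only {len(pts)} candidate ring points")
    pts_arr = np.asarray(pts)
    cy, cz, r, rms = fit_circle(pts_arr[:, :2])

    # iterative refinement: look for maxima within refine_window_px of the
    # predicted ring locations in each plane, then refit
    for _ in range(3):
        new_pts = []
        for k in range(nz):
            z = k * dz_um
            disc = r**2 - (z - cz) ** 2
            if disc <= 0:
                continue
            for sign in (-1.0, 1.0):
                y_pred = cy + sign * math.sqrt(disc)
                j = int(round(y_pred / pixel_size))
                j0, j1 = max(0, j - refine_window_px), min(ny, j + refine_window_px + 1)
                if j1 <= j0:
                    continue
                seg = sm[k, j0:j1, x_lo:x_hi]
                jj, xx = np.unravel_index(np.argmax(seg), seg.shape)
                if seg[jj, xx] < floor:
                    continue
                new_pts.append(((j0 + jj) * pixel_size, z, (xx + x_lo - x_origin) * pixel_size))
        if len(new_pts) < 5:
            break
        pts_arr = np.asarray(new_pts)
        cy2, cz2, r2, rms = fit_circle(pts_arr[:, :2])
        if abs(r2 - r) < 1e-3 and math.hypot(cy2 - cy, cz2 - cz) < 1e-3:
            cy, cz, r = cy2, cz2, r2
            break
        cy, cz, r = cy2, cz2, r2

    ap_um = float(np.mean(pts_arr[:, 2]))
    r_emb = pose.embryo_radius_um
    rbar = r / r_emb if np.isfinite(r_emb) and r_emb > 0 else float("nan")
    lat0 = pose.center_lateral_um if np.isfinite(pose.center_lateral_um) else 0.0
    dep0 = pose.center_depth_um if np.isfinite(pose.center_depth_um) else 0.0
    return RingFit(
        time=time,
        radius=float(r),
        center=(ap_um, float(math.hypot(cy - lat0, cz - dep0))),
        rbar=float(min(rbar, 1.2)) if np.isfinite(rbar) else 1.0,
        residual=float(rms),
        center_end_on=(float(cy), float(cz)),
    )


# ---------------------------------------------------------------------------
# ingression axis
# ---------------------------------------------------------------------------

def initial_ingression_axis(
    rings: Sequence[RingFit],
    rbar_min: float = 0.3,
    origin: Tuple[float, float] = (0.0, 0.0),
) -> IngressionAxis:
    """Total-least-squares line through the centers of sufficiently open rings.

    Only rings with ``rbar > rbar_min`` (default 0.3) qualify.  The returned
    angle is measured in the end-on plane from the vertical (depth) axis and
    points toward the side the furrow ingressed from first (the earliest
    qualifying ring's center).
    """
    qual = [r for r in rings if r.rbar > rbar_min and r.center_end_on is not None]
    if len(qual) < 2:
        raise UndefinedAxisError(
            f"need >= 2 rings with rbar > {rbar_min}; got {len(qual)}"
        )
    pts = np.asarray([r.center_end_on for r in qual], dtype=float)
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid)
    direction = vt[0]
    # orient toward the earliest ring's offset
    earliest = min(qual, key=lambda r: r.time)
    off = np.asarray(earliest.center_end_on) - np.asarray(origin)
    if np.dot(direction, off) < 0:
        direction = -direction
    # rms of orthogonal residuals
    normal = vt[-1]
    rms = float(np.sqrt(np.mean(((pts - centroid) @ normal) ** 2)))
    angle = math.degrees(math.atan2(direction[0], direction[1]))  # from depth axis
    return IngressionAxis(angle=angle % 360.0, fit_rms=rms)
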