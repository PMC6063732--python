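"""Constriction-Coupled Disassembly with Compression Feedback model.

The cytokinetic contractile ring of the one-cell *C. elegans* embryo closes
at a roughly constant overall rate even though its perimeter shrinks, which
means the per-unit-length constriction rate accelerates.  The model
implemented here explains the acceleration with a positive feedback loop
along the axis perpendicular to the ring: myosin engaged in the ring/Rho
zone compresses cortical surface, compression pulls naive cortex into the
zone, and the incoming cortex is loaded with fresh myosin at concentration
``m_rho``.  In the around-the-ring direction, constriction is coupled to
disassembly and leaves per-unit-length amounts unchanged.

The feedback gives exponential growth of the engaged per-unit-length ring
myosin, ``M_ring(t) = M0_ring * exp(t / tau)`` with ``tau = 1/(alpha *
m_rho)``, and, in the time frame whose origin is the half-closure point
(``Rbar(0) = 1/2``), a closed-form normalized ring size

    Rbar(tbar) = Rbar_ini * (2 * Rbar_ini) ** (-exp(tbar)),   tbar = t / tau.

This module provides the closed forms, a conservative finite-volume
simulator of the underlying advection PDE, least-squares fitting of the
model (and of the alternative Retention model, per-unit-length amounts
growing as 1/Rbar) to per-unit-length time series, photobleach (pulse-chase)
predictions for both models, and the expected-rate arithmetic for cortical
laser-ablation experiments.

Parameters
----------
alpha : cortical compressibility, velocity of compression per unit
    per-unit-length engaged myosin (µm/s per amount/µm).
beta : constriction coefficient, per-unit-length constriction rate per unit
    per-unit-length engaged myosin (1/s per amount/µm).
m_rho : concentration of myosin loaded onto cortex entering the Rho zone
    (amount/µm²).
Rbar_ini : dimensionless characteristic ring size, held fixed at 1.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ModelParams",
    "ComponentParams",
    "PDEState",
    "InvalidParameterError",
    "CFLError",
    "FitFailureError",
    "mring_closed_form",
    "ring_size_closed_form",
    "vflow_closed_form",
    "per_length_constriction_rate",
    "component_closed_form",
    "pde_simulate",
    "fit_feedback",
    "fit_retention",
    "compare_models",
    "ModelComparison",
    "aicc",
    "predict_bleach",
    "laser_cut_expectation",
    "LaserCutExpectation",
]


class InvalidParameterError(ValueError):
    """Model parameters violate a physical constraint."""


class CFLError(RuntimeError):
    """Requested time step violates the advection stability limit."""


class FitFailureError(RuntimeError):
    """A model fit could not be carried out (degenerate data)."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the compression-feedback model.

    ``tau`` and ``m0_ring`` are derived quantities: ``tau = 1/(alpha*m_rho)``
    and ``m0_ring = ln(2*Rbar_ini) / (beta*tau)`` is the engaged per-unit-length
    myosin at half closure (the model's reference time, ``tbar = 0``).
    """

    alpha: float
    beta: float
    m_rho: float
    rbar_ini: float = 1.1
    zone_half_width: float = 5.0  # w, µm; the Rho zone spans 2w = 10 µm

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.m_rho > 0):
            raise InvalidParameterError("alpha, beta and m_rho must be positive")
        if not self.rbar_ini > 0.5:
            raise InvalidParameterError("rbar_ini must exceed 1/2")
        if not self.zone_half_width > 0:
            raise InvalidParameterError("zone_half_width must be positive")

    @property
    def tau(self) -> float:
        """Characteristic time of myosin accumulation, 1/(alpha*m_rho), s."""
        return 1.0 / (self.alpha * self.m_rho)

    @property
    def m0_ring(self) -> float:
        """Engaged per-unit-length ring myosin at half closure (amount/µm)."""
        return math.log(2.0 * self.rbar_ini) / (self.beta * self.tau)

    @classmethod
    def from_timescale(
        cls,
        tau: float,
        *,
        alpha_over_beta: float = 10.0,
        m_rho: float = 1.0,
        rbar_ini: float = 1.1,
        zone_half_width: float = 5.0,
    ) -> "ModelParams":
        """Build parameters from the accumulation timescale.

        ``alpha_over_beta`` (µm) sets how much cortical surface is compressed
        per unit of ring shortening; it controls the ratio of cortical inflow
        to division-plane growth.
        """
        if tau <= 0:
            raise InvalidParameterError("tau must be positive")
        alpha = 1.0 / (tau * m_rho)
        return cls(
            alpha=alpha,
            beta=alpha / alpha_over_beta,
            m_rho=m_rho,
            rbar_ini=rbar_ini,
            zone_half_width=zone_half_width,
        )


@dataclass(frozen=True)
class ComponentParams:
    """Loading parameters of a generic ring component (e.g. anillin).

    ``c_ring_base`` is the per-unit-length baseline that does not grow
    exponentially; it is tied to the amount at half closure ``c0_ring`` by
    ``c_ring_base = c0_ring - ln(2*Rbar_ini) * alpha * c_rho / beta``.
    """

    c_rho: float
    c0_ring: float

    def __post_init__(self) -> None:
        if self.c_rho < 0:
            raise InvalidParameterError("c_rho must be non-negative")

    def c_ring_base(self, params: ModelParams) -> float:
        return self.c0_ring - math.log(2.0 * params.rbar_ini) * params.alpha * self.c_rho / params.beta


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def mring_closed_form(params: ModelParams, t, baseline: float = 0.0):
    """Engaged per-unit-length ring myosin at time ``t`` (seconds from half
    closure): ``M0_ring * exp(t/tau)``, plus an optional non-engaged baseline."""
    t = np.asarray(t, dtype=float)
    return params.m0_ring * np.exp(t / params.tau) + baseline


def ring_size_closed_form(params: ModelParams, tbar):
    """Normalized ring size ``Rbar(tbar) = Rbar_ini*(2*Rbar_ini)**(-exp(tbar))``."""
    tbar = np.asarray(tbar, dtype=float)
    return params.rbar_ini * np.power(2.0 * params.rbar_ini, -np.exp(tbar))


def vflow_closed_form(params: ModelParams, tbar, dimensionless: bool = False):
    """Per-side speed of cortical flow into the ring, ``alpha*M_ring/2``.

    Returns µm/s by default; with ``dimensionless=True`` returns the
    tau-normalized speed ``(alpha/2 beta) ln(2 Rbar_ini) e**tbar``.
    """
    tbar = np.asarray(tbar, dtype=float)
    vbar = (params.alpha / (2.0 * params.beta)) * math.log(2.0 * params.rbar_ini) * np.exp(tbar)
    return vbar if dimensionless else vbar / params.tau


def per_length_constriction_rate(params: ModelParams, tbar, dimensionless: bool = True):
    """Per-unit-length constriction rate ``-(1/Rbar) dRbar/dtbar = ln(2*Rbar_ini)*e**tbar``.

    With ``dimensionless=False`` the rate is per second instead of per tau.
    """
    tbar = np.asarray(tbar, dtype=float)
    rate = math.log(2.0 * params.rbar_ini) * np.exp(tbar)
    return rate if dimensionless else rate / params.tau


def component_closed_form(params: ModelParams, comp: ComponentParams, tbar):
    """Per-unit-length amount of a ring component:
    ``c_ring_base + (alpha*c_rho/beta) * ln(2*Rbar_ini) * e**tbar``."""
    tbar = np.asarray(tbar, dtype=float)
    amp = params.alpha * comp.c_rho / params.beta * math.log(2.0 * params.rbar_ini)
    return comp.c_ring_base(params) + amp * np.exp(tbar)


# ---------------------------------------------------------------------------
# PDE simulator
# ---------------------------------------------------------------------------

@dataclass
class PDEState:
    """Snapshot of the one-dimensional myosin advection problem on [-w, w]."""

    t: float
    x: np.ndarray            # cell centers, µm
    m: np.ndarray            # myosin concentration, amount/µm²
    v: np.ndarray            # velocity at cell centers, µm/s (negative = toward 0 for x>0)
    m_ring: float            # ∫ m dx, amount/µm
    edge_speed: float        # |v(±w)| = alpha*M_ring/2, µm/s

    @property
    def strain_rate(self) -> np.ndarray:
        """Compression strain rate −alpha·m(x), 1/s."""
        return self._alpha * -self.m

    _alpha: float = field(default=0.0, repr=False)


def pde_simulate(
    params: ModelParams,
    m_init,
    t_end: float,
    dx: float,
    dt: float | None = None,
    store_every: int | None = None,
) -> list[PDEState]:
    """Integrate the myosin conservation law with compression-driven advection.

    The velocity is slaved to the instantaneous concentration,
    ``v(x,t) = -alpha * ∫0^x m(x',t) dx'``, and the concentration obeys
    ``∂m/∂t = -∂(m v)/∂x`` on ``[-w, w]`` with influx at both edges carrying
    the loading concentration ``m_rho``.  A first-order conservative upwind
    finite-volume scheme is used; the engaged total then satisfies
    ``dM_ring/dt = alpha*m_rho*M_ring`` exactly in space, so the scheme
    converges to the closed-form exponential as the grid is refined.

    Parameters
    ----------
    m_init : callable x->concentration, scalar, or array of cell values.
    dt : fixed time step; if None an adaptive CFL-safe step is chosen.
        A fixed dt that violates the CFL limit raises ``CFLError`` before any
        stepping (and mid-run if growth makes it unstable).
    """
    w = params.zone_half_width
    n = max(4, int(round(2.0 * w / dx)))
    if n % 2:
        n += 1
    dx = 2.0 * w / n
    xc = -w + (np.arange(n) + 0.5) * dx
    xf = -w + np.arange(n + 1) * dx  # faces

    if callable(m_init):
        m = np.asarray([float(m_init(x)) for x in xc])
    else:
        m = np.broadcast_to(np.asarray(m_init, dtype=float), (n,)).copy()
    if np.any(m < 0):
        raise InvalidParameterError("initial concentration must be non-negative")

    i_mid = n // 2  # face index at x = 0

    def face_velocity(m: np.ndarray) -> np.ndarray:
        cum = np.concatenate(([0.0], np.cumsum(m) * dx))  # ∫_{-w}^{x_f} m
        return -params.alpha * (cum - cum[i_mid])

    v = face_velocity(m)
    vmax = np.max(np.abs(v))
    if dt is not None and vmax > 0 and dt > 0.9 * dx / vmax:
        raise CFLError(
            f"dt={dt:g} exceeds CFL limit {0.9 * dx / max(vmax, 1e-300):g} s"
        )

    states: list[PDEState] = []

    def record(t: float, m: np.ndarray, v: np.ndarray) -> None:
        m_ring = float(np.sum(m) * dx)
        st = PDEState(
            t=t,
            x=xc.copy(),
            m=m.copy(),
            v=0.5 * (v[:-1] + v[1:]),
            m_ring=m_ring,
            edge_speed=params.alpha * m_ring / 2.0,
            _alpha=params.alpha,
        )
        states.append(st)

    record(0.0, m, v)
    t = 0.0
    step = 0
    while t < t_end - 1e-12:
        v = face_velocity(m)
        vmax = np.max(np.abs(v))
        if dt is None:
            h = 0.5 * dx / vmax if vmax > 0 else t_end - t
        else:
            if vmax > 0 and dt > dx / vmax:
                raise CFLError(f"dt={dt:g} became unstable at t={t:g} s")
            h = dt
        h = min(h, t_end - t)

        # upwind flux; boundary upstream cells carry the loading concentration
        m_up = np.empty(n + 1)
        m_up[1:-1] = np.where(v[1:-1] > 0, m[:-1], m[1:])
        m_up[0] = params.m_rho if v[0] > 0 else m[0]
        m_up[-1] = params.m_rho if v[-1] < 0 else m[-1]
        flux = v * m_up
        m = m - h / dx * (flux[1:] - flux[:-1])
        t += h
        step += 1
        if store_every and step % store_every == 0 and t < t_end - 1e-12:
            record(t, m, face_velocity(m))
    record(t, m, face_velocity(m))
    return states


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def aicc(ssr: float, n: int, k: int) -> float:
    """Akaike information criterion with small-sample correction."""
    if n <= k + 1:
        return math.inf
    return n * math.log(max(ssr, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class FeedbackFit:
    """Result of a joint compression-feedback fit.

    ``k = t_CK / tau`` converts normalized time to model time,
    ``tbar = k * (t_hat - t_hat_half)``.
    """

    k: float
    t_hat_half: float
    tau: float | None          # seconds, requires t_ck
    amplitudes: Dict[str, float]
    baselines: Dict[str, float]
    rbar_ini: float
    ssr: float
    n_obs: int
    n_params: int
    aicc: float
    per_series_ssr: Dict[str, float]

    def beta(self, t_ck: float | None = None) -> float | None:
        """Constriction coefficient from the rate/myosin amplitude ratio."""
        if "myosin" in self.amplitudes and "constriction_rate" in self.amplitudes:
            return self.amplitudes["constriction_rate"] / self.amplitudes["myosin"]
        return None

    def alpha(self) -> float | None:
        """Compressibility from the compression-rate/myosin amplitude ratio."""
        if "myosin" in self.amplitudes and "compression_rate" in self.amplitudes:
            return self.amplitudes["compression_rate"] / self.amplitudes["myosin"]
        return None


def _series_arrays(
    series: Mapping[str, Tuple[np.ndarray, np.ndarray]]
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    out = {}
    for name, (t, y) in series.items():
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError(f"series {name!r}: time and value shapes differ")
        if t.size < 6:
            raise FitFailureError(f"series {name!r}: need at least 6 time points")
        out[name] = (t, y)
    return out


def fit_feedback(
    series: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    rbar: Tuple[np.ndarray, np.ndarray] | None = None,
    t_ck: float | None = None,
    rbar_ini: float = 1.1,
) -> FeedbackFit:
    """Jointly fit ``base + A*exp(k*(t_hat - t_hat_half))`` to each series.

    All series share the dimensionless growth rate ``k = t_CK/tau`` and the
    half-closure time ``t_hat_half``; each has its own amplitude and baseline.
    When ``rbar`` (normalized ring size vs t_hat) is supplied, the closed-form
    trajectory with ``rbar_ini`` held fixed at 1.1 is fitted simultaneously,
    which pins ``t_hat_half`` and sharpens ``k``.  Residual blocks are scaled
    by each series' RMS so fluorescence units do not dominate.

    Returns a :class:`FeedbackFit`; ``tau`` is filled in when ``t_ck`` given.
    """
    data = _series_arrays(series)
    if not data and rbar is None:
        raise FitFailureError("nothing to fit")

    names = list(data)
    scales = {}
    for name, (t, y) in data.items():
        s = float(np.sqrt(np.mean(y**2)))
        if s <= 0 or np.ptp(y) <= 0:
            raise FitFailureError(f"series {name!r} is flat; rate not identifiable")
        scales[name] = s

    if rbar is not None:
        tr = np.asarray(rbar[0], dtype=float)
        rr = np.asarray(rbar[1], dtype=float)
        t_half0 = float(np.interp(0.5, rr[::-1], tr[::-1])) if rr[0] > rr[-1] else 0.5
    else:
        t_half0 = 0.5

    # parameter vector: [k, t_half, (log_amp_i, base_i)...]
    def unpack(p):
        k, th = p[0], p[1]
        amps = {}
        bases = {}
        for i, name in enumerate(names):
            amps[name] = math.exp(p[2 + 2 * i])
            bases[name] = p[3 + 2 * i]
        return k, th, amps, bases

    def resid(p):
        k, th, amps, bases = unpack(p)
        blocks = []
        for name in names:
            t, y = data[name]
            model = bases[name] + amps[name] * np.exp(np.clip(k * (t - th), -50, 50))
            blocks.append((y - model) / scales[name])
        if rbar is not None:
            model_r = rbar_ini * np.power(2.0 * rbar_ini, -np.exp(np.clip(k * (tr - th), -50, 50)))
            blocks.append(rr - model_r)
        return np.concatenate(blocks)

    p0 = [2.5, t_half0]
    for name in names:
        t, y = data[name]
        ymin = float(np.min(y))
        amp0 = max(float(np.interp(t_half0, t, y)) - ymin, 1e-3 * scales[name])
        p0 += [math.log(amp0), ymin]
    lo = [0.05, -5.0] + [-30.0, -np.inf] * len(names)
    hi = [20.0, 5.0] + [30.0, np.inf] * len(names)

    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf", max_nfev=20000)
    if not sol.success and sol.status <= 0:
        raise FitFailureError(f"feedback fit failed: {sol.message}")
    k, th, amps, bases = unpack(sol.x)

    # un-scaled SSR per series for model comparison
    per_ssr = {}
    n_obs = 0
    ssr = 0.0
    for name in names:
        t, y = data[name]
        model = bases[name] + amps[name] * np.exp(k * (t - th))
        r = y - model
        per_ssr[name] = float(np.sum(r**2))
        ssr += per_ssr[name] / scales[name] ** 2
        n_obs += y.size
    if rbar is not None:
        model_r = rbar_ini * np.power(2.0 * rbar_ini, -np.exp(k * (tr - th)))
        per_ssr["rbar"] = float(np.sum((rr - model_r) ** 2))
        ssr += per_ssr["rbar"]
        n_obs += rr.size

    n_params = 2 + 2 * len(names)
    return FeedbackFit(
        k=k,
        t_hat_half=th,
        tau=(t_ck / k) if t_ck is not None else None,
        amplitudes=amps,
        baselines=bases,
        rbar_ini=rbar_ini,
        ssr=float(ssr),
        n_obs=n_obs,
        n_params=n_params,
        aicc=aicc(float(ssr), n_obs, n_params),
        per_series_ssr=per_ssr,
    )


@dataclass
class RetentionFit:
    """Result of fitting the Retention alternative, ``base + B / Rbar(t_hat)``."""

    amplitudes: Dict[str, float]
    baselines: Dict[str, float]
    ssr: float
    n_obs: int
    n_params: int
    aicc: float
    per_series_ssr: Dict[str, float]


def fit_retention(
    series: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    rbar: Tuple[np.ndarray, np.ndarray],
) -> RetentionFit:
    """Fit ``base + B/Rbar`` to each per-unit-length series.

    Under Retention, components are kept as the perimeter shrinks, so
    per-unit-length amounts grow as the inverse of normalized ring size.
    ``Rbar(t_hat)`` is interpolated from the supplied trajectory; the fit is
    linear and solved exactly per series.  SSR is normalized by each series'
    RMS, matching the convention of :func:`fit_feedback` so the two criteria
    are comparable.
    """
    data = _series_arrays(series)
    tr = np.asarray(rbar[0], dtype=float)
    rr = np.asarray(rbar[1], dtype=float)
    amps, bases, per_ssr = {}, {}, {}
    ssr = 0.0
    n_obs = 0
    for name, (t, y) in data.items():
        scale = float(np.sqrt(np.mean(y**2)))
        if scale <= 0:
            raise FitFailureError(f"series {name!r} is flat")
        rb = np.interp(t, tr, rr)
        if np.any(rb <= 0):
            raise FitFailureError("Rbar must stay positive over the fitted range")
        X = np.column_stack([np.ones_like(t), 1.0 / rb])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        model = X @ coef
        bases[name], amps[name] = float(coef[0]), float(coef[1])
        per_ssr[name] = float(np.sum((y - model) ** 2))
        ssr += per_ssr[name] / scale**2
        n_obs += y.size
    n_params = 2 * len(data)
    return RetentionFit(
        amplitudes=amps,
        baselines=bases,
        ssr=float(ssr),
        n_obs=n_obs,
        n_params=n_params,
        aicc=aicc(float(ssr), n_obs, n_params),
        per_series_ssr=per_ssr,
    )


@dataclass
class ModelComparison:
    """Paired comparison of the feedback and retention fits on shared data."""

    feedback: FeedbackFit
    retention: RetentionFit
    series_ssr_feedback: Dict[str, float]
    series_ssr_retention: Dict[str, float]
    aicc_feedback: float
    aicc_retention: float
    preferred: str


def compare_models(
    series: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    rbar: Tuple[np.ndarray, np.ndarray],
    t_ck: float | None = None,
    rbar_ini: float = 1.1,
) -> ModelComparison:
    """Fit both models to the same per-unit-length series and compare.

    The feedback fit shares its growth rate with the ring-size trajectory
    (the model couples them), so the comparison asks which functional form —
    ``base + A e^(tbar)`` with the trajectory's timescale, or
    ``base + B/Rbar`` — explains the series; SSRs are computed per series on
    identical data, and the overall preference uses AICc on the RMS-scaled
    series residuals (trajectory block excluded so both criteria see the
    same observations).
    """
    fb = fit_feedback(series, rbar=rbar, t_ck=t_ck, rbar_ini=rbar_ini)
    rt = fit_retention(series, rbar=rbar)
    data = _series_arrays(series)
    ssr_fb = 0.0
    ssr_rt = 0.0
    n_obs = 0
    for name, (t, y) in data.items():
        scale2 = float(np.mean(y**2))
        ssr_fb += fb.per_series_ssr[name] / scale2
        ssr_rt += rt.per_series_ssr[name] / scale2
        n_obs += y.size
    k_fb = 2 + 2 * len(data)   # shared rate & origin + per-series amp/base
    k_rt = 2 * len(data)
    a_fb = aicc(ssr_fb, n_obs, k_fb)
    a_rt = aicc(ssr_rt, n_obs, k_rt)
    return ModelComparison(
        feedback=fb,
        retention=rt,
        series_ssr_feedback={k: fb.per_series_ssr[k] for k in data},
        series_ssr_retention={k: rt.per_series_ssr[k] for k in data},
        aicc_feedback=a_fb,
        aicc_retention=a_rt,
        preferred="feedback" if a_fb < a_rt else "retention",
    )


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def predict_bleach(
    params: ModelParams,
    bleach_tbar: float,
    model: str = "feedback",
    tbar: Sequence[float] | None = None,
    bleach_fraction: float = 1.0,
) -> Dict[str, np.ndarray]:
    """Pulse-chase prediction for photobleaching the whole division plane.

    The bleach converts a fraction of the fluorescent per-unit-length myosin
    present at ``bleach_tbar`` into dark subunits; the ``difference`` curve
    (control minus bleached) tracks the fate of that dark pool.

    * ``feedback``: constriction-coupled disassembly removes dark subunits in
      proportion to perimeter loss, so their per-unit-length amount — hence
      the difference curve — stays constant at the pre-bleach level.
    * ``retention``: dark subunits are retained while the perimeter shrinks,
      so the difference grows as ``R(bleach)/R(t)``.

    Returns arrays ``tbar``, ``control``, ``bleached``, ``difference``.
    """
    if model not in ("feedback", "retention"):
        raise ValueError("model must be 'feedback' or 'retention'")
    if not 0.0 <= bleach_fraction <= 1.0:
        raise ValueError("bleach_fraction must be within [0, 1]")
    if tbar is None:
        tbar = np.linspace(bleach_tbar, bleach_tbar + 2.0, 60)
    tbar = np.asarray(tbar, dtype=float)

    m_bleach = params.m0_ring * math.exp(bleach_tbar)
    if model == "feedback":
        control = params.m0_ring * np.exp(tbar)
        difference = np.full_like(tbar, bleach_fraction * m_bleach)
    else:
        rb = ring_size_closed_form(params, tbar)
        rb_bleach = float(ring_size_closed_form(params, bleach_tbar))
        control = m_bleach * rb_bleach / rb
        difference = bleach_fraction * m_bleach * rb_bleach / rb
    return {
        "tbar": tbar,
        "control": control,
        "bleached": control - difference,
        "difference": difference,
    }


@dataclass(frozen=True)
class LaserCutExpectation:
    """Expected effect of a cortical laser cut on the closure rate."""

    plane_gain_um2: float
    radius_decrement_um: float
    rate_increment_um_s: float
    expected_rate_um_s: float


def laser_cut_expectation(
    opening_area_um2: float,
    ring_radius_um: float,
    control_rate_um_s: float,
    interval_s: float,
) -> LaserCutExpectation:
    """Expected constriction rate if cortical tension limited ring closure.

    The cortical opening created by the cut is assumed to be shared between
    the two nascent cells, so half of it adds to the division plane; the area
    gain maps to a ring-radius decrement through the perimeter, and the
    decrement spread over the re-measurement interval adds to the closure
    rate.  Observed rates matching the control rather than this expectation
    indicate that cortical tension does not resist ring pulling.
    """
    if min(opening_area_um2, ring_radius_um, control_rate_um_s, interval_s) < 0 or (
        ring_radius_um <= 0 or interval_s <= 0
    ):
        raise ValueError("inputs must be positive (opening area may be zero)")
    plane_gain = opening_area_um2 / 2.0
    radius_dec = plane_gain / (2.0 * math.pi * ring_radius_um)
    rate_inc = radius_dec / interval_s
    return LaserCutExpectation(
        plane_gain_um2=plane_gain,
        radius_decrement_um=radius_dec,
        rate_increment_um_s=rate_inc,
        expected_rate_um_s=control_rate_um_s + rate_inc,
    )
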