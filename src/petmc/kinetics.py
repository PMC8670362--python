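"""One-tissue compartment modeling of dynamic PET time-activity curves.

Implements the forward 1T model with a blood-volume/spillover term,
weighted-least-squares fitting with frame weights ``w_n = L_n^2 / (T_n * DCF_n^2)``,
and the conversion from the uptake rate K1 to myocardial blood flow (MBF)
through a Renkin-Crone style extraction relationship.

Units: activity in Bq/mL, rate constants K1 (mL/min/g) and k2 (1/min),
time in seconds at the interface (converted to minutes internally where
rate constants apply).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "KineticParams",
    "FitResult",
    "FlowModelConfig",
    "RB82_HALF_LIFE_S",
    "sample_roi_tac",
    "decay_correction_factors",
    "frame_weights",
    "model_tac",
    "fit_1t_wls",
    "mbf_from_k1",
]

#: Physical half-life of Rb-82 in seconds.  External physical constant
#: (not derived from any dataset); override through function arguments
#: wherever a different isotope is modeled.
RB82_HALF_LIFE_S = 75.0


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the 1-tissue compartment model.

    K1 : uptake rate (mL/min/g), k2 : washout rate (1/min),
    vb : blood-volume / spillover fraction in [0, 1].
    """

    K1: float
    k2: float
    vb: float

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("K1 and k2 must be nonnegative")
        if not 0.0 <= self.vb <= 1.0:
            raise ValueError("vb must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.vb], dtype=float)


@dataclass(frozen=True)
class FitResult:
    params: KineticParams
    wss: float
    converged: bool
    iterations: int


@dataclass(frozen=True)
class FlowModelConfig:
    """Extraction relationship K1 = MBF * (1 - a * exp(-b / MBF)).

    The coefficients are deliberately user-supplied: no published pair is
    bundled, and ``a = 0`` reduces the relationship to the identity.
    """

    a: float = 0.0
    b: float = 1.0
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if not 0.0 <= self.a < 1.0:
            raise ValueError("a must lie in [0, 1)")
        if self.b <= 0:
            raise ValueError("b must be positive")

    def k1_of_mbf(self, mbf: float) -> float:
        if mbf <= 0:
            return 0.0
        return mbf * (1.0 - self.a * np.exp(-self.b / mbf))


def sample_roi_tac(seq, labels, roi_code: int) -> np.ndarray:
    """Mean activity per frame over the voxels carrying ``roi_code``.

    ``seq`` is a DynamicSequence (or any object with a ``frames`` array of
    shape (T, X, Y, Z)); ``labels`` an integer volume of the spatial shape.
    """
    frames = np.asarray(seq.frames, dtype=float)
    lab = np.asarray(labels.volume if hasattr(labels, "volume") else labels)
    if lab.shape != frames.shape[1:]:
        raise ValueError(
            f"label shape {lab.shape} does not match frame shape {frames.shape[1:]}"
        )
    mask = lab == roi_code
    if not mask.any():
        raise ValueError(f"ROI code {roi_code} selects no voxels")
    return frames[:, mask].mean(axis=1)


def decay_correction_factors(schedule, half_life_s: float = RB82_HALF_LIFE_S) -> np.ndarray:
    """Per-frame decay-correction factor DCF_n.

    DCF_n converts the frame-averaged decayed activity to activity corrected
    to scan start: DCF_n = lambda * L_n / (exp(-lambda t_n) * (1 - exp(-lambda L_n)))
    with t_n the frame start and L_n its duration.  As half_life -> inf the
    factor tends to 1.
    """
    if half_life_s <= 0:
        raise ValueError("half_life_s must be positive")
    lam = np.log(2.0) / half_life_s
    t = np.asarray(schedule.start_s, dtype=float)
    dur = np.asarray(schedule.duration_s, dtype=float)
    # -expm1(-x) = 1 - exp(-x) without cancellation for tiny lambda
    return lam * dur / (np.exp(-lam * t) * -np.expm1(-lam * dur))


def frame_weights(
    schedule,
    total_activity: np.ndarray,
    half_life_s: float = RB82_HALF_LIFE_S,
) -> np.ndarray:
    """WLS frame weights w_n = L_n^2 / (T_n * DCF_n^2).

    ``total_activity`` is the per-frame total activity T_n (must be > 0).
    """
    T = np.asarray(total_activity, dtype=float)
    dur = np.asarray(schedule.duration_s, dtype=float)
    if T.shape != dur.shape:
        raise ValueError("total_activity length must match schedule length")
    if np.any(T <= 0):
        raise ValueError("total activity must be strictly positive for every frame")
    dcf = decay_correction_factors(schedule, half_life_s)
    return dur**2 / (T * dcf**2)


def _fine_grid(schedule, dt: float) -> np.ndarray:
    t_end = float(schedule.start_s[-1] + schedule.duration_s[-1])
    n = int(np.ceil(t_end / dt)) + 1
    return np.linspace(0.0, t_end, n)


def _resolve_input(idif, schedule, dt: float):
    """Return (t_grid, values) for the input function on a fine grid.

    ``idif`` may be a callable of time (seconds) or a per-frame TAC, in which
    case it is linearly interpolated at frame midpoints (0 before the first
    midpoint start).
    """
    t = _fine_grid(schedule, dt)
    if callable(idif):
        return t, np.asarray(idif(t), dtype=float)
    vals = np.asarray(idif, dtype=float)
    starts = np.asarray(schedule.start_s, dtype=float)
    durs = np.asarray(schedule.duration_s, dtype=float)
    if vals.shape != starts.shape:
        raise ValueError("idif TAC length must match schedule length")
    mids = starts + durs / 2.0
    return t, np.interp(t, mids, vals, left=0.0, right=vals[-1])


def tissue_response(
    params: KineticParams, t: np.ndarray, cin: np.ndarray
) -> np.ndarray:
    """Tissue concentration K1 * int_0^t cin(tau) exp(-k2 (t - tau)) dtau.

    Exact exponential-integrator recursion on a uniform grid, with ``cin``
    treated as piecewise linear.  Rate constants are per minute; ``t`` is in
    seconds.
    """
    k1 = params.K1 / 60.0  # per second
    k2 = params.k2 / 60.0
    dt = t[1] - t[0]
    y = np.zeros_like(cin)
    if k2 > 0:
        e = np.exp(-k2 * dt)
        # int over one step of linear cin against the exponential kernel
        a0 = (1.0 - e) / k2
        a1 = (dt - a0) / (k2 * dt)  # weight on the slope term
        for i in range(1, len(t)):
            c0 = cin[i - 1]
            slope = cin[i] - cin[i - 1]
            y[i] = y[i - 1] * e + k1 * (c0 * a0 + slope * a1)
    else:
        # pure integration (trapezoid)
        y[1:] = k1 * np.cumsum((cin[1:] + cin[:-1]) / 2.0 * dt)
    return y


def model_tac(
    params: KineticParams,
    idif,
    schedule,
    dt: float = 0.1,
) -> np.ndarray:
    """Frame-averaged model TAC of the 1T model with spillover.

    C(t) = (1 - vb) * K1 * conv(idif, exp(-k2 t)) + vb * idif(t), averaged
    over each frame interval of ``schedule``.
    """
    t, cin = _resolve_input(idif, schedule, dt)
    ct = tissue_response(params, t, cin)
    c = (1.0 - params.vb) * ct + params.vb * cin
    starts = np.asarray(schedule.start_s, dtype=float)
    durs = np.asarray(schedule.duration_s, dtype=float)
    out = np.empty(len(starts))
    for n, (t0, L) in enumerate(zip(starts, durs)):
        i0 = int(round(t0 / dt))
        i1 = int(round((t0 + L) / dt))
        i1 = min(i1, len(t) - 1)
        out[n] = np.trapezoid(c[i0 : i1 + 1], t[i0 : i1 + 1]) / (t[i1] - t[i0])
    return out


_DEFAULT_INITS = (
    KineticParams(0.5, 0.1, 0.2),
    KineticParams(1.5, 0.5, 0.4),
    KineticParams(3.0, 1.0, 0.1),
)

_BOUNDS_LO = np.array([0.0, 0.0, 0.0])
_BOUNDS_HI = np.array([10.0, 10.0, 1.0])


def fit_1t_wls(
    measured: np.ndarray,
    idif,
    schedule,
    weights: np.ndarray,
    init: KineticParams | None = None,
    dt: float = 0.1,
) -> FitResult:
    """Weighted least-squares fit of the 1T model to a measured TAC.

    Minimizes sum_n w_n (measured_n - model_n)^2 over (K1, k2, vb) within
    bounds K1, k2 in [0, 10], vb in [0, 1].  When ``init`` is None a fixed
    3-point multi-start is used and the lowest-WSS solution returned;
    deterministic either way.
    """
    measured = np.asarray(measured, dtype=float)
    w = np.asarray(weights, dtype=float)
    if measured.shape != w.shape:
        raise ValueError("measured and weights must have the same length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValueError("all-zero weights make the fit degenerate")
    sw = np.sqrt(w)

    t, cin = _resolve_input(idif, schedule, dt)
    starts = np.asarray(schedule.start_s, dtype=float)
    durs = np.asarray(schedule.duration_s, dtype=float)
    edges = [
        (int(round(t0 / dt)), min(int(round((t0 + L) / dt)), len(t) - 1))
        for t0, L in zip(starts, durs)
    ]

    def frame_average(c: np.ndarray) -> np.ndarray:
        return np.array(
            [np.trapezoid(c[i0 : i1 + 1], t[i0 : i1 + 1]) / (t[i1] - t[i0]) for i0, i1 in edges]
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        p = KineticParams(x[0], x[1], x[2])
        ct = tissue_response(p, t, cin)
        c = (1.0 - p.vb) * ct + p.vb * cin
        return sw * (frame_average(c) - measured)

    inits = (init,) if init is not None else _DEFAULT_INITS
    best = None
    for p0 in inits:
        x0 = np.clip(p0.as_array(), _BOUNDS_LO, _BOUNDS_HI)
        sol = least_squares(
            residuals, x0, bounds=(_BOUNDS_LO, _BOUNDS_HI), xtol=1e-10, ftol=1e-10
        )
        wss = float(np.sum(sol.fun**2))
        if best is None or wss < best[1]:
            best = (sol, wss)
    sol, wss = best
    params = KineticParams(*(float(v) for v in sol.x))
    return FitResult(
        params=params, wss=wss, converged=bool(sol.success), iterations=int(sol.nfev)
    )


def mbf_from_k1(K1: float, flow_cfg: FlowModelConfig) -> float:
    """Invert K1 = MBF * (1 - a exp(-b / MBF)) for MBF by bracketed root finding."""
    if K1 < 0:
        raise ValueError("K1 must be nonnegative")
    if flow_cfg.a == 0.0:
        return float(K1)
    if K1 == 0.0:
        return 0.0

    def f(m: float) -> float:
        return flow_cfg.k1_of_mbf(m) - K1

    lo, hi = 1e-9, max(1.0, 2.0 * K1 / (1.0 - flow_cfg.a))
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(f"K1={K1} outside the attainable range of the flow model")
    return float(brentq(f, lo, hi, xtol=1e-12))
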