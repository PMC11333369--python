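"""Assistance-profile parameterization: the piecewise-cubic template.

Every assistance strategy is expressed by four parameters — peak value
tau_peak (Nm/kg) and start/peak/end times t1 < t2 < t3 (% of gait cycle) —
through the unique pair of cubics with zero value and zero slope at t1 and
t3 and value tau_peak with zero slope at t2:

    f(t) = tau_peak * (3 s^2 - 2 s^3),      s = (t - t1)/(t2 - t1), t1<=t<=t2
    f(t) = tau_peak * (1 - 3 u^2 + 2 u^3),  u = (t - t2)/(t3 - t2), t2<=t<=t3
    f(t) = 0 otherwise.

These Hermite closed forms satisfy all eight boundary constraints exactly
and make the template C^1 everywhere.

Raw optimal-assistance curves are cleaned before template matching: the
dorsiflexion (negative) portion is zeroed (the device assists plantarflexion
only), a zero-lag 6th-order Butterworth low-pass at 10 Hz is applied
(forward-backward, so no phase shift), and the result is full-wave
rectified. Template matching is a least-squares fit over the parameter
space: a coarse grid over the knots (closed-form optimal peak per knot
triple) followed by deterministic local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .errors import DomainError
from .gait_synth import PHASE_GRID

#: curves whose maximum falls below this are treated as "no assistance"
NO_ASSIST_THRESHOLD = 0.01  # Nm/kg


@dataclass(frozen=True)
class AssistanceProfile:
    """Four-parameter plantarflexion assistance profile."""

    peak_value: float  # Nm/kg
    start_time: float  # t1, % of cycle
    peak_time: float  # t2
    end_time: float  # t3
    fit_residual: float = 0.0  # RMS residual of template matching, Nm/kg

    def __post_init__(self):
        if not (0.0 <= self.start_time < self.peak_time
                < self.end_time <= 100.0):
            raise DomainError(
                f"knots must satisfy 0 <= t1 < t2 < t3 <= 100, got "
                f"({self.start_time}, {self.peak_time}, {self.end_time})")
        if self.peak_value < 0:
            raise DomainError("peak_value must be >= 0")

    @property
    def sampled_curve(self) -> np.ndarray:
        """The template evaluated on the 101-point phase grid (Nm/kg)."""
        return eval_template(self, PHASE_GRID)

    def as_dict(self) -> dict:
        return {"peak_value": self.peak_value, "start_time": self.start_time,
                "peak_time": self.peak_time, "end_time": self.end_time}


def _template_values(t: np.ndarray, peak: float, t1: float, t2: float,
                     t3: float) -> np.ndarray:
    if not (t1 < t2 < t3):
        raise DomainError("degenerate knots: need t1 < t2 < t3")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = (t >= t1) & (t <= t2)
    s = (t[rising] - t1) / (t2 - t1)
    out[rising] = peak * (3.0 * s**2 - 2.0 * s**3)
    falling = (t > t2) & (t <= t3)
    u = (t[falling] - t2) / (t3 - t2)
    out[falling] = peak * (1.0 - 3.0 * u**2 + 2.0 * u**3)
    return out


def eval_template(profile: AssistanceProfile,
                  t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the piecewise-cubic template at phase(s) ``t`` (% of cycle)."""
    values = _template_values(np.atleast_1d(t), profile.peak_value,
                              profile.start_time, profile.peak_time,
                              profile.end_time)
    return float(values[0]) if np.ndim(t) == 0 else values


def postprocess_raw(raw: np.ndarray, duration: float,
                    cutoff_hz: float = 10.0, order: int = 6,
                    reflect_df: bool = False) -> np.ndarray:
    """Clean a raw optimal-assistance curve for template matching.

    Steps: zero (or, with ``reflect_df``, reflect) the dorsiflexion portion,
    zero-lag Butterworth low-pass (forward-backward), full-wave rectify.
    The sampling rate is the 101-sample grid over the cycle ``duration``;
    the cutoff is clamped to 0.45x Nyquist for long cycles.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (101,):
        raise DomainError("raw curve must have 101 samples")
    if not np.all(np.isfinite(raw)):
        raise DomainError("raw curve must be finite")
    if duration <= 0:
        raise DomainError("duration must be positive")
    x = np.abs(raw) if reflect_df else np.maximum(raw, 0.0)
    fs = 100.0 / duration  # Hz
    wn = min(cutoff_hz / (fs / 2.0), 0.9)
    sos = signal.butter(order, wn, btype="low", output="sos")
    filtered = signal.sosfiltfilt(sos, x)
    return np.abs(filtered)


def fit_template(curve: np.ndarray, threshold: float = NO_ASSIST_THRESHOLD,
                 grid_step: float = 2.0) -> AssistanceProfile | None:
    """Least-squares template matching on a cleaned 101-sample curve.

    Returns None (the "no assistance" sentinel) when the curve never exceeds
    ``threshold``. Otherwise: coarse search over knot triples on a
    ``grid_step``-% grid with the closed-form optimal peak for each triple,
    then Nelder-Mead refinement of the knots from the best starts (ties
    broken toward earlier start time).
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape != (101,):
        raise DomainError("curve must have 101 samples")
    if np.any(curve < -1e-12):
        raise DomainError("curve must be non-negative (postprocess first)")
    if float(np.max(curve)) < threshold:
        return None

    knots = np.arange(0.0, 100.0 + 1e-9, grid_step)
    i, j, k = np.meshgrid(np.arange(len(knots)), np.arange(len(knots)),
                          np.arange(len(knots)), indexing="ij")
    valid = (i < j) & (j < k)
    triples = np.column_stack([knots[i[valid]], knots[j[valid]],
                               knots[k[valid]]])

    # closed-form optimal peak for each knot triple, evaluated in blocks
    yy = float(curve @ curve)
    n = len(triples)
    sse = np.empty(n)
    tg = PHASE_GRID[None, :]
    for start in range(0, n, 4096):
        block = triples[start:start + 4096]
        t1c, t2c, t3c = (block[:, m:m + 1] for m in range(3))
        s = np.clip((tg - t1c) / (t2c - t1c), 0.0, 1.0)
        u = np.clip((tg - t2c) / (t3c - t2c), 0.0, 1.0)
        basis = np.where(tg <= t2c, 3.0 * s**2 - 2.0 * s**3,
                         1.0 - 3.0 * u**2 + 2.0 * u**3)
        bb = np.einsum("ij,ij->i", basis, basis)
        by = basis @ curve
        peak = np.where(bb > 0, np.maximum(by / np.where(bb > 0, bb, 1.0),
                                           0.0), 0.0)
        sse[start:start + 4096] = yy - 2.0 * peak * by + peak**2 * bb

    order_idx = np.lexsort((triples[:, 0], sse))  # ties -> earlier t1

    def objective(params):
        t1, t2, t3 = params
        if not (0.0 <= t1 < t2 < t3 <= 100.0) or t2 - t1 < 0.5 or \
                t3 - t2 < 0.5:
            return yy * 10.0 + abs(t1) + abs(t3)  # outside feasible box
        basis = _template_values(PHASE_GRID, 1.0, t1, t2, t3)
        bb = float(basis @ basis)
        by = float(basis @ curve)
        peak = max(by / bb, 0.0) if bb > 0 else 0.0
        return yy - 2.0 * peak * by + peak**2 * bb

    def residuals(params):
        t1, t2, t3 = params
        if not (0.0 <= t1 < t2 < t3 <= 100.0):
            return curve + yy
        basis = _template_values(PHASE_GRID, 1.0, t1, t2, t3)
        bb = float(basis @ basis)
        peak = max(float(basis @ curve) / bb, 0.0) if bb > 0 else 0.0
        return peak * basis - curve

    best = None
    for start_idx in order_idx[:3]:
        res = optimize.minimize(
            objective, triples[start_idx], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000})
        x = res.x
        if 0.0 <= x[0] < x[1] < x[2] <= 100.0:
            polish = optimize.least_squares(
                residuals, x, xtol=1e-15, ftol=1e-15, gtol=1e-15,
                diff_step=1e-6)
            if polish.cost * 2.0 <= res.fun + 1e-15:
                x = polish.x
        fun = objective(tuple(x))
        cand = (fun, x[0], tuple(x))
        if best is None or cand < best:
            best = cand
    _, _, (t1, t2, t3) = best
    basis = _template_values(PHASE_GRID, 1.0, t1, t2, t3)
    bb = float(basis @ basis)
    peak = max(float(basis @ curve) / bb, 0.0) if bb > 0 else 0.0
    resid = float(np.sqrt(max(objective((t1, t2, t3)), 0.0) / 101.0))
    return AssistanceProfile(
        peak_value=peak, start_time=float(t1), peak_time=float(t2),
        end_time=float(t3), fit_residual=resid)
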