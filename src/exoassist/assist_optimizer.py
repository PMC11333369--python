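"""Per-timestep static optimization of muscle redundancy with assistance.

At each 1% phase sample the solver distributes the net ankle moment demand
over muscles and auxiliary actuators by minimizing the instantaneous effort
criterion

    J = sum_i a_i^2 + sum_j (tau_j / w_j)^2

subject to the moment balance

    tau_net = sum_i sign_i r_i(theta) F_i(a_i) + sum_j tau_j,

with a_i in [0.02, 1] and tau_j box-bounded (the ideal assistive actuator is
unbounded and carries penalty weight w = 1e6, so the optimizer uses it
freely). Under the rigid-tendon Hill law the muscle force is linear in
activation, so this is a separable box-constrained quadratic program with a
single linear equality; it is solved exactly by parametric KKT analysis
(piecewise-linear root find in the Lagrange multiplier) with deterministic
tie-breaking, giving machine-precision moment-balance residuals.

Four walking conditions are supported: ``no_exo`` (bare leg), ``na`` (device
worn, unpowered: the sole's added mass raises swing demand), ``oa``
(ideal-actuator optimal assistance) and ``pa`` (a parameterized assistance
profile applied as exogenous torque).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError, InfeasibleError
from .gait_synth import GaitCycle, SubjectProfile
from .musculotendon import (ACTIVATION_MAX, ACTIVATION_MIN, MuscleParams,
                            force_length, force_velocity,
                            kinematics_to_state)

IDEAL_WEIGHT = 1.0e6  # penalty weight of the ideal assistive actuator
RESERVE_BOUND = 25.0  # Nm, reserve-actuator threshold
_G = 9.81

CONDITIONS = ("no_exo", "na", "oa", "pa")


@dataclass(frozen=True)
class ActuatorSpec:
    """One auxiliary torque source of the effort criterion."""

    kind: str  # "reserve" | "residual" | "ideal"
    weight: float = 1.0  # penalty weight w (Nm)
    bounds: tuple | None = (-RESERVE_BOUND, RESERVE_BOUND)  # Nm; None = unbounded

    def __post_init__(self):
        if self.kind not in ("reserve", "residual", "ideal"):
            raise ConfigurationError(f"unknown actuator kind {self.kind!r}")
        if self.weight <= 0:
            raise ConfigurationError("penalty weight must be positive")
        if self.bounds is not None and self.bounds[0] > self.bounds[1]:
            raise ConfigurationError("actuator bounds reversed")


def ideal_actuator(weight: float = IDEAL_WEIGHT) -> ActuatorSpec:
    return ActuatorSpec(kind="ideal", weight=weight, bounds=None)


def reserve_actuator(weight: float = 1.0,
                     bound: float = RESERVE_BOUND) -> ActuatorSpec:
    return ActuatorSpec(kind="reserve", weight=weight, bounds=(-bound, bound))


@dataclass
class TimestepProblem:
    """Moment-balance problem at one phase sample (torques in absolute Nm)."""

    muscle_states: list  # MuscleState per muscle (activation unset)
    muscle_params: list  # MuscleParams per muscle
    angle_deg: float
    net_moment: float  # demand tau_net, Nm (plantarflexion positive)
    actuators: list = field(default_factory=list)  # ActuatorSpec
    assist_torque: float = 0.0  # exogenous (PA) torque, Nm
    min_activations: np.ndarray | None = None  # per-muscle lower bounds

    def __post_init__(self):
        if len(self.muscle_states) != len(self.muscle_params):
            raise ConfigurationError("muscle states/params length mismatch")
        if not np.isfinite(self.net_moment):
            raise DomainError("net-moment demand must be finite")
        if len(self.muscle_params) + len(self.actuators) == 0:
            raise ConfigurationError("at least one torque source is required")


@dataclass
class ActivationSolution:
    """KKT-optimal activations and actuator torques at one timestep."""

    activations: np.ndarray  # per muscle, in [0.02, 1]
    actuator_torques: np.ndarray  # Nm per actuator
    objective: float  # J
    balance_residual: float  # Nm (achieved - demanded)


def _torque_gains(problem: TimestepProblem) -> np.ndarray:
    """Nm of ankle moment per unit activation, per muscle (signed)."""
    gains = np.empty(len(problem.muscle_params))
    for i, (state, params) in enumerate(
            zip(problem.muscle_states, problem.muscle_params)):
        f_unit = (params.max_isometric_force
                  * force_length(state.normalized_length)
                  * force_velocity(state.normalized_velocity,
                                   params.max_contraction_velocity))
        gains[i] = (params.action_sign * params.moment_arm(problem.angle_deg)
                    * f_unit)
    return gains


def solve_timestep(problem: TimestepProblem) -> ActivationSolution:
    """Solve the box-constrained effort QP at one timestep, exactly.

    Every variable has objective q x^2 and enters the balance with
    coefficient c, so at multiplier ``lam`` the optimum is
    x(lam) = clip(lam c / (2 q), lo, hi). The balance g(lam) = sum c x(lam)
    is piecewise linear and non-decreasing; the root is found by sorting the
    clip breakpoints and solving the containing segment analytically.
    """
    gains = _torque_gains(problem)
    n_m = len(gains)
    lo = np.full(n_m, ACTIVATION_MIN)
    if problem.min_activations is not None:
        lo = np.maximum(lo, np.asarray(problem.min_activations, dtype=float))
    hi = np.full(n_m, ACTIVATION_MAX)
    q = np.ones(n_m)
    c = gains.copy()

    for spec in problem.actuators:
        q = np.append(q, 1.0 / spec.weight**2)
        c = np.append(c, 1.0)
        if spec.bounds is None:
            lo = np.append(lo, -np.inf)
            hi = np.append(hi, np.inf)
        else:
            lo = np.append(lo, spec.bounds[0])
            hi = np.append(hi, spec.bounds[1])

    demand = problem.net_moment - problem.assist_torque

    def x_of(lam: float) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            raw = lam * c / (2.0 * q)
        raw = np.where(c == 0.0, 0.0, raw)
        return np.clip(raw, lo, hi)

    # breakpoints where any variable saturates
    with np.errstate(divide="ignore", invalid="ignore"):
        bp_lo = 2.0 * q * lo / c
        bp_hi = 2.0 * q * hi / c
    bps = np.concatenate([bp_lo, bp_hi])[np.tile(c != 0.0, 2)]
    bps = np.unique(np.concatenate([bps[np.isfinite(bps)], [0.0]]))

    def g_of(lam: float) -> float:
        return float(c @ x_of(lam))

    g_vals = np.array([g_of(b) for b in bps])
    free_slope = float(np.sum(np.where(c != 0.0, c**2 / (2.0 * q), 0.0)))

    if demand <= g_vals[0]:
        # below lowest breakpoint: all c>0 vars at lo, c<0 at hi, slope from
        # unbounded vars only
        slope = float(np.sum(
            (c**2 / (2.0 * q))[np.isinf(lo) | np.isinf(hi)]))
        if g_vals[0] - demand > 1e-9 and slope <= 0.0:
            raise InfeasibleError(
                f"demand {demand:.3f} Nm below minimum achievable "
                f"{g_vals[0]:.3f} Nm")
        lam = bps[0] + (demand - g_vals[0]) / slope if slope > 0 else bps[0]
    elif demand >= g_vals[-1]:
        slope = float(np.sum(
            (c**2 / (2.0 * q))[np.isinf(lo) | np.isinf(hi)]))
        if demand - g_vals[-1] > 1e-9 and slope <= 0.0:
            raise InfeasibleError(
                f"demand {demand:.3f} Nm above maximum achievable "
                f"{g_vals[-1]:.3f} Nm")
        lam = bps[-1] + (demand - g_vals[-1]) / slope if slope > 0 else bps[-1]
    else:
        k = int(np.searchsorted(g_vals, demand, side="left"))
        lam0, lam1 = bps[k - 1], bps[k]
        g0, g1 = g_vals[k - 1], g_vals[k]
        lam = lam0 if g1 == g0 else lam0 + (demand - g0) * (lam1 - lam0) / (g1 - g0)

    x = x_of(lam)
    a = x[:n_m]
    taus = x[n_m:]
    weights = np.array([s.weight for s in problem.actuators])
    objective = float(a @ a + np.sum((taus / weights) ** 2)) if taus.size \
        else float(a @ a)
    residual = float(c @ x - demand)
    if abs(residual) > 1e-6:
        raise InfeasibleError(
            f"moment balance residual {residual:.2e} Nm exceeds tolerance")
    return ActivationSolution(
        activations=a, actuator_torques=taus, objective=objective,
        balance_residual=residual)


@dataclass(frozen=True)
class ConditionSpec:
    """Assistance condition and device mass properties."""

    condition: str  # one of CONDITIONS
    cuff_mass: float = 1.5  # kg (acts proximal to the ankle; no moment term)
    sole_mass: float = 0.5  # kg
    sole_com_distance: float = 0.10  # m anterior of the ankle
    pa_profile: object | None = None  # AssistanceProfile, PA only

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.cuff_mass < 0 or self.sole_mass < 0:
            raise ConfigurationError("device masses must be >= 0")
        if (self.pa_profile is not None) != (self.condition == "pa"):
            raise ConfigurationError(
                "pa_profile must be present iff condition == 'pa'")


def _swing_weight(phase: np.ndarray | float, t_off: float = 63.0) -> np.ndarray:
    """Smooth 0->1->0 swing window: rises over [t_off, t_off+8], falls 92->100."""
    p = np.asarray(phase, dtype=float)

    def smooth(s):
        s = np.clip(s, 0.0, 1.0)
        return 3.0 * s**2 - 2.0 * s**3

    return smooth((p - t_off) / 8.0) * (1.0 - smooth((p - 92.0) / 8.0))


def added_mass_moment(condition: ConditionSpec, cycle: GaitCycle,
                      phase: float | np.ndarray) -> float | np.ndarray:
    """Ankle-moment increment (Nm) from the sole's added mass during swing.

    Pendulum approximation for the foot-fixed point mass: gravity on the
    sole (anterior of the ankle) tends to plantarflex the hanging foot, so
    carrying it costs the dorsiflexors extra effort — the increment is
    dorsiflexion-directed (non-positive in the plantarflexion-positive
    convention). The gravitational term m g d is augmented by the inertial
    term m d^2 theta_ddot, windowed to swing, with the magnitude floored at
    zero so the device mass only ever adds demand. Zero for ``no_exo`` and
    identically linear in the sole mass.
    """
    if condition.condition == "no_exo":
        return np.zeros_like(np.asarray(phase, dtype=float)) if \
            np.ndim(phase) else 0.0
    theta = np.deg2rad(cycle.ankle_angle)
    t = cycle.times
    theta_dd = np.gradient(np.gradient(theta, t), t)  # rad/s^2
    p = np.asarray(phase, dtype=float)
    idx = np.clip(np.round(p).astype(int), 0, 100)
    m, d = condition.sole_mass, condition.sole_com_distance
    per_kg = np.maximum(0.0, d * (_G * np.cos(theta[idx])
                                  + d * theta_dd[idx]))
    out = -m * per_kg * _swing_weight(p)
    return float(out) if out.ndim == 0 else out


def _phase_angular_velocity(cycle: GaitCycle) -> np.ndarray:
    """Ankle angular velocity (deg/s) at each phase sample."""
    return np.gradient(cycle.ankle_angle, cycle.times)


def build_problems(cycle: GaitCycle, subject: SubjectProfile,
                   muscles: list[MuscleParams], condition: ConditionSpec,
                   stance_end: float = 63.0) -> list[TimestepProblem]:
    """Assemble the 101 per-timestep problems for one cycle and condition."""
    omega = _phase_angular_velocity(cycle)
    demand = cycle.net_moment * subject.mass  # Nm
    demand = demand + added_mass_moment(condition, cycle, cycle.phase_grid)

    assist = np.zeros(101)
    if condition.condition == "pa":
        from .profile_param import eval_template
        assist = eval_template(condition.pa_profile, cycle.phase_grid) \
            * subject.mass  # Nm

    actuators = [reserve_actuator()]
    if condition.condition == "oa":
        actuators = [ideal_actuator(), reserve_actuator()]

    problems = []
    for k in range(101):
        states = [kinematics_to_state(m, cycle.ankle_angle[k], omega[k])
                  for m in muscles]
        min_a = np.array([
            m.min_activation_stance if cycle.phase_grid[k] <= stance_end
            else ACTIVATION_MIN for m in muscles])
        problems.append(TimestepProblem(
            muscle_states=states, muscle_params=muscles,
            angle_deg=float(cycle.ankle_angle[k]),
            net_moment=float(demand[k]), actuators=list(actuators),
            assist_torque=float(assist[k]), min_activations=min_a))
    return problems


def solve_cycle(cycle: GaitCycle, subject: SubjectProfile,
                muscles: list[MuscleParams], condition: ConditionSpec
                ) -> list[ActivationSolution]:
    """Solve all 101 timesteps of one cycle under one condition."""
    if cycle is None:
        raise DomainError("cycle is required")
    solutions = []
    for k, problem in enumerate(
            build_problems(cycle, subject, muscles, condition)):
        try:
            solutions.append(solve_timestep(problem))
        except InfeasibleError as exc:
            raise InfeasibleError(
                f"timestep {k} ({cycle.phase_grid[k]:.0f}% of cycle): {exc}",
                phase=float(cycle.phase_grid[k])) from exc
    return solutions


def derive_oa(cycle: GaitCycle, subject: SubjectProfile,
              muscles: list[MuscleParams],
              condition: ConditionSpec | None = None) -> np.ndarray:
    """Raw optimal-assistance torque curve: the ideal actuator's trajectory.

    Returns 101 signed samples in Nm/kg (plantarflexion positive; both
    directions permitted at this stage).
    """
    condition = condition or ConditionSpec(condition="oa")
    if condition.condition != "oa":
        raise ConfigurationError("derive_oa requires the 'oa' condition")
    solutions = solve_cycle(cycle, subject, muscles, condition)
    # ideal actuator is the first actuator under OA (see build_problems)
    torque = np.array([s.actuator_torques[0] for s in solutions])
    return torque / subject.mass


def sum_squared_activation(solutions: list[ActivationSolution]) -> float:
    """Total squared activation over a cycle (effort summary)."""
    return float(sum(np.sum(s.activations**2) for s in solutions))
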