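"""Reduced sagittal-plane ankle musculotendon set with a Hill-type force law.

Three lumped actuators span the ankle: soleus and gastrocnemius (combined
medial/lateral heads) as plantarflexors, tibialis anterior as the dorsiflexor.
Forces follow the rigid-tendon multiplicative Hill form

    F = a * Fmax * f_L(l) * f_V(v)

with a Gaussian active force-length curve and a Hill hyperbola for the
force-velocity relation (clipped at 1.4 during lengthening). Activation is
bounded to [0.02, 1]; the lower bound models muscle tone.

Sign conventions: ankle angle is dorsiflexion-positive, joint torque is
plantarflexion-positive. ``action_sign`` is +1 for plantarflexors and -1 for
dorsiflexors, so a plantarflexor lengthens as the ankle dorsiflexes:
d(length)/dt = action_sign * r(angle) * omega, equivalently -r_axis * omega
with r_axis the moment arm signed about the dorsiflexion-positive axis.

Because the tendon is rigid, ``optimal_fiber_length`` is an effective
musculotendon length scale (0.2-0.3 m) rather than an anatomical fiber
length; it keeps normalized length within a plausible band over the
physiological angle range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

ACTIVATION_MIN = 0.02
ACTIVATION_MAX = 1.0

#: physiological ankle angle range, degrees (dorsiflexion positive)
ANGLE_RANGE = (-35.0, 35.0)

_FL_WIDTH = 0.45  # Gaussian width of the active force-length curve
_FV_AF = 0.25  # Hill shape factor (shortening)
_FV_ECC_MAX = 1.4  # eccentric plateau
_DEG = np.pi / 180.0


@dataclass(frozen=True)
class MuscleParams:
    """Constant parameters of one lumped musculotendon actuator.

    ``moment_arm_coeffs`` are polynomial coefficients in the ankle angle in
    degrees, lowest order first, yielding the (positive) moment-arm magnitude
    in metres. ``min_activation_stance`` is an optional co-contraction floor
    applied during stance; it models demand on a biarticular muscle from the
    un-modelled neighbouring joint (used for the gastrocnemius) and defaults
    to the global activation lower bound.
    """

    name: str
    max_isometric_force: float  # N
    optimal_fiber_length: float  # m (effective, rigid tendon)
    max_contraction_velocity: float  # optimal lengths / s
    moment_arm_coeffs: tuple  # m, polynomial in angle (deg), lowest order first
    action_sign: int  # +1 plantarflexor, -1 dorsiflexor
    muscle_mass: float  # kg
    min_activation_stance: float = ACTIVATION_MIN

    def __post_init__(self):
        if self.max_isometric_force <= 0:
            raise ConfigurationError("max_isometric_force must be positive")
        if self.optimal_fiber_length <= 0 or self.max_contraction_velocity <= 0:
            raise ConfigurationError("length/velocity scales must be positive")
        if self.action_sign not in (-1, 1):
            raise ConfigurationError("action_sign must be +1 or -1")
        if self.muscle_mass <= 0:
            raise ConfigurationError("muscle_mass must be positive")
        if not ACTIVATION_MIN <= self.min_activation_stance <= ACTIVATION_MAX:
            raise ConfigurationError("min_activation_stance outside [0.02, 1]")
        angles = np.linspace(*ANGLE_RANGE, 71)
        arms = np.polyval(self.moment_arm_coeffs[::-1], angles)
        if np.any(np.abs(arms) > 0.08):
            raise ConfigurationError(
                f"{self.name}: |moment arm| exceeds 0.08 m in the "
                "physiological range")
        if np.any(arms <= 0):
            raise ConfigurationError(
                f"{self.name}: moment-arm magnitude must stay positive")

    def moment_arm(self, angle_deg: float) -> float:
        """Moment-arm magnitude (m) at the given ankle angle."""
        return float(np.polyval(self.moment_arm_coeffs[::-1], angle_deg))

    def _arm_integral(self, angle_deg: float) -> float:
        """Integral of the moment arm over joint angle in radians, from 0."""
        theta = angle_deg * _DEG
        total = 0.0
        for k, c in enumerate(self.moment_arm_coeffs):
            total += c * (1.0 / _DEG) ** k * theta ** (k + 1) / (k + 1)
        return total


@dataclass
class MuscleState:
    """Kinematic state (and, once solved, activation) of one muscle."""

    normalized_length: float  # l, dimensionless
    normalized_velocity: float  # v, optimal lengths/s, shortening negative
    activation: float | None = None  # a in [0.02, 1]

    def __post_init__(self):
        if self.activation is not None:
            _check_activation(self.activation)


def _check_activation(a: float):
    if not ACTIVATION_MIN <= a <= ACTIVATION_MAX:
        raise DomainError(
            f"activation {a} outside [{ACTIVATION_MIN}, {ACTIVATION_MAX}]")


def force_length(l: float | np.ndarray) -> float | np.ndarray:
    """Active force-length multiplier: Gaussian about the optimal length."""
    return np.exp(-(((np.asarray(l) - 1.0) / _FL_WIDTH) ** 2))


def force_velocity(v: float | np.ndarray,
                   vmax: float = 10.0) -> float | np.ndarray:
    """Force-velocity multiplier: Hill hyperbola (concentric), saturating
    eccentric branch clipped at 1.4. ``v`` in optimal lengths/s, shortening
    negative."""
    v = np.asarray(v, dtype=float)
    con = np.clip((vmax + v) / (vmax - v / _FV_AF), 0.0, 1.0)
    ecc = 1.0 + (_FV_ECC_MAX - 1.0) * v / (v + vmax / 7.5)
    out = np.where(v < 0, con, np.minimum(ecc, _FV_ECC_MAX))
    return float(out) if out.ndim == 0 else out


def muscle_force(state: MuscleState, params: MuscleParams) -> float:
    """Tensile force (N) of one muscle: a * Fmax * f_L(l) * f_V(v)."""
    if state.activation is None:
        raise DomainError("activation is unset")
    _check_activation(state.activation)
    f = (state.activation * params.max_isometric_force
         * force_length(state.normalized_length)
         * force_velocity(state.normalized_velocity,
                          params.max_contraction_velocity))
    return float(max(f, 0.0))


def kinematics_to_state(muscle: MuscleParams, angle_deg: float,
                        angular_velocity_degs: float = 0.0) -> MuscleState:
    """Map joint kinematics to normalized muscle length and velocity.

    Calibrated so the neutral angle (0 deg) gives l = 1. Length changes follow
    the geometric relation d(length) = -r_axis d(theta) with r_axis the
    moment arm about the dorsiflexion-positive axis (= -action_sign * |r|);
    plantarflexors therefore lengthen with dorsiflexion. ``l`` is clamped to
    [0.5, 1.5], with a warning outside the physiological angle range.
    """
    if not ANGLE_RANGE[0] <= angle_deg <= ANGLE_RANGE[1]:
        warnings.warn(
            f"ankle angle {angle_deg} deg outside physiological range "
            f"{ANGLE_RANGE}; state clamped", stacklevel=2)
        angle_deg = float(np.clip(angle_deg, *ANGLE_RANGE))
    l_opt = muscle.optimal_fiber_length
    dlen = muscle.action_sign * muscle._arm_integral(angle_deg)  # m
    l = float(np.clip(1.0 + dlen / l_opt, 0.5, 1.5))
    omega = angular_velocity_degs * _DEG  # rad/s
    v = muscle.action_sign * muscle.moment_arm(angle_deg) * omega / l_opt
    return MuscleState(normalized_length=l, normalized_velocity=float(v))


def moment_contribution(muscle: MuscleParams, angle_deg: float,
                        force: float) -> float:
    """Signed ankle moment (Nm, plantarflexion positive) of one muscle force."""
    if force < 0:
        raise DomainError("muscle force must be non-negative")
    return muscle.action_sign * muscle.moment_arm(angle_deg) * force


def default_muscles(gastroc_stance_floor: float = ACTIVATION_MIN
                    ) -> list[MuscleParams]:
    """The default calf set at published musculoskeletal-model scale.

    ``gastroc_stance_floor`` > 0.02 enables the knee-demand co-contraction
    floor on the gastrocnemius during stance (biarticular knee-flexion demand
    that ankle assistance cannot remove); the default leaves it off.
    """
    return [
        MuscleParams(
            name="soleus", max_isometric_force=3549.0,
            optimal_fiber_length=0.25, max_contraction_velocity=10.0,
            moment_arm_coeffs=(0.048, -8.0e-5), action_sign=+1,
            muscle_mass=0.45),
        MuscleParams(
            name="gastrocnemius", max_isometric_force=2241.0,
            optimal_fiber_length=0.30, max_contraction_velocity=10.0,
            moment_arm_coeffs=(0.048, -8.0e-5), action_sign=+1,
            muscle_mass=0.40,
            min_activation_stance=gastroc_stance_floor),
        MuscleParams(
            name="tibialis_anterior", max_isometric_force=905.0,
            optimal_fiber_length=0.22, max_contraction_velocity=10.0,
            moment_arm_coeffs=(0.037, 5.0e-5), action_sign=-1,
            muscle_mass=0.15),
    ]


def muscles_from_config(entries: list[dict]) -> list[MuscleParams]:
    """Build muscle parameter sets from a parsed YAML/JSON list of mappings.

    Each entry requires the ``MuscleParams`` field names; ``moment_arm_coeffs``
    is a list (lowest order first, metres per deg^k).
    """
    out = []
    for entry in entries:
        try:
            kwargs = dict(entry)
            kwargs["moment_arm_coeffs"] = tuple(kwargs["moment_arm_coeffs"])
            out.append(MuscleParams(**kwargs))
        except (TypeError, KeyError) as exc:
            raise ConfigurationError(f"bad muscle entry {entry!r}: {exc}") from exc
    return out
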