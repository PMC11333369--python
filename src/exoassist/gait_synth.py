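"""Synthetic subjects and speed-dependent ankle gait cycles.

Generates the inputs every downstream stage consumes: a walking population
(anthropometrics drawn from treadmill-study statistics) and time-normalized
gait cycles (101 samples, 0-100% of stride in 1% steps) of ankle angle and
mass-normalized net ankle moment.

The curves are sums of zero-slope cubic Hermite segments through landmark
points whose values interpolate linearly in walking speed between calibrated
anchors:

===================  =========  =========
landmark             0.5 m/s    1.8 m/s
===================  =========  =========
max dorsiflexion     25 deg     15 deg
max plantarflexion   0 deg      15 deg
PF-angle peak time   70 %       60 %
peak net moment      1.1 Nm/kg  1.7 Nm/kg
peak-moment time     50 %       45 %
===================  =========  =========

With ``noise_sd=0`` every landmark is met exactly (dorsiflexion and moment
peaks fall on grid samples at the anchor speeds), so the generator doubles as
a calibration oracle for the rest of the pipeline.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DomainError

PHASE_GRID = np.arange(101, dtype=float)  # percent of gait cycle

SPEED_MIN = 0.5
SPEED_MAX = 1.8
#: 14-level treadmill speed grid, m/s
DEFAULT_SPEED_GRID = tuple(np.round(np.arange(0.5, 1.81, 0.1), 1))

#: segment lengths as fractions of stature (standard anthropometric tables)
DEFAULT_SEGMENT_FRACTIONS = {
    "thigh_length": 0.245,
    "calf_length": 0.246,
    "foot_length": 0.152,
    "torso_length": 0.288,
    "pelvis_width": 0.191,
}

_G = 9.81  # m/s^2


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics of one synthetic walker (9 of the 13 predictor features)."""

    subject_id: str
    sex: str  # "female" | "male"
    mass: float  # kg
    height: float  # m
    bmi: float  # kg/m^2
    thigh_length: float  # m
    calf_length: float  # m
    foot_length: float  # m
    torso_length: float  # m
    pelvis_width: float  # m

    def __post_init__(self):
        if self.mass <= 0 or self.height <= 0:
            raise DomainError("mass and height must be positive")
        if self.sex not in ("female", "male"):
            raise DomainError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if abs(self.bmi - self.mass / self.height**2) > 1e-9 * max(self.bmi, 1.0):
            raise DomainError("bmi inconsistent with mass/height^2")
        for name in ("thigh_length", "calf_length", "foot_length",
                     "torso_length", "pelvis_width"):
            value = getattr(self, name)
            if not (0 < value < self.height):
                raise DomainError(f"{name}={value} outside (0, height)")


@dataclass(frozen=True)
class GaitCycle:
    """One time-normalized stride of ankle kinematics and kinetics.

    ``ankle_angle`` is in degrees, dorsiflexion positive; ``net_moment`` is the
    mass-normalized net ankle moment in Nm/kg, plantarflexion positive.
    """

    subject_id: str
    speed: float  # m/s
    ankle_angle: np.ndarray  # deg, 101 samples
    net_moment: np.ndarray  # Nm/kg, 101 samples
    stride_length: float  # m
    cadence: float  # steps/min
    max_heel_clearance: float  # m
    duration: float  # s
    phase_grid: np.ndarray = field(default_factory=lambda: PHASE_GRID.copy())

    def __post_init__(self):
        for name in ("ankle_angle", "net_moment", "phase_grid"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (101,):
                raise DomainError(f"{name} must have exactly 101 samples")
            object.__setattr__(self, name, arr)
        if self.speed <= 0:
            raise DomainError("speed must be positive")
        if abs(self.duration - self.stride_length / self.speed) > 1e-9 * self.duration:
            raise DomainError("duration inconsistent with stride_length/speed")
        if abs(self.cadence - 120.0 / self.duration) > 1e-9 * self.cadence:
            raise DomainError("cadence inconsistent with 120/duration")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, spanning [0, duration]."""
        return self.phase_grid / 100.0 * self.duration


@dataclass(frozen=True)
class PopulationConfig:
    """Population statistics and generator settings."""

    mass_mean: float = 68.5  # kg
    mass_sd: float = 11.33
    height_mean: float = 1.71  # m
    height_sd: float = 0.07
    male_fraction: float = 13.0 / 22.0
    segment_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_FRACTIONS))
    segment_jitter_sd: float = 0.03  # relative jitter on segment fractions
    cycle_noise_sd: float = 0.05  # multiplicative amplitude noise on cycles
    timing_noise_sd: float = 1.0  # additive landmark-timing noise, % of cycle
    speed_grid: tuple = DEFAULT_SPEED_GRID
    stride_coeff: float = 1.25  # stride_length = stride_coeff * speed**0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("mass_sd", "height_sd", "segment_jitter_sd",
                     "cycle_noise_sd", "timing_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must lie in [0, 1]")
        if self.mass_mean <= 0 or self.height_mean <= 0:
            raise ConfigurationError("mean mass and height must be positive")
        grid = np.asarray(self.speed_grid, dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ConfigurationError("speed_grid must be strictly increasing")
        missing = set(DEFAULT_SEGMENT_FRACTIONS) - set(self.segment_fractions)
        if missing:
            raise ConfigurationError(f"segment_fractions missing {sorted(missing)}")


def speed_landmarks(speed: float) -> dict:
    """Continuous landmark values at ``speed`` (linear in speed between anchors).

    Returns a dict with keys ``max_df_deg``, ``max_pf_deg``, ``t_df``, ``t_pf``,
    ``peak_moment``, ``t_peak_moment``, ``t_toe_off`` (all timings in % cycle).
    """
    if speed <= 0:
        raise DomainError("speed must be positive")
    u = (speed - SPEED_MIN) / (SPEED_MAX - SPEED_MIN)
    return {
        "max_df_deg": 25.0 - 10.0 * u,
        "max_pf_deg": 15.0 * u,
        "t_df": 45.0,
        "t_pf": 70.0 - 10.0 * u,
        "peak_moment": 1.1 + 0.6 * u,
        "t_peak_moment": 50.0 - 5.0 * u,
        "t_toe_off": 63.0 - 5.0 * u,
    }


def _hermite_through(knot_t: np.ndarray, knot_v: np.ndarray,
                     t: np.ndarray) -> np.ndarray:
    """Piecewise cubic through (knot_t, knot_v) with zero slope at every knot.

    Each segment is the smoothstep blend v0 + (v1-v0)*(3s^2-2s^3); the curve is
    C^1 and attains its extrema exactly at the knots.
    """
    knot_t = np.asarray(knot_t, dtype=float)
    knot_v = np.asarray(knot_v, dtype=float)
    idx = np.clip(np.searchsorted(knot_t, t, side="right") - 1, 0,
                  len(knot_t) - 2)
    t0, t1 = knot_t[idx], knot_t[idx + 1]
    v0, v1 = knot_v[idx], knot_v[idx + 1]
    s = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return v0 + (v1 - v0) * (3.0 * s**2 - 2.0 * s**3)


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(subject_id.encode())]))


def sample_subject(config: PopulationConfig, subject_index: int) -> SubjectProfile:
    """Draw one subject from the configured population, deterministically.

    Mass and height come from (possibly degenerate) normal distributions and
    are resampled while nonpositive; sex is Bernoulli with the configured male
    fraction; segment lengths are height fractions with relative jitter.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, int(subject_index)]))

    def _positive_normal(mean, sd):
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if x > 0:
                return float(x)
        raise ConfigurationError("could not draw a positive value; check mean/SD")

    mass = _positive_normal(config.mass_mean, config.mass_sd)
    height = _positive_normal(config.height_mean, config.height_sd)
    sex = "male" if rng.uniform() < config.male_fraction else "female"
    segments = {}
    for name, frac in config.segment_fractions.items():
        jitter = rng.normal(0.0, config.segment_jitter_sd)
        segments[name] = float(frac * height * (1.0 + jitter))
    return SubjectProfile(
        subject_id=f"S{subject_index:03d}",
        sex=sex,
        mass=mass,
        height=height,
        bmi=mass / height**2,
        **segments,
    )


def generate_cycle(subject: SubjectProfile, speed: float, noise_sd: float = 0.05,
                   seed: int = 0, timing_noise_sd: float | None = None,
                   stride_coeff: float = 1.25) -> GaitCycle:
    """Generate one gait cycle at ``speed`` for ``subject``.

    Noise is multiplicative on landmark amplitudes (SD ``noise_sd``) and
    additive on landmark timings (SD ``timing_noise_sd`` percent of cycle,
    active only when ``noise_sd > 0``), with a subject-level random effect of
    the same scale so cycles from one subject are correlated.
    """
    if speed <= 0:
        raise DomainError("speed must be positive")
    if not SPEED_MIN <= speed <= SPEED_MAX:
        warnings.warn(
            f"speed {speed} m/s outside the calibrated range "
            f"[{SPEED_MIN}, {SPEED_MAX}]; landmarks are extrapolated",
            stacklevel=2)
    if timing_noise_sd is None:
        timing_noise_sd = 1.0 if noise_sd > 0 else 0.0

    lm = speed_landmarks(speed)
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(subject.subject_id.encode()),
         int(round(speed * 1000))]))
    srng = _subject_rng(seed, subject.subject_id)
    # subject-level random effect: one amplitude factor, one timing shift
    subj_amp = 1.0 + srng.normal(0.0, noise_sd)
    subj_shift = srng.normal(0.0, timing_noise_sd)

    def amp(x):
        return x * subj_amp * (1.0 + rng.normal(0.0, noise_sd))

    def tshift(t):
        return t + subj_shift + rng.normal(0.0, timing_noise_sd)

    max_df = amp(lm["max_df_deg"])
    max_pf = amp(lm["max_pf_deg"])
    peak_m = amp(lm["peak_moment"])
    dip_m = amp(0.15 + 0.05 * (speed - SPEED_MIN) / (SPEED_MAX - SPEED_MIN))
    t_df = np.clip(tshift(lm["t_df"]), 20.0, 60.0)
    t_pf = np.clip(tshift(lm["t_pf"]), t_df + 3.0, 90.0)
    t_pm = np.clip(tshift(lm["t_peak_moment"]), 20.0, 60.0)
    t_off = np.clip(tshift(lm["t_toe_off"]), t_pm + 3.0, 95.0)

    angle = _hermite_through(
        [0.0, t_df, t_pf, 100.0],
        [0.0, max_df, -max_pf, 0.0],
        PHASE_GRID)
    moment = _hermite_through(
        [0.0, 4.0, t_pm, t_off, 100.0],
        [0.0, -dip_m, peak_m, 0.0, 0.0],
        PHASE_GRID)

    stride_length = float(stride_coeff * np.sqrt(speed)
                          * (1.0 + rng.normal(0.0, noise_sd / 2.0)))
    duration = stride_length / speed
    heel = float(max(1e-4, (0.02 + 0.01 * speed)
                     * (1.0 + rng.normal(0.0, noise_sd))))
    return GaitCycle(
        subject_id=subject.subject_id,
        speed=float(speed),
        ankle_angle=angle,
        net_moment=moment,
        stride_length=stride_length,
        cadence=120.0 / duration,
        max_heel_clearance=heel,
        duration=duration,
    )


def build_dataset(config: PopulationConfig, n_subjects: int,
                  cycles_per_subject: int) -> list[tuple[SubjectProfile, GaitCycle]]:
    """Generate ``n_subjects x cycles_per_subject`` (subject, cycle) pairs.

    Speeds cycle through the configured grid so every speed level receives an
    (almost) equal share of each subject's cycles; with 14 levels and >= 140
    cycles per subject every level gets at least 10 cycles.
    """
    if n_subjects < 0 or cycles_per_subject < 0:
        raise ConfigurationError("n_subjects and cycles_per_subject must be >= 0")
    grid = list(config.speed_grid)
    pairs: list[tuple[SubjectProfile, GaitCycle]] = []
    for si in range(n_subjects):
        subject = sample_subject(config, si)
        for ci in range(cycles_per_subject):
            speed = grid[ci % len(grid)]
            cycle_seed = (config.seed * 1_000_003 + si * 1009 + ci) & 0x7FFFFFFF
            cycle = generate_cycle(
                subject, speed, noise_sd=config.cycle_noise_sd, seed=cycle_seed,
                timing_noise_sd=(config.timing_noise_sd
                                 if config.cycle_noise_sd > 0 else 0.0),
                stride_coeff=config.stride_coeff)
            pairs.append((subject, cycle))
    return pairs


def mean_subject(config: PopulationConfig | None = None,
                 subject_id: str = "MEAN") -> SubjectProfile:
    """The population-mean subject (zero-SD draw); handy for noise-free runs."""
    config = config or PopulationConfig()
    zero_sd = replace(config, mass_sd=0.0, height_sd=0.0, segment_jitter_sd=0.0)
    s = sample_subject(zero_sd, 0)
    return replace(s, subject_id=subject_id)
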