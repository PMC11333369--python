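import numpy as np
import pytest

from exoassist import gait_synth as gs
from exoassist import metabolics as mb
from exoassist.musculotendon import default_muscles


@pytest.fixture(scope="session")
def subject():
    """Population-mean subject (68.5 kg, 1.71 m)."""
    return gs.mean_subject()


@pytest.fixture(scope="session")
def muscles():
    return default_muscles()


@pytest.fixture(scope="session")
def muscles_with_floor():
    """Calf set with the gastrocnemius knee-demand floor enabled."""
    return default_muscles(0.3)


@pytest.fixture(scope="session")
def coeffs():
    return mb.MetabolicCoeffs()


@pytest.fixture(scope="session")
def cycle_13(subject):
    """Noise-free cycle at the normal walking speed."""
    return gs.generate_cycle(subject, 1.3, noise_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_cycles(subject):
    """Noise-free cycles on the full 14-level speed grid."""
    return {speed: gs.generate_cycle(subject, speed, noise_sd=0.0)
            for speed in gs.DEFAULT_SPEED_GRID}


@pytest.fixture(scope="session")
def solved_conditions(subject, cycle_13, muscles):
    """All four conditions solved on the same noise-free 1.3 m/s cycle."""
    from exoassist import assist_optimizer as ao
    from exoassist import profile_param as pp

    raw = ao.derive_oa(cycle_13, subject, muscles)
    profile = pp.fit_template(pp.postprocess_raw(raw, cycle_13.duration))
    out = {}
    for cond in ao.CONDITIONS:
        spec = ao.ConditionSpec(
            condition=cond, pa_profile=profile if cond == "pa" else None)
        out[cond] = ao.solve_cycle(cycle_13, subject, muscles, spec)
    return out
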