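import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study1_table():
    """One Study-1-scale synthetic trial table (60 subjects x 10 items)."""
    from riskimagery import gen_study1

    return gen_study1(seed=1)


@pytest.fixture(scope="session")
def study2_bundle():
    from riskimagery import gen_study2

    return gen_study2(seed=2)


@pytest.fixture(scope="session")
def small_study3():
    """A reduced Study-3 bundle (2 subjects, 2 scenarios, short baselines)
    that keeps the EEG chain fast while preserving all invariants."""
    from riskimagery import gen_study3
    from riskimagery.synthetic_data import Study3Config

    cfg = Study3Config(n_subjects=2, n_scenarios=2, baseline_seconds=16.0)
    return gen_study3(cfg, seed=3)


def make_bp_series(maps, pulse_pressure=40.0, subject_id="s01", domains=None):
    """Build a canonical 20-reading BPSeries whose MAPs equal ``maps``."""
    import pandas as pd

    from riskimagery.data_model import BPSeries, DOMAINS

    maps = np.asarray(maps, dtype=float)
    assert maps.shape == (20,)
    if domains is None:
        domains = list(DOMAINS)
    phases = ["pre_baseline"] * 8 + ["training"] + ["scenario"] * 5 + ["post_baseline"] * 6
    doms = [None] * 9 + list(domains) + [None] * 6
    sy = maps + (2.0 / 3.0) * pulse_pressure
    dy = maps - (1.0 / 3.0) * pulse_pressure
    return BPSeries(
        subject_id=subject_id,
        readings=pd.DataFrame(
            {"phase": phases, "scenario_domain": doms, "systolic": sy, "diastolic": dy}
        ),
    )
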