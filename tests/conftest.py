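import numpy as np
import pytest
from hypothesis import settings

from uevabt.design import GROUPS, TIME_POINTS, SampleRecord, StudyDesign
from uevabt.simulate import SimulationConfig, simulate_cohort

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_design(n_per_group=2, u_crea=1.0, groups=GROUPS, time_points=TIME_POINTS):
    records = []
    for g in groups:
        for i in range(n_per_group):
            subj = f"{g}_{i + 1:02d}"
            for tp in time_points:
                records.append(
                    SampleRecord(f"{subj}_{tp}", subj, g, tp, u_crea=u_crea)
                )
    return StudyDesign(records)


@pytest.fixture
def tiny_design():
    return make_design(n_per_group=2)


@pytest.fixture(scope="session")
def default_cohort():
    """One full simulated cohort at the default study conditions."""
    return simulate_cohort(SimulationConfig(seed=1))
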