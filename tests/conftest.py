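import numpy as np
import pytest

import markovcea as m


@pytest.fixture
def fixture_config() -> m.ModelConfiguration:
    return m.load_fixture()


@pytest.fixture
def lom_arm() -> m.ArmClinicalInputs:
    return m.ArmClinicalInputs(arm_label="LOM", median_pfs=1.5, median_os=8.6)


@pytest.fixture
def bev_arm() -> m.ArmClinicalInputs:
    return m.ArmClinicalInputs(arm_label="BEV+LOM", median_pfs=4.2, median_os=9.1)


def random_chain(rng: np.random.Generator) -> m.TransitionMatrix:
    """A random valid PFS/PD/Death matrix (PD->PFS = 0, Death absorbing)."""
    stay, p_pd, p_death = rng.dirichlet([3.0, 1.0, 1.0])
    p_pd_death = rng.uniform(0.0, 1.0)
    tp = m.TransitionProbabilities.from_exit_probs(p_pd, p_death, p_pd_death)
    return m.build_matrix(tp)


@pytest.fixture
def identical_arms_config() -> m.ModelConfiguration:
    """Both arms clinically and economically identical (zero increments)."""
    arm = dict(median_pfs=3.0, median_os=8.0, cost_pfs_per_cycle=500.0,
               cost_pd_per_cycle=200.0)
    return m.ModelConfiguration(
        intervention=m.ArmConfig(label="A", **arm),
        comparator=m.ArmConfig(label="B", **arm),
    )
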