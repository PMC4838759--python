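import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import popblood as pb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def coefficients() -> pd.DataFrame:
    return pb.builtin_coefficients()


@pytest.fixture(scope="session")
def chemicals() -> pd.DataFrame:
    return pb.builtin_chemicals()


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Noise-free multi-chemical cohort: fits must invert the generator."""
    spec = pb.paper_like_spec(seed=11)
    quiet = [
        pb.ChemicalSim(
            name=c.name, chem_class=c.chem_class, gm_blood=c.gm_blood,
            gsd_blood=c.gsd_blood, k_pb=c.k_pb, k_bd=c.k_bd,
            ratio_noise_cv=0.0, dbs_noise_cv=0.0,
        )
        for c in spec.chemicals
    ]
    quiet_spec = pb.SimulationSpec(chemicals=quiet, seed=11, replicate_cv=0.0)
    panel, participants, chem_table, truth = pb.simulate_cohort(quiet_spec)
    return quiet_spec, panel, participants, chem_table, truth


@pytest.fixture(scope="session")
def stochastic_cohort():
    """One seeded paper-like cohort shared by read-only tests."""
    spec = pb.paper_like_spec(seed=42)
    panel, participants, chem_table, truth = pb.simulate_cohort(spec)
    return spec, panel, participants, chem_table, truth
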