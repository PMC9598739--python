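import numpy as np
import pytest

from daphdem import simulate


@pytest.fixture(scope="session")
def default_records():
    """One simulated default experiment (192 females, fixed seed)."""
    return simulate.simulate_experiment(simulate.default_config())


@pytest.fixture(scope="session")
def default_by_treatment(default_records):
    groups = {}
    for r in default_records:
        groups.setdefault(r.treatment.key(), []).append(r)
    return groups


def make_record(ind="ind1", ca=1.74, food=2.0, temp=17.5, death_day=19,
                censored=True, maturity_day=None, moult_days=(),
                clutches=(), body_size=None):
    """Hand-built record for oracle tests."""
    if censored and body_size is None:
        body_size = 2000.0
    return simulate.IndividualRecord(
        individual_id=ind,
        treatment=simulate.Treatment(ca=ca, food=food, temp=temp),
        death_day=death_day,
        censored=censored,
        maturity_day=maturity_day,
        moult_days=list(moult_days),
        clutches=list(clutches),
        body_size=body_size,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
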