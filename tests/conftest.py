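import numpy as np
import pytest

from dogyears.taxonomy import AgeBinScheme, CauseTaxonomy, DeathRecord


@pytest.fixture(scope="session")
def taxonomy():
    return CauseTaxonomy.default()


@pytest.fixture(scope="session")
def bin_scheme():
    return AgeBinScheme.vmdb_default()


@pytest.fixture(scope="session")
def small_dog_cohort():
    """5,000 dog-like records with contamination, shared across tests."""
    from dogyears.simulate import default_dog_spec, simulate_cohort

    return simulate_cohort(default_dog_spec(), 5000, seed=20260930)


def make_death(
    id="r1",
    cohort="dog",
    sex="female",
    age=8.0,
    diagnoses=("lymphoma",),
    primary=None,
    pp="neoplastic",
    os="hematopoietic",
    event="death",
):
    """Terse DeathRecord builder for toy tests."""
    return DeathRecord(
        id=id,
        cohort=cohort,
        sex=sex,
        age_years=age,
        diagnoses=list(diagnoses),
        primary_diagnosis=primary or (diagnoses[0] if diagnoses else None),
        cause_pp=pp if event == "death" else None,
        cause_os=os if event == "death" else None,
        event=event,
    )
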