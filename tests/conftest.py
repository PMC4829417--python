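import warnings

import numpy as np
import pytest

from socdiff import SimScenario, simulate_study
from socdiff.records import PhenotypeRecord, phenotype_frame


@pytest.fixture(autouse=True)
def _quiet_unknown_warnings():
    """Unidentified-acquirer drops are expected in synthetic data."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*unidentified acquirer.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def tiny_phen():
    """Five individuals, one troop, hand-set phenotypes."""
    recs = [
        PhenotypeRecord("A", "T", "male", 9.0, 1, 30.0),
        PhenotypeRecord("B", "T", "female", 12.0, 2, 5.0),
        PhenotypeRecord("C", "T", "female", 4.0, 3, 12.0),
        PhenotypeRecord("D", "T", "male", 3.0, 4, 50.0),
        PhenotypeRecord("E", "T", "female", 7.0, 5, 0.0),
    ]
    return phenotype_frame(recs)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared across tests (two small troops)."""
    scenario = SimScenario(
        seed=11,
        troop_sizes=(16, 18),
        n_diffusions_per_troop=8,
        unknown_rate=0.0,
        tie_rate=0.1,
    )
    return simulate_study(scenario)
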