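import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from seedpellet import classify_table1, load_table1_fixture
from seedpellet.datamodel import ReplicateRecord
from seedpellet.stats import DegenerateTableWarning


@pytest.fixture(scope="session")
def table1_rows():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_report(table1_rows):
    """Default-configuration classification of the published per-lot table."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateTableWarning)
        return classify_table1(table1_rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240814)


def make_arm(days, survived=None, species="sp", treatment="bare", n_sown=None, provenance=None):
    """Build one lot-treatment arm: `days` lists emerged replicates' census
    days; `n_sown` pads with never-emerged replicates."""
    n_sown = n_sown if n_sown is not None else len(days)
    survived = survived if survived is not None else [True] * len(days)
    records = [
        ReplicateRecord(
            species=species,
            provenance=provenance,
            growth_form="herb",
            treatment=treatment,
            replicate_id=f"r{i:03d}",
            emergence_day=d,
            survived=s,
        )
        for i, (d, s) in enumerate(zip(days, survived))
    ]
    records += [
        ReplicateRecord(
            species=species,
            provenance=provenance,
            growth_form="herb",
            treatment=treatment,
            replicate_id=f"r{i:03d}",
            emergence_day=None,
            survived=None,
        )
        for i in range(len(days), n_sown)
    ]
    return records
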