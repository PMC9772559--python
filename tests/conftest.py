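import numpy as np
import pytest

from soilmicro.io_core import AbundanceTable


@pytest.fixture
def toy_table() -> AbundanceTable:
    """3 taxa x 4 samples with one dominant, one mid, one rare taxon."""
    counts = np.array(
        [
            [80, 15, 5],
            [75, 20, 5],
            [85, 10, 5],
            [70, 25, 5],
        ]
    )
    return AbundanceTable(
        ("s1", "s2", "s3", "s4"),
        ("t1", "t2", "t3"),
        counts,
        {"t1": "d__X;g__a", "t2": "d__X;g__b", "t3": "d__X;g__c"},
    )


@pytest.fixture(scope="session")
def metacommunity() -> np.ndarray:
    from soilmicro.synthetic import lognormal_metacommunity

    return lognormal_metacommunity(300, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def simulated_dataset(tmp_path_factory):
    """One full synthetic dataset directory, shared across CLI tests."""
    from soilmicro.synthetic import ExperimentDesign, simulate_experiment

    out = tmp_path_factory.mktemp("dataset")
    truth = simulate_experiment(ExperimentDesign(), seed=7, out_dir=out)
    return out, truth
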