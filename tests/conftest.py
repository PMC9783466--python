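import numpy as np
import pandas as pd
import pytest

from cagefit import synthetic
from cagefit.popgen import COUNT_COLUMNS


@pytest.fixture
def scenario():
    """Default study conditions with a fixed master seed."""
    return synthetic.SyntheticScenario(seed=7)


@pytest.fixture
def cage_data(scenario):
    """One seeded cage dataset generated under the default scenario."""
    return synthetic.gen_cage_counts(scenario)


@pytest.fixture
def single_record_cages():
    """A minimal cage table: one cage, one generation at exact HWE(0.5)."""
    return pd.DataFrame(
        [{"cage": "c1", "generation": 1, "n_R1R1": 25, "n_R1R2": 50, "n_R2R2": 25}]
    )


def make_cage_table(records):
    """Build a cage table from (cage, generation, n11, n12, n22) tuples."""
    return pd.DataFrame(
        [
            dict(zip(("cage", "generation", *COUNT_COLUMNS), rec))
            for rec in records
        ]
    )
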