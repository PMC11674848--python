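import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from adtrx import lncrna_discovery as ld
from adtrx import synthetic_data as sd


@pytest.fixture(scope="session")
def study():
    """Default-scale synthetic study used across the suite."""
    return sd.simulate_study(sd.SimConfig(seed=11))


@pytest.fixture(scope="session")
def reference(study):
    return sd.reference_catalog(study.catalog, study.truth)


@pytest.fixture(scope="session")
def scorers():
    """Coding-potential scorers calibrated on an independent training split."""
    train = sd.simulate_study(sd.SimConfig(seed=20_777, n_lncrna=200, n_genes=210))
    return ld.ScorerSet.calibrate(*sd.training_sequences(train))
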