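import numpy as np
import pytest

from bimodalkit import classify_modality, reference_rates, sample_snapshot
from bimodalkit.reactions import build_reduced_model


@pytest.fixture(scope="session")
def ref_rates():
    return reference_rates()


@pytest.fixture(scope="session")
def ref_system(ref_rates):
    return build_reduced_model(ref_rates)


@pytest.fixture(scope="session")
def ref_snapshot(ref_system):
    """Stationary snapshot of the reference two-state model (shared)."""
    return sample_snapshot(ref_system, n_cells=5000, seed=101)


@pytest.fixture(scope="session")
def ref_call(ref_snapshot):
    return classify_modality(ref_snapshot.values)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
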