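import numpy as np
import pytest

from ctxmotif.data import extract_windows, split_subjects
from ctxmotif.synth import toy_fixture


@pytest.fixture(scope="session")
def toy_cohort():
    """Tiny deterministic cohort: 4 subjects (2 SZ / 2 HC), N=6, T=40, W=10."""
    records, truth = toy_fixture()
    return records, truth


@pytest.fixture(scope="session")
def toy_windows(toy_cohort):
    records, _ = toy_cohort
    return extract_windows(records, window_length=10, stride=1)


@pytest.fixture(scope="session")
def toy_dsvae(toy_cohort, toy_windows):
    """A small DSVAE trained on the toy cohort, shared across tests."""
    from ctxmotif.models import DSVAE

    model = DSVAE(local_size=2, context_size=2, hidden_widths=(32,),
                  epochs=30, batch_size=64, seed=42)
    return model.fit(toy_windows)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
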