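import warnings

import pytest

from its2kit.synthetic_data import default_study_config, generate_study


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_study():
    """A small labeled synthetic study shared across tests (fixed seed)."""
    return generate_study(default_study_config(n_ampelomyces=20, master_seed=11))


@pytest.fixture(scope="session")
def truth_by_id(small_study):
    return {t.id: t for t in small_study.truth}
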