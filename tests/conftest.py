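import numpy as np
import pytest

from consdock import GeneratorConfig
from consdock.datasets import fenpyroximate_ci_scores, fenpyroximate_ci_specs


@pytest.fixture(scope="session")
def fpm_table():
    """The published 2-ligand x 11-function E/Z-fenpyroximate score pair."""
    return fenpyroximate_ci_scores()


@pytest.fixture(scope="session")
def fpm_specs():
    return fenpyroximate_ci_specs()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_cfg():
    """A scaled-down synthetic study for fast pipeline-level tests."""
    return GeneratorConfig(n_ci=6, n_ciii=5, n_unc=2, core_size=10, seed=7)
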