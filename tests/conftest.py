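import logging
import warnings

import numpy as np
import pytest

from affectbias import synth
from affectbias.normative import NormativeReference
from affectbias.scoring import build_cells
from affectbias.stimuli import build_registry

# boundary variance components make statsmodels chatty; the fits themselves
# are checked through their results
warnings.filterwarnings("ignore", category=RuntimeWarning, module="statsmodels")
logging.getLogger("affectbias").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture(scope="session")
def study_dataset():
    """One study-shaped synthetic dataset shared across tests (seed 7)."""
    return synth.generate_dataset(synth.GeneratorConfig(), seed=7)


@pytest.fixture(scope="session")
def norm_ref(study_dataset):
    return NormativeReference().fit(study_dataset["controls"])


@pytest.fixture(scope="session")
def scored(study_dataset, norm_ref):
    return norm_ref.transform(study_dataset["trials"])


@pytest.fixture(scope="session")
def cells(scored, study_dataset):
    return build_cells(scored, study_dataset["clinical"])


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
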