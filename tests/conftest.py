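import numpy as np
import pytest

from bindfit.equilibria import SequentialBindingModel
from bindfit.itc import ITCProtocol

# Published assay parameter sets used across the suite: stepwise Ca2+
# dissociation constants (M) and per-step enthalpies (kcal/mol) measured in
# Na+- and K+-containing buffers.
NA_KD = (265e-9, 758e-9, 379e-9)
NA_DH = (-7.7, 3.0, -9.1)
K_KD = (165.6e-9, 362.3e-9, 253e-9)
K_DH = (-7.66, 1.00, -9.44)


@pytest.fixture
def na_model() -> SequentialBindingModel:
    return SequentialBindingModel(kd=NA_KD, dh=NA_DH)


@pytest.fixture
def k_model() -> SequentialBindingModel:
    return SequentialBindingModel(kd=K_KD, dh=K_DH)


@pytest.fixture
def vpitc_protocol() -> ITCProtocol:
    """Default VP-ITC geometry: 1.4619 ml cell, 110 uM macromolecule,
    1.5 mM titrant, 2 ul discarded first injection + 28 x 10 ul."""
    return ITCProtocol()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
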