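import dataclasses

import numpy as np
import pytest

from sparsectp import AcquisitionProtocol
from sparsectp.phantom import DigitalBrainSpec, generate_digital_brain


@pytest.fixture(scope="session")
def noiseless_spec():
    return dataclasses.replace(DigitalBrainSpec(), noise_sd=0.0)


@pytest.fixture(scope="session")
def ctp_phantom(noiseless_spec):
    """Noiseless digital brain sampled under the dense CTP protocol."""
    return generate_digital_brain(noiseless_spec, AcquisitionProtocol.ctp())


@pytest.fixture(scope="session")
def mcta_phantom(noiseless_spec):
    """Noiseless digital brain sampled under the 4-frame mCTA-P protocol
    (with the protocol's +4 HU bias on the post-baseline frames)."""
    return generate_digital_brain(noiseless_spec, AcquisitionProtocol.mcta_p())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
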