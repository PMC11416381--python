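import logging

import numpy as np
import pytest

from regexgp.datasets import Peptide, PeptideDataset
from regexgp.synthetic import fixture_model

logging.getLogger("regexgp").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """Five labeled peptides with hand-checkable statistics."""
    return PeptideDataset(
        [
            Peptide("KKKKKKKKKKKK", 12.5),
            Peptide("APVPKKPRLL", 9.1),
            Peptide("QSLKQSIKKLKK", 15.0),
            Peptide("TTEEVVNNGG", 4.2),
            Peptide("KKTTQSWRYH", 13.0),
        ]
    )


@pytest.fixture
def hand_model():
    return fixture_model()
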