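import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from motifmodules import (BackgroundModel, ScanParams, build_pfm_from_sequences,
                          pfm_to_pwm)

JASPAR_ONE = """>MA0001.1 TEST
A [ 4 0 0 ]
C [ 0 4 0 ]
G [ 0 0 4 ]
T [ 0 0 0 ]
"""

JASPAR_TWO = JASPAR_ONE + """>MA0002.1 OTHER
A [ 1 2 ]
C [ 3 0 ]
G [ 0 1 ]
T [ 0 1 ]
"""


@pytest.fixture
def jaspar_one_text():
    return JASPAR_ONE


@pytest.fixture
def jaspar_two_text():
    return JASPAR_TWO


@pytest.fixture
def rng():
    return np.random.default_rng(20221020)


@pytest.fixture
def aataaa_pwm():
    """Sharp matrix for the canonical poly(A) hexamer (zero pseudocount)."""
    pfm = build_pfm_from_sequences(["AATAAA"], "HEX", "hexamer")
    return pfm_to_pwm(pfm, BackgroundModel(pseudocount=0.0))


@pytest.fixture
def permissive_params(aataaa_pwm):
    return ScanParams(la_min=0.0, ld_max=aataaa_pwm.lm)
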