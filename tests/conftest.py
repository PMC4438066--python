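import numpy as np
import pandas as pd
import pytest

from splicescreen.quant import AseAssay
from splicescreen.screen import PsiMatrix
from splicescreen.synth import SimConfig


@pytest.fixture
def assay() -> AseAssay:
    return AseAssay(
        ase_id="ASE1", gene="GENE1", species="mouse", event_type="cassette",
        size_short_nt=200, size_long_nt=300,
    )


@pytest.fixture
def zero_noise_config() -> SimConfig:
    return SimConfig(n_ases=100, psi_noise_sd=0.0, spurious_peak_rate=0.0, seed=7)


@pytest.fixture
def small_matrix() -> PsiMatrix:
    values = pd.DataFrame(
        {
            "brain": [90.0, 50.0, 10.0, np.nan],
            "kidney": [20.0, 50.0, 80.0, 30.0],
            "liver": [30.0, 50.0, 75.0, 40.0],
        },
        index=["a", "b", "c", "d"],
    )
    return PsiMatrix(values)
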