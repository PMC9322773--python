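import numpy as np
import pytest

from multilstm.data_io import ExpressionMatrix
from multilstm.synthetic import (
    ExpressionPanelSpec,
    ToneMixtureSpec,
    ToneSpec,
    make_expression_panel,
    make_tone_mixture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix():
    """2 genes x 3 time points with easily traced values."""
    return ExpressionMatrix(
        ["g1", "g2"], ["t1", "t2", "t3"],
        np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]]),
    )


@pytest.fixture(scope="session")
def two_tone():
    """The canonical two-tone validation signal: 5 Hz + 0.5 Hz over 2 s."""
    spec = ToneMixtureSpec([ToneSpec(5.0), ToneSpec(0.5)], duration=2.0,
                           n_samples=1000, noise_sd=0.0, seed=0)
    t, x, comps = make_tone_mixture(spec)
    return t, x, comps


@pytest.fixture(scope="session")
def small_panel():
    """Small degradation panel for fast pipeline tests."""
    spec = ExpressionPanelSpec(n_genes=12, seed=7)
    return make_expression_panel(spec)
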