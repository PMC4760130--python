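import numpy as np
import pytest
from hypothesis import settings

from roma.containers import ExpressionMatrix, ModuleDefinition, ModuleGene
from roma.simulate import generate, single_factor_spec

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20160218)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, no missing values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [0.5, -0.5, 1.5, -1.5],
            [2.0, 2.0, 2.0, 2.0],
        ]
    )
    return ExpressionMatrix(values, ["G1", "G2", "G3"], ["S1", "S2", "S3", "S4"])


@pytest.fixture
def signed_module():
    return ModuleDefinition(
        "E2F",
        "cell-cycle module",
        [
            ModuleGene("E2F1", 1.0, sign_defined=True),
            ModuleGene("RB1", -1.0, sign_defined=True),
            ModuleGene("CCNE1"),
        ],
    )


@pytest.fixture
def planted_dataset():
    """300 background genes + one planted 30-gene single-factor module."""
    spec = single_factor_spec("M1", 30, 20, snr=2.0, rng=11)
    X, truth, modules = generate(
        300, 20, [spec], seed=11, n_control_modules=2, control_size=30
    )
    return X, truth, modules
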