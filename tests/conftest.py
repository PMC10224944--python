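import numpy as np
import pytest

from isodenit.grid import GridSpec
from isodenit.isotope import IsotopeParams
from isodenit import synthetic


@pytest.fixture(scope="session")
def spec10() -> GridSpec:
    """Coarse 10-degree global grid: fast, still latitudinally resolved."""
    return GridSpec(resolution=10.0)


@pytest.fixture(scope="session")
def spec1cell() -> GridSpec:
    """Single-cell grid for scalar worked examples."""
    return GridSpec(lat_min=0, lat_max=2, lon_min=0, lon_max=2, resolution=2.0)


@pytest.fixture(scope="session")
def world10(spec10):
    """(truth, input_sets, params) synthetic world on the coarse grid."""
    return synthetic.make_synthetic_world(spec10, seed=7)


@pytest.fixture(scope="session")
def predictors10(spec10):
    return synthetic.make_predictor_stack(spec10, seed=7)


@pytest.fixture(scope="session")
def feature_table():
    """Synthetic cell table: nonlinear d15N truth from the 16 predictors + noise."""
    from isodenit.upscaling import PREDICTORS
    import pandas as pd

    rng = np.random.default_rng(11)
    n = 600
    df = pd.DataFrame({p: rng.uniform(0, 1, n) for p in PREDICTORS})
    df["T"] = rng.uniform(-15, 28, n)
    df["P"] = rng.uniform(100, 3000, n)
    signal = (
        0.15 * df["T"]
        - 0.001 * df["P"]
        + 3.0 * np.sin(3.0 * df["Nfix"])
        + 2.0 * df["ECM"] ** 2
        + 0.8 * df["T"].to_numpy() * df["Nfix"].to_numpy() / 10.0
    )
    df["delta15n"] = signal + rng.normal(0, 0.8, n)
    return df


@pytest.fixture
def params() -> IsotopeParams:
    return IsotopeParams()
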