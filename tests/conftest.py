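import numpy as np
import pytest

from hemoscat import (
    SkinParameters,
    TrainingGrid,
    TransportConfig,
    build_skin_model,
    default_library,
    train_model,
)


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture(scope="session")
def default_skin_stack(lib):
    """Two-layer skin model at grid-center parameters."""
    p = SkinParameters(cm=5.0, cth=0.6, a=6.3e9, b=3.0)
    return build_skin_model(p, lib)


@pytest.fixture
def fast_cfg():
    """Small photon budget for shape/contract tests."""
    return TransportConfig(n_photons=2000, rng_seed=42)


@pytest.fixture(scope="session")
def default_training(lib):
    """Regression model + records from the full default 1250-point grid.

    Shared by the estimator, synthetic-data and acceptance tests; the
    photon budget keeps the whole-suite training cost at a few minutes
    while giving per-band absorbance noise well below the model's
    intrinsic residuals (the fit is bias-limited above ~2e4 photons).
    """
    return train_model(
        TrainingGrid(), TransportConfig(n_photons=25_000, rng_seed=1234), lib
    )


@pytest.fixture(scope="session")
def default_model(default_training):
    return default_training[0]


@pytest.fixture(scope="session")
def small_model(lib):
    """Quickly trained model on a reduced grid, for plumbing tests."""
    from hemoscat import build_training_grid

    grid = build_training_grid(
        a_values=[5.8e9, 6.8e9],
        b_values=[2.95, 3.05],
        cm_values=[2.0, 8.0],
        cth_values=[0.3, 0.9],
    )
    model, _ = train_model(grid, TransportConfig(n_photons=5_000, rng_seed=7), lib)
    return model
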