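import numpy as np
import pytest

from dormancy import (
    Model1Params,
    Model2Params,
    Model3Params,
    ZerothParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def reference_params():
    """One moderate parameter setting per model, shared across tests."""
    return {
        "zeroth": ZerothParams(N_bar=1.0, kappa=0.15),
        "model1": Model1Params(N_bar=1.5, kappa=0.2, lam=0.1, mu=0.3, p_M=0.6),
        "model2": Model2Params(Ns_bar=1.2, NV_bar=0.4, kappa_s=0.5, kappa_V=0.3),
        "model3": Model3Params(N_bar=1.1, a=0.1, b=0.02),
    }


def random_params(model: str, rng: np.random.Generator):
    """Random moderate parameter draw for property tests."""
    if model == "zeroth":
        return ZerothParams(N_bar=rng.uniform(0.1, 5), kappa=rng.uniform(0.01, 1))
    if model == "model1":
        return Model1Params(
            N_bar=rng.uniform(0.1, 5),
            kappa=rng.uniform(0.01, 1),
            lam=rng.uniform(0, 1),
            mu=rng.uniform(0, 1),
            p_M=rng.uniform(0, 1),
        )
    if model == "model2":
        return Model2Params(
            Ns_bar=rng.uniform(0.1, 5),
            NV_bar=rng.uniform(0, 5),
            kappa_s=rng.uniform(0.01, 1),
            kappa_V=rng.uniform(0.01, 1),
        )
    if model == "model3":
        return Model3Params(
            N_bar=rng.uniform(0.1, 5), a=rng.uniform(0.01, 1), b=rng.uniform(0, 0.3)
        )
    raise ValueError(model)
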