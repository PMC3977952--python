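import numpy as np
import pytest

from countseg.losses import LossModel
from countseg.simulate import nb_rvs


def random_series(family: str, n: int, seed: int, phi: float = 0.5) -> np.ndarray:
    """A random test series appropriate for the given loss family."""
    rng = np.random.default_rng(seed)
    if family == "nbinom":
        half = n // 2
        a = nb_rvs(0.7, phi, half, rng)
        b = nb_rvs(0.25, phi, n - half, rng)
        return np.concatenate((a, b)).astype(np.float64)
    if family == "poisson":
        half = n // 2
        return np.concatenate(
            (rng.poisson(1.0, half), rng.poisson(6.0, n - half))
        ).astype(np.float64)
    return np.concatenate(
        (rng.normal(0.0, 1.0, n // 2), rng.normal(2.0, 1.0, n - n // 2))
    )


@pytest.fixture(params=["nbinom", "poisson", "gaussian"])
def family(request):
    return request.param


@pytest.fixture
def loss_model(family):
    return LossModel(family, 0.5 if family == "nbinom" else 1.0)
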