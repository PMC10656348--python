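import numpy as np
import pytest

from irtpower import ItemParametrization, LatentDistribution, MarginalModel


@pytest.fixture(scope="session")
def beta_2pl_5() -> np.ndarray:
    """A 5-item 2PL alternative with moderate slope spread."""
    beta = np.empty(10)
    beta[0::2] = [0.8, 1.1, 1.25, 0.9, 1.43]
    beta[1::2] = [0.5, -0.3, 0.1, 0.9, -0.7]
    return beta


@pytest.fixture(scope="session")
def model_2pl_5(beta_2pl_5) -> MarginalModel:
    return MarginalModel(ItemParametrization("two_pl", 5), beta_2pl_5)


@pytest.fixture(scope="session")
def latent_default() -> LatentDistribution:
    return LatentDistribution.standard_normal()
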