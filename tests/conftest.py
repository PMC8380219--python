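import numpy as np
import pytest

from radpipe.features import extract_all
from radpipe.synthetic import DEFAULT_PHANTOM, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """PET/CT/mask/truth for the default phantom (seeded)."""
    return generate_phantom(DEFAULT_PHANTOM)


@pytest.fixture(scope="session")
def default_features(default_phantom):
    """The 1404-feature vector of the default phantom."""
    pet, ct, mask, _ = default_phantom
    res = extract_all(pet, ct, mask)
    assert not res.excluded
    return res.features


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
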