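import numpy as np
import pytest

from gliomaseg import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 48-cubed phantom case (volume, mask)."""
    cfg = PhantomConfig(shape=(48, 48, 48), edema_radius_range=(8.0, 12.0), seed=0)
    return generate_phantom(cfg, 0)


@pytest.fixture(scope="session")
def phantom_dataset_dir(tmp_path_factory):
    """Four tiny phantom cases written in BraTS case layout."""
    from gliomaseg import generate_dataset

    cfg = PhantomConfig(
        shape=(32, 32, 32), n_cases=4, edema_radius_range=(5.0, 7.0), seed=3
    )
    out = tmp_path_factory.mktemp("phantoms")
    generate_dataset(cfg, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
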