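import numpy as np
import pytest

from mitomir.synthetic import ArrayDesign


@pytest.fixture(scope="session")
def default_design() -> ArrayDesign:
    return ArrayDesign.default()


@pytest.fixture
def small_design() -> ArrayDesign:
    """A 20-probe design (4 calibrators), quadruplicate spots."""
    probes = tuple(f"p{i:02d}" for i in range(1, 17)) + tuple(
        f"cal{i}" for i in range(1, 5)
    )
    return ArrayDesign(
        probe_ids=probes,
        calibrator_ids=frozenset(f"cal{i}" for i in range(1, 5)),
        n_replicate_spots=4,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
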