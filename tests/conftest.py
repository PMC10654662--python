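import numpy as np
import pytest

from histoharm import PatchRecord, generate_feature_table


@pytest.fixture
def constant_patch() -> PatchRecord:
    """50x50 patch with every channel fixed at 128."""
    return PatchRecord(np.full((50, 50, 3), 128, dtype=np.uint8), "const")


@pytest.fixture
def random_patch() -> PatchRecord:
    rng = np.random.default_rng(7)
    return PatchRecord(
        rng.integers(0, 256, size=(50, 50, 3)).astype(np.uint8), "rand7"
    )


@pytest.fixture
def stripe_patch() -> PatchRecord:
    """Vertical stripes alternating 0/255 (all horizontal pairs differ)."""
    img = np.zeros((50, 50, 3), dtype=np.uint8)
    img[:, 1::2, :] = 255
    return PatchRecord(img, "stripes")


@pytest.fixture(scope="session")
def combat_sim():
    """The two-batch generative table with known gamma/delta truth."""
    return generate_feature_table(
        n_per_batch=(200, 200),
        p=100,
        gamma_params=((0.0, 0.0), (1.5, 0.3)),
        delta_params=(1.0, 2.0),
        seed=11,
    )
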