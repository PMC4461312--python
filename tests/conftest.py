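import numpy as np
import pytest

from commsize import CommunityMatrix


@pytest.fixture
def small_matrix() -> CommunityMatrix:
    """5 samples x 6 taxa with a clear compositional gradient."""
    counts = np.array(
        [
            [40, 20, 5, 0, 0, 0],
            [20, 30, 15, 5, 0, 0],
            [5, 20, 30, 20, 5, 0],
            [0, 5, 15, 30, 20, 5],
            [0, 0, 5, 20, 30, 40],
        ]
    )
    return CommunityMatrix(
        counts=counts,
        sample_ids=tuple(f"s{i}" for i in range(1, 6)),
        taxon_ids=tuple(f"t{j}" for j in range(1, 7)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
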