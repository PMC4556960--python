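import numpy as np
import pytest

from fcdpipe.images import BoldImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_bold(rng):
    """Small 4D volume of independent noise on a 3 mm grid."""

    def make(shape=(6, 6, 6), t=50, tr_s=2.0, mask=None):
        data = rng.standard_normal(shape + (t,))
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        return BoldImage(data=data, voxel_size_mm=(3.0, 3.0, 3.0), tr_s=tr_s,
                         brain_mask=mask)

    return make
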