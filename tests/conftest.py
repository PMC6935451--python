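import dataclasses

import numpy as np
import pytest

from thermoseg import synthetic


@pytest.fixture(scope="session")
def normal_phantom():
    """A noiseless-ish default phantom without hot spot."""
    return synthetic.render_phantom(synthetic.PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def abnormal_phantom():
    spec = dataclasses.replace(
        synthetic.PhantomSpec(seed=12),
        hot_spot=synthetic.HotSpot(present=True, side="left",
                                   offset=(4.0, -6.0)),
    )
    return synthetic.render_phantom(spec)


@pytest.fixture(scope="session")
def two_disk_mask():
    """Binary mask with one filled disk per image half."""
    from skimage import draw

    mask = np.zeros((60, 120), dtype=bool)
    rr, cc = draw.disk((30, 30), 15)
    mask[rr, cc] = True
    rr, cc = draw.disk((30, 90), 15)
    mask[rr, cc] = True
    return mask
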