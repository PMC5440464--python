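import numpy as np
import pytest

from enharch import BackgroundModel


@pytest.fixture
def uniform_bg():
    return BackgroundModel.uniform(N=175.5e6)


@pytest.fixture
def skewed_bg():
    # AT-rich composition, loosely intergenic-like
    return BackgroundModel(q=np.array([0.3, 0.2, 0.2, 0.3]), N=175.5e6)
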