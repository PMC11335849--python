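import numpy as np
import pytest

import acoforms as af


@pytest.fixture(scope="session")
def small_bank():
    """4 domains x 6 items, realistic discriminations, no DIF."""
    return af.generate_item_bank(4, 6, seed=5)


@pytest.fixture(scope="session")
def small_data(small_bank):
    return af.simulate_responses(small_bank, (300, 300), seed=11)


@pytest.fixture(scope="session")
def grid():
    return af.default_grid()


@pytest.fixture(scope="session")
def fitted_form(small_data, grid):
    items = small_data.item_ids[:6]
    sub = small_data.subset(items)
    return af.fit_2pl(sub, grid, item_ids=items)


def rng(seed=0):
    return np.random.default_rng(seed)
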