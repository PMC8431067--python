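import numpy as np
import pytest

from hequity import generate_dataset, get_scenario, prepare


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210831)


@pytest.fixture(scope="session")
def share_like_prepared():
    """A small two-country share-like extract with derived columns."""
    cfg = get_scenario("share_like", n_per_group=1500, groups=("A", "B"), seed=11)
    return prepare(generate_dataset(cfg))


@pytest.fixture(scope="session")
def single_group_prepared(share_like_prepared):
    return share_like_prepared[share_like_prepared["group"] == "A"].reset_index(drop=True)
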