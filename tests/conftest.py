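import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture
def tiny_tree_3():
    import dendropy

    tree = dendropy.Tree.get(data="((A,B),C);", schema="newick")
    tree.is_rooted = True
    return tree


@pytest.fixture
def tiny_tree_4():
    import dendropy

    tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
    tree.is_rooted = True
    return tree
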