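import dendropy
import numpy as np
import pytest

from convar import generate_fixture_suite, toy_partition_8, toy_tree_8


@pytest.fixture
def tree8():
    return toy_tree_8()


@pytest.fixture
def part8():
    return toy_partition_8()


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("suite")
    return generate_fixture_suite(out, seed=0)


def random_binary_tree(labels, rng, min_bl=0.05, max_bl=0.5):
    """Random rooted binary tree over the given leaf labels."""

    def newick(labs):
        if len(labs) == 1:
            return labs[0]
        split = int(rng.integers(1, len(labs)))
        left, right = labs[:split], labs[split:]
        return f"({newick(left)}:{_bl()},{newick(right)}:{_bl()})"

    def _bl():
        return f"{rng.uniform(min_bl, max_bl):.4f}"

    labels = list(labels)
    rng.shuffle(labels)
    tree = dendropy.Tree.get(
        data=newick(labels) + ";", schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
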