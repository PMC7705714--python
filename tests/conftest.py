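import numpy as np
import pytest
from hypothesis import settings

from phyloaudit.model import GTRModel
from phyloaudit.tree import Node, Tree

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def jc1() -> GTRModel:
    """Jukes-Cantor without rate variation (closed forms apply)."""
    return GTRModel(n_categories=1)


@pytest.fixture(scope="session")
def gtr_gamma() -> GTRModel:
    """The campaign model: equal rates/frequencies, Gamma(1) with 4 categories."""
    return GTRModel()


@pytest.fixture(scope="session")
def gtr_uneven() -> GTRModel:
    """A deliberately asymmetric GTR model for oracle checks."""
    return GTRModel(
        exchangeabilities=(1.3, 2.5, 0.8, 1.1, 3.2, 1.0),
        freqs=(0.3, 0.2, 0.25, 0.25),
    )


def random_binary_tree(rng, n, *, with_supports=False, length_range=(0.01, 0.5)):
    """Random unrooted-normal-form binary topology with random lengths."""
    labels = [f"t{i}" for i in range(1, n + 1)]
    perm = rng.permutation(n)
    order = [labels[i] for i in perm]
    root = Node()
    for lab in order[:3]:
        root.add_child(Node(label=lab))
    tree = Tree(root)
    for lab in order[3:]:
        edges = [nd for nd in tree.postorder() if nd is not tree.root]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        joint = Node()
        parent.children[parent.children.index(target)] = joint
        joint.parent = parent
        joint.add_child(target)
        joint.add_child(Node(label=lab))
    for node in tree.postorder():
        if node.parent is not None:
            node.length = float(rng.uniform(*length_range))
            if with_supports and not node.is_leaf:
                node.support = int(rng.integers(0, 101))
    if with_supports:
        tree.support_scale = "percent"
    return tree


@pytest.fixture
def make_random_tree():
    return random_binary_tree
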