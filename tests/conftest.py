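import numpy as np
import pytest

import phylopls as pp

WORKED_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def worked_tree():
    """Three-taxon tree with known C, mean, and contrasts."""
    return pp.read_newick(WORKED_NEWICK)


@pytest.fixture
def worked_traits():
    return pp.TraitMatrix(
        values=np.array([[1.0], [3.0], [8.0]]),
        row_labels=("A", "B", "C"),
        col_labels=("x",),
    )


def star_tree(n, length=1.0):
    return pp.read_newick(
        "(" + ",".join(f"s{i:02d}:{length}" for i in range(n)) + ");"
    )


@pytest.fixture
def star8():
    return star_tree(8)


def random_traits(tree, p=6, b=0.0, seed=0):
    return pp.simulate_bm(tree, pp.build_input_cov(p, b), seed=seed)


@pytest.fixture
def blocks6():
    return pp.BlockSpec.halves(6)
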