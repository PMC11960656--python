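import numpy as np
import pytest

from phylocure.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_synth():
    """30-species synthetic dataset with its tree ensemble and truth."""
    return generate_dataset(SimConfig(n_species=30), seed=11)


@pytest.fixture(scope="session")
def tiny_tree():
    """The 3-tip ultrametric tree ((A:1,B:1):1,C:2)."""
    import dendropy

    tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
    tree.is_rooted = True
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = leaf.taxon.label.capitalize()
    return tree


def random_ultrametric_tree(n_tips, seed):
    from phylocure.phylo import simulate_yule_tree

    return simulate_yule_tree(n_tips, seed)
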