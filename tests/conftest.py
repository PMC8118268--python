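import numpy as np
import pytest

import pbdelim as pb


@pytest.fixture
def cherry():
    """Two-leaf tree with pendant durations 5 and 5."""
    return pb.LineageTree.from_newick("(A:5,B:5);")


@pytest.fixture
def balanced4():
    """Balanced four-leaf tree, all durations 1."""
    return pb.LineageTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar5():
    return pb.LineageTree.from_newick(
        "((((A:1,B:1):1,C:2):1,D:3):1,E:4);"
    )


def random_lineage_tree(rng, n_leaves):
    """Random topology with random durations (not ultrametric), labels T0.."""
    labels = [f"T{i}" for i in range(n_leaves)]
    nodes = [f"{label}:{rng.uniform(0.2, 3.0):.6f}" for label in labels]
    while len(nodes) > 2:
        k = 2 if rng.random() < 0.8 else min(3, len(nodes))
        picked = [nodes.pop(rng.integers(len(nodes))) for _ in range(k)]
        nodes.append(f"({','.join(picked)}):{rng.uniform(0.2, 3.0):.6f}")
    newick = f"({','.join(nodes)});"
    return pb.LineageTree.from_newick(newick)


def random_partition(rng, labels):
    """Uniform-ish random set partition via random block assignment."""
    labels = list(labels)
    assign = {}
    next_block = 0
    for label in labels:
        b = rng.integers(next_block + 1)
        assign[label] = b
        if b == next_block:
            next_block += 1
    blocks = {}
    for label, b in assign.items():
        blocks.setdefault(b, []).append(label)
    return pb.SpeciesPartition(blocks.values())


def steiner_subtrees_overlap(tree, partition):
    """Independent graph oracle: do the partition blocks' minimal connecting
    subtrees share a vertex?  (Uses shortest paths on the tree graph.)"""
    import itertools

    import networkx as nx

    g = nx.Graph()
    for node in tree.branches:
        g.add_edge(id(node.parent_node), id(node))
    leaf_of = {
        node.taxon.label: id(node)
        for node in tree.postorder_nodes()
        if node.is_leaf()
    }
    used = set()
    for block in partition.blocks:
        vertices = set()
        members = list(block)
        for a, b in itertools.combinations(members, 2):
            vertices.update(nx.shortest_path(g, leaf_of[a], leaf_of[b]))
        if not vertices:
            vertices = {leaf_of[members[0]]}
        if vertices & used:
            return True
        used |= vertices
    return False


def pendant_branch_index(tree, label):
    for i, node in enumerate(tree.branches):
        if node.is_leaf() and node.taxon.label == label:
            return i
    raise KeyError(label)
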