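import numpy as np
import pandas as pd
import pytest

from pterodiv import Node, OccurrenceTable, TreeDocument


def random_topology(names, rng, with_lengths=False):
    """Random rooted binary topology over the given leaf names."""
    root = Node(children=[Node(name=names[0]), Node(name=names[1])])
    for name in names[2:]:
        edges = [(n, c) for n in root.preorder() for c in n.children]
        parent, child = edges[rng.integers(len(edges))]
        mid = Node(children=[child, Node(name=name)])
        parent.children[parent.children.index(child)] = mid
    if with_lengths:
        for node in root.preorder():
            for child in node.children:
                child.length = float(np.round(rng.uniform(0.1, 9.9), 3))
    return TreeDocument(root)


def splits(tree: TreeDocument) -> frozenset:
    """Unrooted bipartition set — topology comparison key."""
    leaves = frozenset(tree.leaf_names())
    n = len(leaves)
    out = set()

    def down(node):
        if node.is_leaf:
            return frozenset([node.name])
        got = frozenset().union(*(down(c) for c in node.children))
        if 2 <= len(got) <= n - 2:
            out.add(min((got, leaves - got), key=lambda s: tuple(sorted(s))))
        return got

    down(tree.root)
    return frozenset(out)


def make_occurrences(rows) -> OccurrenceTable:
    """rows: list of (taxon, fad, lad) or (taxon, fad, lad, override)."""
    recs = {}
    for row in rows:
        taxon, fad, lad = row[:3]
        recs[taxon] = {"fad": fad, "lad": lad,
                       "override_fad": row[3] if len(row) > 3 else np.nan}
    df = pd.DataFrame(recs).T
    df.index.name = "taxon"
    return OccurrenceTable(df)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
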