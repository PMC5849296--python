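"""Time-calibration of a cladogram against stratigraphic ranges.

The calibration is the minimal ("basic") scaling used throughout vertebrate
palaeontology: each leaf is pinned at its first appearance datum (fad, Ma),
and each internal node at the age of its oldest child plus ``min_branch``,
applied post-order.  With ``min_branch = 0`` node ages are the minimum
divergence dates compatible with the fossil record; a positive value
(commonly 1 Ma for plotting) pushes every divergence that much earlier than
its oldest child.  Any gap between a lineage's divergence and its first
observation is a ghost lineage.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import Node, OccurrenceTable, TreeDocument

__all__ = ["TimeTree", "calibrate_tree", "ghost_lineages"]


@dataclass
class TimeTree:
    """A calibrated tree: every node carries an age (Ma), and each leaf its
    observed range.  Edges decompose into a ghost segment (divergence age
    down to the first observation) and, for leaves, the observed range."""

    tree: TreeDocument
    occurrences: OccurrenceTable
    min_branch: float

    def leaf_range(self, taxon: str) -> tuple[float, float]:
        return self.occurrences.fad(taxon), self.occurrences.lad(taxon)

    def lineage_extents(self) -> pd.DataFrame:
        """Total temporal extent of every non-root edge's lineage.

        For a leaf edge this runs from the divergence that created it down
        to the taxon's last appearance (ghost portion plus observed range);
        for an internal edge, from the parent's to the child's age.
        """
        rows = []
        parents = self.tree.parents()
        for node in self.tree.root.preorder():
            if id(node) not in parents:
                continue  # root subtends no edge
            parent = parents[id(node)]
            if node.is_leaf:
                rows.append((node.name, True, parent.age,
                             self.occurrences.lad(node.name)))
            else:
                rows.append((_clade_label(node), False, parent.age, node.age))
        return pd.DataFrame(rows, columns=["lineage", "is_leaf", "start", "end"])


def _clade_label(node: Node) -> str:
    leaves = sorted(n.name for n in node.postorder() if n.is_leaf)
    return "clade(" + "+".join(leaves) + ")"


def calibrate_tree(tree: TreeDocument, occ: OccurrenceTable,
                   min_branch: float = 0.0) -> TimeTree:
    """Assign node ages: leaf age = effective fad; internal node age =
    max over children of (child age + ``min_branch``).

    Polytomies are calibrated as-is.  Raises on a leaf without an
    occurrence record or a negative ``min_branch``.
    """
    if min_branch < 0:
        raise ValueError("min_branch must be non-negative")
    missing = [n for n in tree.leaf_names() if n not in occ.table.index]
    if missing:
        raise ValueError(f"leaves without occurrence records: {sorted(missing)}")

    calibrated = tree.copy()
    for node in calibrated.root.postorder():
        if node.is_leaf:
            node.age = occ.fad(node.name)
        else:
            node.age = max(c.age + min_branch for c in node.children)
    for node in calibrated.root.preorder():
        for child in node.children:
            child.length = node.age - child.age
    return TimeTree(calibrated, occ, min_branch)


def ghost_lineages(tt: TimeTree) -> pd.DataFrame:
    """Tabulate ghost segments: one row per edge whose subtending divergence
    predates the earliest observation on that edge (the fad for a leaf;
    internal edges are never directly observed, so any positive-length
    internal edge is entirely ghost).  Zero-length segments are omitted.

    Columns: ``lineage, start, end, length`` with start/end in Ma
    (start older).
    """
    rows = []
    parents = tt.tree.parents()
    for node in tt.tree.root.preorder():
        if id(node) not in parents:
            continue
        parent = parents[id(node)]
        if node.is_leaf:
            start, end = parent.age, tt.occurrences.fad(node.name)
            label = node.name
        else:
            start, end = parent.age, node.age
            label = _clade_label(node)
        if start - end > 1e-12:
            rows.append((label, start, end, start - end))
    return pd.DataFrame(rows, columns=["lineage", "start", "end", "length"])
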