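"""Maximum-parsimony scoring and a basic heuristic search for mixed
discrete and continuous character matrices.

Tree length is computed character by character with exact dynamic
programming over a candidate state set (the Sankoff recursion), which
handles polytomies, polymorphic cells and missing data uniformly:

* unordered characters use a 0/1 step cost between the observed states;
* ordered characters use |a - b| over the observed integer states;
* continuous characters (first rescaled to unit range, the convention of
  rescaling each character's observed values to [0, 1]) use |a - b| over
  the grid of observed values — exact, because with absolute-difference
  costs an optimal assignment always exists with internal nodes taking
  observed leaf values (the objective is piecewise linear in each internal
  value with breakpoints only at leaf values).

Missing and inapplicable cells constrain nothing; polymorphic cells may be
satisfied by any of their states.  Length is invariant to re-rooting, so a
rooted representation is used internally.

The consistency index CI = sum(m_i) / sum(s_i) compares observed steps to
the minimum conceivable on any tree; the retention index
RI = (sum(g_i) - sum(s_i)) / (sum(g_i) - sum(m_i)) measures retained
synapomorphy against the star-tree maximum g_i.

The heuristic search is deliberately modest: random-addition starting
trees, subtree pruning and regrafting (SPR) to a local optimum, an
optional parsimony-ratchet perturbation cycle, zero-length branches
collapsed in the reported trees, and all equally best topologies retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CharacterMatrix, CharacterSpec, Node, TreeDocument

__all__ = ["TreeScore", "rescale_continuous", "tree_length", "ci_ri",
           "min_steps", "max_steps", "heuristic_search", "exhaustive_search",
           "collapse_zero_length_branches"]

_INF = float("inf")


@dataclass
class TreeScore:
    """Per-character observed (s), minimum (m) and star-tree maximum (g)
    steps, plus weights; length L = sum(w * s)."""

    steps: np.ndarray
    min_steps: np.ndarray
    max_steps: np.ndarray
    weights: np.ndarray

    @property
    def length(self) -> float:
        return float(np.dot(self.weights, self.steps))

    @property
    def ci(self) -> float:
        return ci_ri(self)[0]

    @property
    def ri(self) -> float:
        return ci_ri(self)[1]


# ---------------------------------------------------------------------------
# character preparation
# ---------------------------------------------------------------------------

def rescale_continuous(matrix: CharacterMatrix) -> CharacterMatrix:
    """Map each continuous character to (x - min) / (max - min) over its
    observed values (missing cells ignored).  A zero-range character is
    dropped with a warning.  Raises if the matrix has no continuous
    characters."""
    import warnings

    cont = [j for j, c in enumerate(matrix.characters) if c.kind == "continuous"]
    if not cont:
        raise ValueError("matrix has no continuous characters")
    out = matrix.copy()
    drop = []
    for j in cont:
        vals = [v for v in out.column(j) if v is not None]
        lo, hi = min(vals), max(vals)
        if hi == lo:
            warnings.warn(f"continuous character {j} has zero range; dropped")
            drop.append(j)
            continue
        for i in range(out.n_taxa):
            if out.cells[i][j] is not None:
                out.cells[i][j] = (out.cells[i][j] - lo) / (hi - lo)
    if drop:
        keep = [j for j in range(out.n_characters) if j not in drop]
        out = CharacterMatrix(
            out.taxa, [out.characters[j] for j in keep],
            [[row[j] for j in keep] for row in out.cells],
            {(i, keep.index(j)) for (i, j) in out.inapplicable if j in keep})
    out.continuous_rescaled = True
    return out


def _character_column(matrix: CharacterMatrix, j: int):
    """(candidate states, cost matrix, per-taxon allowed-state cost rows).

    Candidates are the distinct observed states/values; a leaf's cost row
    is 0 for states its cell allows (any state when missing) and +inf
    otherwise, except that observed cells not matching any candidate can
    never occur (candidates are built from the cells).
    """
    spec = matrix.characters[j]
    col = matrix.column(j)
    if spec.kind == "unordered":
        universe = sorted({s for cell in col if cell is not None for s in cell})
        if len(universe) <= 1:
            return None  # invariant character: zero steps on any tree
        k = len(universe)
        cost = 1.0 - np.eye(k)
        index = {s: a for a, s in enumerate(universe)}
        leaf_costs = []
        for cell in col:
            if cell is None:
                leaf_costs.append(np.zeros(k))
            else:
                row = np.full(k, _INF)
                for s in cell:
                    row[index[s]] = 0.0
                leaf_costs.append(row)
        return np.array(universe, float), cost, leaf_costs

    # ordered / continuous: intervals with |a - b| costs
    intervals = _interval_column(matrix, j)
    points = sorted({p for iv in intervals if iv is not None for p in iv})
    if len(points) <= 1:
        return None
    pts = np.array(points, float)
    cost = np.abs(pts[:, None] - pts[None, :])
    leaf_costs = []
    for iv in intervals:
        if iv is None:
            leaf_costs.append(np.zeros(len(pts)))
        else:
            lo, hi = iv
            row = np.where((pts >= lo - 1e-12) & (pts <= hi + 1e-12), 0.0, _INF)
            leaf_costs.append(row)
    return pts, cost, leaf_costs


def _interval_column(matrix: CharacterMatrix, j: int):
    """Each cell as an allowed interval (lo, hi) or None for missing."""
    spec = matrix.characters[j]
    out = []
    for cell in matrix.column(j):
        if cell is None:
            out.append(None)
        elif spec.kind == "continuous":
            out.append((float(cell), float(cell)))
        else:  # ordered: polymorphism spans its extreme states
            out.append((float(min(cell)), float(max(cell))))
    return out


# ---------------------------------------------------------------------------
# length on a fixed tree
# ---------------------------------------------------------------------------

def _sankoff_steps(tree: TreeDocument, leaf_costs: dict[str, np.ndarray],
                   cost: np.ndarray) -> float:
    """Exact minimum steps for one character on a (possibly multifurcating)
    rooted tree.  ``leaf_costs[name]`` is the 0/inf admissibility row."""
    def down(node: Node) -> np.ndarray:
        if node.is_leaf:
            return leaf_costs[node.name]
        total = np.zeros(cost.shape[0])
        for child in node.children:
            c = down(child)
            total = total + np.min(c[None, :] + cost, axis=1)
        return total

    return float(down(tree.root).min())


def tree_length(tree: TreeDocument, matrix: CharacterMatrix) -> TreeScore:
    """Score a tree: per-character exact minimum steps, with m and g
    (minimum conceivable and star-tree maximum) for CI/RI."""
    if sorted(tree.leaf_names()) != sorted(matrix.taxa):
        raise ValueError("tree and matrix taxa differ")
    if any(c.kind == "continuous" for c in matrix.characters) \
            and not matrix.continuous_rescaled:
        raise ValueError(
            "continuous characters must pass through rescale_continuous first")
    steps = np.zeros(matrix.n_characters)
    for j in range(matrix.n_characters):
        prep = _character_column(matrix, j)
        if prep is None:
            continue
        _, cost, leaf_costs = prep
        by_name = dict(zip(matrix.taxa, leaf_costs))
        steps[j] = _sankoff_steps(tree, by_name, cost)
    return TreeScore(steps, min_steps(matrix), max_steps(matrix),
                     np.array([c.weight for c in matrix.characters]))


def min_steps(matrix: CharacterMatrix) -> np.ndarray:
    """Minimum conceivable steps per character on any tree.

    Ordered/continuous: the shortest interval meeting every cell, i.e.
    max(cell minima) - min(cell maxima) when positive.  Unordered: number
    of extra states forced beyond one — singleton states must all appear;
    polymorphic cells not already covered are covered greedily (exact for
    the small state counts used here).
    """
    out = np.zeros(matrix.n_characters)
    for j, spec in enumerate(matrix.characters):
        if spec.kind == "unordered":
            cells = [c for c in matrix.column(j) if c is not None]
            if not cells:
                continue
            # smallest state set hitting every cell (exact: the state
            # universe is tiny, so enumerate covers by size)
            required = frozenset(next(iter(c)) for c in cells if len(c) == 1)
            uncovered = [c for c in cells if not (c & required)]
            optional = sorted({s for c in uncovered for s in c})
            extra = len(optional)
            for size in range(len(optional) + 1):
                found = False
                from itertools import combinations
                for combo in combinations(optional, size):
                    chosen = required | frozenset(combo)
                    if all(c & chosen for c in uncovered):
                        found = True
                        break
                if found:
                    extra = size
                    break
            out[j] = max(0, len(required) + extra - 1)
        else:
            ivs = [iv for iv in _interval_column(matrix, j) if iv is not None]
            if not ivs:
                continue
            out[j] = max(0.0, max(lo for lo, _ in ivs) - min(hi for _, hi in ivs))
    return out


def max_steps(matrix: CharacterMatrix) -> np.ndarray:
    """Steps per character on a star phylogeny: the best single central
    state (unordered) or value (ordered/continuous) against all cells."""
    out = np.zeros(matrix.n_characters)
    for j, spec in enumerate(matrix.characters):
        if spec.kind == "unordered":
            cells = [c for c in matrix.column(j) if c is not None]
            if not cells:
                continue
            universe = {s for c in cells for s in c}
            out[j] = min(sum(1 for c in cells if s not in c) for s in universe)
        else:
            ivs = [iv for iv in _interval_column(matrix, j) if iv is not None]
            if not ivs:
                continue
            candidates = sorted({p for iv in ivs for p in iv})
            out[j] = min(
                sum(max(0.0, lo - c, c - hi) for lo, hi in ivs)
                for c in candidates)
    return out


def ci_ri(score: TreeScore, informative_only: bool = False) -> tuple[float, float]:
    """Ensemble consistency and retention indices.

    CI is summed over all variable characters; RI excludes characters with
    g = m (those can retain no synapomorphy, the usual convention).  With
    ``informative_only`` both sums are restricted to characters that can
    show homoplasy (g > m).
    """
    w, s, m, g = score.weights, score.steps, score.min_steps, score.max_steps
    mask = np.ones_like(s, bool) if not informative_only else (g > m)
    if (w[mask] * s[mask]).sum() == 0:
        raise ValueError("zero total length: CI undefined")
    ci = float((w[mask] * m[mask]).sum() / (w[mask] * s[mask]).sum())
    rimask = mask & (g > m)
    denom = (w[rimask] * (g[rimask] - m[rimask])).sum()
    ri = float((w[rimask] * (g[rimask] - s[rimask])).sum() / denom) if denom else 1.0
    return ci, ri


# ---------------------------------------------------------------------------
# tree surgery for search
# ---------------------------------------------------------------------------

def _binary_tree_from_order(names: list[str]) -> Node:
    root = Node(children=[Node(name=names[0]), Node(name=names[1])])
    return root


def _attach_at_edge(root: Node, parent: Node, child: Node, leaf: Node) -> Node:
    """New node splitting edge parent->child, with ``leaf`` as sibling."""
    mid = Node(children=[child, leaf])
    parent.children[parent.children.index(child)] = mid
    return root


def _edges(root: Node) -> list[tuple[Node, Node]]:
    out = []
    for node in root.preorder():
        for child in node.children:
            out.append((node, child))
    return out


def _detach(root: Node, parent: Node, child: Node) -> None:
    """Remove child and splice out parent if it becomes degree-1."""
    parent.children.remove(child)


def _splice_unary(root: Node) -> Node:
    """Collapse unary internal nodes left by pruning."""
    def fix(node: Node) -> Node:
        node.children = [fix(c) for c in node.children]
        if len(node.children) == 1 and node.name is None:
            return node.children[0]
        return node
    return fix(root)


def _unrooted_splits(root: Node, all_leaves: frozenset[str]) -> frozenset:
    """Canonical unrooted-topology key: the set of non-trivial bipartitions."""
    n = len(all_leaves)
    splits = set()

    def down(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        got = frozenset().union(*(down(c) for c in node.children))
        if 2 <= len(got) <= n - 2:
            comp = all_leaves - got
            splits.add(min((got, comp), key=lambda s: tuple(sorted(s))))
        return got

    down(root)
    return frozenset(splits)


def _score_tree(root: Node, matrix: CharacterMatrix, prepped) -> float:
    total = 0.0
    for cost, by_name, weight in prepped:
        total += weight * _sankoff_steps(TreeDocument(root), by_name, cost)
    return total


def _prep_matrix(matrix: CharacterMatrix):
    prepped = []
    for j in range(matrix.n_characters):
        p = _character_column(matrix, j)
        if p is None:
            continue
        _, cost, leaf_costs = p
        prepped.append((cost, dict(zip(matrix.taxa, leaf_costs)),
                        matrix.characters[j].weight))
    return prepped


def _spr_neighbourhood(root: Node):
    """Yield copies of the tree with one subtree regrafted elsewhere."""
    base_edges = _edges(root)
    for prune_idx in range(len(base_edges)):
        work = root.copy()
        edges = _edges(work)
        pparent, pchild = edges[prune_idx]
        in_subtree = {id(n) for n in pchild.postorder()}
        _detach(work, pparent, pchild)
        work = _splice_unary(work)
        if work.is_leaf or len(_edges(work)) == 0:
            continue
        for rparent, rchild in _edges(work):
            if id(rchild) in in_subtree or id(rparent) in in_subtree:
                continue
            if rchild is pchild:
                continue
            candidate_root = work.copy()
            # map the regraft edge into the copy by position
            src, dst = _edges(work), _edges(candidate_root)
            pos = src.index((rparent, rchild))
            cparent, cchild = dst[pos]
            _attach_at_edge(candidate_root, cparent, cchild, pchild.copy())
            yield candidate_root
        # also regraft at the root (new root above everything)
        candidate_root = Node(children=[work.copy(), pchild.copy()])
        yield candidate_root


def _swap_to_local_optimum(root: Node, matrix: CharacterMatrix, prepped,
                           score: float) -> tuple[Node, float]:
    improved = True
    while improved:
        improved = False
        for cand in _spr_neighbourhood(root):
            s = _score_tree(cand, matrix, prepped)
            if s < score - 1e-9:
                root, score = cand, s
                improved = True
                break
    return root, score


def heuristic_search(matrix: CharacterMatrix, n_replicates: int = 10,
                     ratchet: bool = False, seed: int = 0,
                     ratchet_iters: int = 5
                     ) -> tuple[list[TreeDocument], TreeScore]:
    """Random-addition + SPR parsimony search.

    Each replicate builds a starting tree by stepwise addition in a random
    taxon order (each taxon inserted at the currently best edge), then
    swaps to an SPR local optimum; with ``ratchet`` each replicate also runs
    perturbation cycles in which a random quarter of the characters is
    upweighted threefold, the tree re-swapped, weights restored and the
    tree swapped again.  Zero-length branches are collapsed in the output
    and all distinct equally best topologies are returned with the score of
    the best tree.  Same seed, same result.
    """
    if matrix.n_taxa < 4:
        raise ValueError("heuristic search needs at least 4 taxa")
    if any(c.kind == "continuous" for c in matrix.characters) \
            and not matrix.continuous_rescaled:
        raise ValueError(
            "continuous characters must pass through rescale_continuous first")
    rng = np.random.default_rng(seed)
    prepped = _prep_matrix(matrix)
    all_leaves = frozenset(matrix.taxa)

    best_score = _INF
    best: dict[frozenset, Node] = {}

    for _ in range(n_replicates):
        order = list(matrix.taxa)
        rng.shuffle(order)
        root = _binary_tree_from_order(order)
        for name in order[2:]:
            leaf = Node(name=name)
            best_edge_score, best_tree = _INF, None
            work_edges = _edges(root)
            for k in range(len(work_edges) + 1):
                cand = root.copy()
                if k < len(work_edges):
                    src, dst = _edges(root), _edges(cand)
                    cparent, cchild = dst[k]
                    _attach_at_edge(cand, cparent, cchild, Node(name=name))
                else:
                    cand = Node(children=[cand, Node(name=name)])
                s = _score_tree(cand, matrix, prepped)
                if s < best_edge_score:
                    best_edge_score, best_tree = s, cand
            root = best_tree
        score = _score_tree(root, matrix, prepped)
        root, score = _swap_to_local_optimum(root, matrix, prepped, score)

        if ratchet:
            for _ in range(ratchet_iters):
                perturbed = matrix.copy()
                picked = rng.random(matrix.n_characters) < 0.25
                perturbed.characters = [
                    CharacterSpec(c.kind, c.weight * (3.0 if hit else 1.0))
                    for c, hit in zip(matrix.characters, picked)]
                pprep = _prep_matrix(perturbed)
                r2, _ = _swap_to_local_optimum(
                    root.copy(), perturbed, pprep,
                    _score_tree(root, perturbed, pprep))
                s2 = _score_tree(r2, matrix, prepped)
                r2, s2 = _swap_to_local_optimum(r2, matrix, prepped, s2)
                if s2 < score - 1e-9:
                    root, score = r2, s2

        if score < best_score - 1e-9:
            best_score = score
            best = {}
        if abs(score - best_score) <= 1e-9:
            best.setdefault(_unrooted_splits(root, all_leaves), root)

    trees = []
    for root in best.values():
        doc = collapse_zero_length_branches(TreeDocument(root), matrix)
        trees.append(doc)
    score = tree_length(trees[0], matrix)
    return trees, score


def collapse_zero_length_branches(tree: TreeDocument,
                                  matrix: CharacterMatrix) -> TreeDocument:
    """Collapse internal edges whose removal leaves tree length unchanged
    (edges with zero minimum length); exact because polytomies are scored
    exactly."""
    prepped = _prep_matrix(matrix)
    base = _score_tree(tree.root, matrix, prepped)
    root = tree.root.copy()
    changed = True
    while changed:
        changed = False
        for parent, child in _edges(root):
            if child.is_leaf:
                continue
            work = root.copy()
            wedges = _edges(work)
            wparent, wchild = wedges[_edges(root).index((parent, child))]
            wparent.children.remove(wchild)
            wparent.children.extend(wchild.children)
            if abs(_score_tree(work, matrix, prepped) - base) <= 1e-9:
                root = work
                changed = True
                break
    return TreeDocument(root)


def exhaustive_search(matrix: CharacterMatrix) -> tuple[list[TreeDocument], float]:
    """Score every unrooted binary topology (feasible to ~8 taxa); returns
    all optimal trees and the optimal length.  The independent yardstick
    for the heuristic search."""
    taxa = matrix.taxa
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    prepped = _prep_matrix(matrix)

    def grow(trees: list[Node], names: list[str]) -> list[Node]:
        if not names:
            return trees
        name = names[0]
        out = []
        for t in trees:
            for k, (parent, child) in enumerate(_edges(t)):
                cand = t.copy()
                cparent, cchild = _edges(cand)[k]
                _attach_at_edge(cand, cparent, cchild, Node(name=name))
                out.append(cand)
            out.append(Node(children=[t.copy(), Node(name=name)]))
        return grow(out, names[1:])

    start = _binary_tree_from_order(taxa[:2])
    all_trees = grow([start], list(taxa[2:]))
    scored = [(_score_tree(t, matrix, prepped), t) for t in all_trees]
    best = min(s for s, _ in scored)
    seen = set()
    winners = []
    all_leaves = frozenset(taxa)
    for s, t in scored:
        if abs(s - best) <= 1e-9:
            key = _unrooted_splits(t, all_leaves)
            if key not in seen:
                seen.add(key)
                winners.append(TreeDocument(t))
    return winners, best
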