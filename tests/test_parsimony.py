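import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pterodiv import (CharacterMatrix, CharacterSpec, ci_ri,
                      exhaustive_search, heuristic_search, max_steps,
                      min_steps, read_newick, rescale_continuous, tree_length)
from pterodiv.parsimony import collapse_zero_length_branches

from conftest import random_topology, splits


def discrete(taxa, columns, kinds=None):
    """Build a matrix from per-character strings, '?' = missing,
    'ab' (two chars in braces not needed here) via sets in `columns`."""
    specs = [CharacterSpec(k) for k in (kinds or ["unordered"] * len(columns))]
    cells = []
    for i, _ in enumerate(taxa):
        row = []
        for col in columns:
            c = col[i]
            if c == "?":
                row.append(None)
            elif isinstance(c, (set, frozenset)):
                row.append(frozenset(c))
            else:
                row.append(frozenset({int(c)}))
        cells.append(row)
    return CharacterMatrix(list(taxa), specs, cells)


def brute_force_length(tree, matrix):
    """Independent oracle: enumerate every assignment of states to internal
    nodes and take the cheapest.  Works for any character kind; continuous
    characters use the grid of observed values (optimal assignments exist
    on that grid for absolute-difference costs)."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    parents = tree.parents()
    total = 0.0
    for j, spec in enumerate(matrix.characters):
        col = dict(zip(matrix.taxa, matrix.column(j)))
        if spec.kind == "unordered":
            universe = sorted({s for c in col.values() if c is not None
                               for s in c})
        else:
            vals = set()
            for c in col.values():
                if c is None:
                    continue
                if isinstance(c, frozenset):
                    vals.update(float(s) for s in c)
                else:
                    vals.add(float(c))
            universe = sorted(vals)
        if len(universe) <= 1:
            continue

        def leaf_options(cell):
            if cell is None:
                return universe
            if spec.kind == "unordered":
                return sorted(cell)
            if isinstance(cell, frozenset):
                lo, hi = min(cell), max(cell)
                return [u for u in universe if lo <= u <= hi]
            return [float(cell)]

        def cost(a, b):
            if spec.kind == "unordered":
                return float(a != b)
            return abs(float(a) - float(b))

        best = np.inf
        leaves = [n for n in tree.postorder() if n.is_leaf]
        leaf_opts = [leaf_options(col[n.name]) for n in leaves]
        for internal_combo in itertools.product(universe, repeat=len(internals)):
            assign = {id(n): v for n, v in zip(internals, internal_combo)}
            fixed = 0.0
            for a in internals:
                p = parents.get(id(a))
                if p is not None:
                    fixed += cost(assign[id(a)], assign[id(p)])
            leaf_cost = 0.0
            for leaf, opts in zip(leaves, leaf_opts):
                pv = assign[id(parents[id(leaf)])]
                leaf_cost += min(cost(o, pv) for o in opts)
            best = min(best, fixed + leaf_cost)
        total += spec.weight * best
    return total


class TestRescale:
    def test_linear_map(self):
        m = CharacterMatrix(["a", "b", "c"], [CharacterSpec("continuous")],
                            [[2.0], [4.0], [6.0]])
        out = rescale_continuous(m)
        assert [r[0] for r in out.cells] == [0.0, 0.5, 1.0]
        assert out.continuous_rescaled

    def test_idempotent_on_unit_range(self):
        m = CharacterMatrix(["a", "b"], [CharacterSpec("continuous")],
                            [[0.0], [1.0]])
        assert [r[0] for r in rescale_continuous(m).cells] == [0.0, 1.0]

    def test_missing_ignored_in_range(self):
        m = CharacterMatrix(["a", "b", "c"], [CharacterSpec("continuous")],
                            [[None], [10.0], [20.0]])
        assert [r[0] for r in rescale_continuous(m).cells] == [None, 0.0, 1.0]

    def test_zero_range_character_dropped(self):
        m = CharacterMatrix(["a", "b"], [CharacterSpec("continuous"),
                                         CharacterSpec("continuous")],
                            [[5.0, 0.0], [5.0, 2.0]])
        with pytest.warns(UserWarning, match="zero range"):
            out = rescale_continuous(m)
        assert out.n_characters == 1

    def test_no_continuous_rejected(self):
        m = discrete(["a", "b"], ["01"])
        with pytest.raises(ValueError, match="no continuous"):
            rescale_continuous(m)

    def test_unrescaled_continuous_rejected_by_scoring(self):
        m = CharacterMatrix(["a", "b", "c"], [CharacterSpec("continuous")],
                            [[2.0], [4.0], [6.0]])
        with pytest.raises(ValueError, match="rescale_continuous"):
            tree_length(read_newick("((a,b),c);"), m)


class TestTreeLength:
    def test_single_derived_taxon_one_step(self):
        m = discrete(list("abcd"), ["0001"])
        for nwk in ("((a,b),(c,d));", "(((a,b),c),d);", "((a,d),(b,c));"):
            assert tree_length(read_newick(nwk), m).length == 1

    def test_matches_brute_force_on_random_discrete(self, rng):
        for n_taxa in (5, 6, 7):
            taxa = [f"t{i}" for i in range(n_taxa)]
            for _ in range(4):
                tree = random_topology(taxa, rng)
                cols = []
                kinds = []
                for _ in range(3):
                    col = []
                    for _ in taxa:
                        u = rng.random()
                        if u < 0.12:
                            col.append("?")
                        elif u < 0.22:
                            col.append(frozenset(
                                rng.choice(3, 2, replace=False).tolist()))
                        else:
                            col.append(str(rng.integers(3)))
                    cols.append(col)
                    kinds.append(str(rng.choice(["unordered", "ordered"])))
                m = discrete(taxa, cols, kinds)
                assert tree_length(tree, m).length == \
                    pytest.approx(brute_force_length(tree, m))

    def test_matches_brute_force_on_continuous(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        for _ in range(5):
            tree = random_topology(taxa, rng)
            vals = [[None if rng.random() < 0.15
                     else float(np.round(rng.random(), 3))] for _ in taxa]
            m = CharacterMatrix(taxa, [CharacterSpec("continuous")], vals)
            m.continuous_rescaled = True  # values already in [0, 1]
            assert tree_length(tree, m).length == \
                pytest.approx(brute_force_length(tree, m))

    def test_continuous_total_range_on_chain(self):
        m = CharacterMatrix(list("abc"), [CharacterSpec("continuous")],
                            [[0.0], [0.5], [1.0]])
        m.continuous_rescaled = True
        assert tree_length(read_newick("((a,b),c);"), m).length == \
            pytest.approx(1.0)

    def test_invariant_to_rerooting(self, rng):
        # the same unrooted tree, rooted three ways
        m = discrete(list("abcde"), ["00110", "01010", ["?", "1", "2",
                                                        "0", "1"]])
        lengths = {
            tree_length(read_newick(nwk), m).length
            for nwk in ("(((a,b),c),(d,e));", "((a,b),(c,(d,e)));",
                        "(a,(b,(c,(d,e))));")}
        assert len(lengths) == 1

    def test_polytomy_scored_exactly(self, rng):
        m = discrete(list("abcd"), ["0011", "0101"])
        star = read_newick("(a,b,c,d);")
        assert tree_length(star, m).length == \
            pytest.approx(brute_force_length(star, m))

    def test_taxon_mismatch_rejected(self):
        m = discrete(list("abc"), ["001"])
        with pytest.raises(ValueError, match="differ"):
            tree_length(read_newick("((a,b),d);"), m)


class TestIndices:
    def test_homoplasy_free_perfect_indices(self):
        # nested synapomorphies: no homoplasy on the true tree
        m = discrete(list("abcd"), ["0011", "0001"])
        score = tree_length(read_newick("((a,b),(c,d));"), m)
        assert ci_ri(score) == (1.0, 1.0)

    def test_two_independent_origins(self):
        # 1 appears twice on ((a,b),(c,d)) when a and c are derived:
        # m=1, s=2, g=2 -> CI 0.5, RI 0
        m = discrete(list("abcd"), ["1010"])
        score = tree_length(read_newick("((a,b),(c,d));"), m)
        assert score.steps[0] == 2
        assert score.min_steps[0] == 1 and score.max_steps[0] == 2
        ci, ri = ci_ri(score)
        assert (ci, ri) == (0.5, 0.0)

    def test_bounds_ordering(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        for _ in range(8):
            tree = random_topology(taxa, rng)
            cols = [[str(rng.integers(3)) if rng.random() > 0.1 else "?"
                     for _ in taxa] for _ in range(4)]
            m = discrete(taxa, cols,
                         [str(rng.choice(["unordered", "ordered"]))
                          for _ in range(4)])
            score = tree_length(tree, m)
            assert (score.min_steps <= score.steps + 1e-9).all()
            assert (score.steps <= score.max_steps + 1e-9).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_step_bounds_hold_on_arbitrary_matrices(self, data):
        """m <= s <= g for any mix of kinds, missing cells and
        polymorphism, on an arbitrary pectinate tree."""
        n_taxa = data.draw(st.integers(4, 6))
        taxa = [f"t{i}" for i in range(n_taxa)]
        cell = st.one_of(
            st.none(),
            st.integers(0, 3).map(lambda s: frozenset({s})),
            st.sets(st.integers(0, 3), min_size=2, max_size=3)
            .map(frozenset))
        n_chars = data.draw(st.integers(1, 3))
        specs = [CharacterSpec(data.draw(
            st.sampled_from(["unordered", "ordered"]))) for _ in range(n_chars)]
        cells = [[data.draw(cell) for _ in range(n_chars)] for _ in taxa]
        m = CharacterMatrix(taxa, specs, cells)
        nwk = taxa[0]
        for t in taxa[1:]:
            nwk = f"({nwk},{t})"
        score = tree_length(read_newick(nwk + ";"), m)
        assert (score.min_steps <= score.steps + 1e-9).all()
        assert (score.steps <= score.max_steps + 1e-9).all()

    def test_all_constant_rejected(self):
        m = discrete(list("abc"), ["000"])
        score = tree_length(read_newick("((a,b),c);"), m)
        with pytest.raises(ValueError, match="undefined"):
            ci_ri(score)


class TestSearch:
    def _random_matrix(self, rng, taxa, n_chars=8):
        cols = []
        for _ in range(n_chars):
            cols.append([str(rng.integers(2)) for _ in taxa])
        return discrete(taxa, cols)

    def test_finds_global_optimum_six_taxa(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        for seed in range(3):
            m = self._random_matrix(rng, taxa)
            _, best = exhaustive_search(m)
            _, score = heuristic_search(m, n_replicates=5, seed=seed)
            assert score.length == pytest.approx(best)

    def test_perfect_data_recovers_topology(self):
        # one clean synapomorphy per clade of a pectinate tree
        taxa = list("abcdef")
        cols = ["111110", "111100", "111000", "110000"]
        m = discrete(taxa, cols)
        trees, score = heuristic_search(m, n_replicates=5, seed=1)
        assert score.length == pytest.approx(4.0)
        truth = read_newick("(((((a,b),c),d),e),f);")
        assert any(splits(t) == splits(truth) for t in trees)
        assert ci_ri(score) == (1.0, 1.0)

    def test_same_seed_same_trees(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        m = self._random_matrix(rng, taxa)
        t1, s1 = heuristic_search(m, n_replicates=4, seed=9, ratchet=True)
        t2, s2 = heuristic_search(m, n_replicates=4, seed=9, ratchet=True)
        assert s1.length == s2.length
        assert [splits(t) for t in t1] == [splits(t) for t in t2]

    def test_too_few_taxa_rejected(self):
        m = discrete(list("abc"), ["001"])
        with pytest.raises(ValueError, match="at least 4"):
            heuristic_search(m, seed=0)

    def test_collapse_preserves_length(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        m = self._random_matrix(rng, taxa)
        tree = random_topology(taxa, rng)
        before = tree_length(tree, m).length
        collapsed = collapse_zero_length_branches(tree, m)
        assert tree_length(collapsed, m).length == pytest.approx(before)

    def test_ratchet_never_worse(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        m = self._random_matrix(rng, taxa, n_chars=12)
        _, plain = heuristic_search(m, n_replicates=3, seed=2)
        _, ratcheted = heuristic_search(m, n_replicates=3, seed=2, ratchet=True)
        assert ratcheted.length <= plain.length + 1e-9
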