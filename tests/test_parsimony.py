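import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aletrace.parsimony import (
    Node,
    RootedTree,
    branch_and_bound_search,
    exact_search,
    heuristic_search,
    min_gains,
    read_newick,
    strict_consensus,
    tree_score,
    write_newick,
)

from conftest import (
    all_rooted_binary_trees,
    brute_force_min_gains,
    make_matrix,
)


class TestMinGains:
    def test_all_zero_character(self, caterpillar5):
        assert min_gains(caterpillar5, dict.fromkeys("ABCDE", 0)) == (0, set())

    def test_single_derived_leaf_forced(self, caterpillar5):
        count, edges = min_gains(caterpillar5, {"A": 0, "B": 0, "C": 1, "D": 0, "E": 0})
        assert count == 1 and edges == {frozenset({"C"})}

    def test_two_gain_pattern(self, caterpillar5):
        count, edges = min_gains(caterpillar5, {"A": 1, "B": 1, "C": 0, "D": 1, "E": 0})
        assert count == 2
        assert edges == {frozenset({"A", "B"}), frozenset({"D"})}

    def test_missing_leaf_state_rejected(self, caterpillar5):
        with pytest.raises(ValueError, match="without a state"):
            min_gains(caterpillar5, {"A": 1})

    def test_derived_parental_rejected(self, caterpillar5):
        char = dict.fromkeys("ABCDE", 0)
        char["P"] = 1
        with pytest.raises(ValueError, match="parental"):
            min_gains(caterpillar5, char)

    def test_matches_brute_force_on_caterpillar(self, caterpillar5):
        leaves = "ABCDE"
        for bits in itertools.product([0, 1], repeat=5):
            char = dict(zip(leaves, bits))
            count, _ = min_gains(caterpillar5, char)
            assert count == brute_force_min_gains(caterpillar5, char)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_gain_count_bounds(self, data):
        n = data.draw(st.integers(2, 6))
        leaves = [f"L{i}" for i in range(n)]
        trees = list(all_rooted_binary_trees(leaves))
        tree = trees[data.draw(st.integers(0, len(trees) - 1))]
        bits = [data.draw(st.integers(0, 1)) for _ in leaves]
        char = dict(zip(leaves, bits))
        count, edges = min_gains(tree, char)
        ones = sum(bits)
        if ones == 0:
            assert count == 0
        else:
            assert 1 <= count <= ones
        assert len(edges) == count


class TestTreeScore:
    def test_zero_for_empty_matrix_columns(self, caterpillar5):
        m = make_matrix({l: [] for l in "ABCDE"})
        assert tree_score(caterpillar5, m) == 0

    def test_perfect_phylogeny_score_equals_columns(self):
        m = make_matrix(
            {"A": ["e1"], "B": ["e1", "e2"], "C": ["e1", "e2", "e3"]}
        )
        res = exact_search(m)
        assert res.best_score == m.n_events

    def test_invariant_under_permutations(self, caterpillar5):
        m = make_matrix(
            {"A": ["x", "y"], "B": ["x"], "C": ["z"], "D": ["x", "z"], "E": []}
        )
        base = tree_score(caterpillar5, m)
        shuffled = m.subset_events(list(reversed(m.event_ids)))
        assert tree_score(caterpillar5, shuffled) == base

    def test_leaf_mismatch_reported(self, caterpillar5):
        m = make_matrix({"A": ["x"], "B": []})
        with pytest.raises(ValueError, match="differ"):
            tree_score(caterpillar5, m)


class TestExactSearch:
    def test_two_strains_single_topology(self):
        m = make_matrix({"A": ["e1"], "B": ["e2"]})
        res = exact_search(m)
        assert len(res.mpt_set) == 1

    def test_nested_genotypes_unique_caterpillar(self):
        m = make_matrix({"A": ["m1"], "B": ["m1", "m2"], "C": ["m1", "m2", "m3"]})
        res = exact_search(m)
        assert res.best_score == 3
        assert len(res.mpt_set) == 1
        assert res.mpt_set[0].newick(canonical=True) == "((A,(B,C)))P;"

    def test_conflicting_characters_force_extra_gain(self):
        m = make_matrix({"A": ["c1"], "B": ["c1", "c2"], "C": ["c2"], "D": ["c3"]})
        res = exact_search(m)
        assert res.best_score == 4

    def test_too_many_strains_redirected(self):
        m = make_matrix({f"S{i}": [f"e{i}"] for i in range(9)})
        with pytest.raises(ValueError, match="branch_and_bound|heuristic"):
            exact_search(m)


class TestBranchAndBound:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exact_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 6, 8
        data = rng.integers(0, 2, size=(n, m))
        sets = {
            f"S{i}": [f"e{j}" for j in range(m) if data[i, j]] for i in range(n)
        }
        mat = make_matrix(sets)
        ex = exact_search(mat)
        bb = branch_and_bound_search(mat, collapse_duplicates=False)
        assert bb.best_score == ex.best_score
        assert bb.n_optimal == ex.n_optimal
        ex_keys = {t.newick(canonical=True) for t in ex.mpt_set}
        bb_keys = {t.newick(canonical=True) for t in bb.mpt_set}
        assert ex_keys == bb_keys

    def test_laminar_12_recovers_perfect_phylogeny(self):
        sets = {f"S{i}": [f"e{j}" for j in range(i + 1)] for i in range(12)}
        mat = make_matrix(sets)
        res = branch_and_bound_search(mat)
        assert res.best_score == mat.n_events
        assert len(res.mpt_set) == 1
        # the defining tree is the nested caterpillar S0 ⊃ S1 ⊃ ... ⊃ S11
        node = Node("S11")
        for i in range(10, -1, -1):
            node = Node(None, [Node(f"S{i}"), node])
        expected = RootedTree(Node("P", [node]), "P")
        assert (
            res.mpt_set[0].newick(canonical=True)
            == expected.newick(canonical=True)
        )

    def test_study_shaped_matrix_completes(self, study_matrix):
        m, _ = study_matrix
        res = branch_and_bound_search(m, seed=0)
        assert res.best_score == 50
        assert res.mpt_set, "expected at least one MPT"

    def test_monotone_in_columns(self):
        sets = {"A": ["e1"], "B": ["e1", "e2"], "C": ["e3"], "D": ["e2", "e3"]}
        mat = make_matrix(sets)
        full = branch_and_bound_search(mat).best_score
        for drop in mat.event_ids:
            keep = [e for e in mat.event_ids if e != drop]
            sub = mat.subset_events(keep)
            assert branch_and_bound_search(sub).best_score <= full

    def test_duplicate_strain_does_not_change_score(self):
        sets = {"A": ["e1", "e2"], "B": ["e1"], "C": ["e3"]}
        base = branch_and_bound_search(make_matrix(sets)).best_score
        sets["A2"] = ["e1", "e2"]
        dup = branch_and_bound_search(make_matrix(sets)).best_score
        assert dup == base


class TestHeuristic:
    def test_deterministic_given_seed(self):
        sets = {f"S{i}": [f"e{j}" for j in range(i % 4 + 1)] for i in range(9)}
        mat = make_matrix(sets)
        a = heuristic_search(mat, n_restarts=5, seed=42)
        b = heuristic_search(mat, n_restarts=5, seed=42)
        assert a.best_score == b.best_score
        assert [t.newick() for t in a.mpt_set] == [t.newick() for t in b.mpt_set]

    def test_reaches_perfect_score_on_laminar(self):
        sets = {f"S{i}": [f"e{j}" for j in range(i + 1)] for i in range(10)}
        mat = make_matrix(sets)
        res = heuristic_search(mat, n_restarts=5, seed=0)
        assert res.best_score == mat.n_events

    def test_never_beats_branch_and_bound(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 2, size=(7, 10))
        sets = {
            f"S{i}": [f"e{j}" for j in range(10) if data[i, j]] for i in range(7)
        }
        mat = make_matrix(sets)
        hb = heuristic_search(mat, n_restarts=3, seed=1).best_score
        bb = branch_and_bound_search(mat).best_score
        assert hb >= bb


class TestConsensus:
    def test_single_tree_is_its_own_consensus(self, caterpillar5):
        cons = strict_consensus([caterpillar5])
        assert cons.newick(canonical=True) == caterpillar5.newick(canonical=True)

    def test_rotation_collapses_to_multifurcation(self):
        # two trees differing in the resolution of (A,B,C)
        t1 = RootedTree(
            Node("P", [Node(None, [Node(None, [Node("A"), Node("B")]), Node("C")])]), "P"
        )
        t2 = RootedTree(
            Node("P", [Node(None, [Node("A"), Node(None, [Node("B"), Node("C")])])]), "P"
        )
        cons = strict_consensus([t1, t2])
        assert cons.newick(canonical=True) == "((A,B,C))P;"

    def test_consensus_of_laminar_mpts_is_perfect_phylogeny(self):
        sets = {"A": ["e1"], "B": ["e1"], "C": ["e2"], "D": ["e2"]}
        mat = make_matrix(sets)
        res = exact_search(mat)
        cons = strict_consensus(res.mpt_set)
        masks = {frozenset(["A", "B"]), frozenset(["C", "D"])}
        got = set()

        def walk(n):
            if not n.is_leaf:
                leaves = frozenset(n.leaf_names())
                got.add(leaves)
                for c in n.children:
                    walk(c)

        walk(cons.root)
        assert masks <= got

    def test_mismatched_leaf_sets_rejected(self, caterpillar5):
        other = RootedTree(Node("P", [Node("X")]), "P")
        with pytest.raises(ValueError, match="leaf"):
            strict_consensus([caterpillar5, other])


class TestNewick:
    def test_two_leaf_round_trip(self, tmp_path):
        tree = RootedTree(Node("parent", [Node("A"), Node("B")]), "parent")
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        assert path.read_text().strip() == "(A,B)parent;"
        back = read_newick(path)
        assert back.newick(canonical=True) == tree.newick(canonical=True)

    def test_labels_with_spaces_quoted(self, tmp_path):
        tree = RootedTree(Node("parent", [Node("strain 1"), Node("B")]), "parent")
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        assert "'strain 1'" in path.read_text()
        back = read_newick(path)
        assert set(back.leaves) == {"strain 1", "B"}

    def test_topology_preserved(self, tmp_path, caterpillar5):
        path = tmp_path / "t.nwk"
        write_newick(caterpillar5, path)
        back = read_newick(path)
        assert back.newick(canonical=True) == caterpillar5.newick(canonical=True)
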