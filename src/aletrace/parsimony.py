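"""Camin–Sokal parsimony on rooted strain phylogenies.

The ancestral (parental) genotype is known and all-reference, so every
mutational character is directed: state 0 at the root, gains 0→1 allowed,
losses 1→0 forbidden.  Under this model the minimum number of gains for a
character on a fixed rooted tree equals the number of maximal subtrees
whose leaves all carry the derived state, and the gain edges are the
edges immediately above those subtrees' roots.

Search strategies:

* ``exact_search`` — enumerate every rooted binary topology (n ≤ 8).
* ``branch_and_bound_search`` — stepwise taxon insertion with an
  admissible bound (partial-tree score + characters not yet attachable);
  guarantees global optimality, practical to n ≈ 25 on low-homoplasy
  matrices such as adaptive-evolution catalogs.
* ``heuristic_search`` — random-order stepwise addition followed by
  nearest-neighbour-interchange hill climbing; seeded, no guarantee.

Trees are rooted at the parental strain; sampled intermediate strains are
always leaves (an ancestral strain shows up as a leaf on a zero-gain
pendant edge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .variant_io import EventMatrix

__all__ = [
    "Node",
    "RootedTree",
    "SearchResult",
    "min_gains",
    "tree_score",
    "exact_search",
    "branch_and_bound_search",
    "heuristic_search",
    "strict_consensus",
    "write_newick",
    "read_newick",
]

DEFAULT_MPT_CAP = 10_000
EXACT_MAX_N = 8
BNB_MAX_N = 25


class Node:
    """Tree node; leaves carry strain names, internal nodes may be unnamed."""

    __slots__ = ("name", "children", "parent")

    def __init__(self, name: str | None = None, children: list["Node"] | None = None):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        for c in children or []:
            self.add(c)

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterable["Node"]:
        stack, out = [self], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]


class RootedTree:
    """A strain phylogeny rooted at the parental (all-reference) genotype.

    ``root`` is the parental strain itself; every non-parental strain is a
    leaf.  Internal nodes may multifurcate (consensus trees); search
    operates on binary trees.
    """

    def __init__(self, root: Node, parental: str = "parental"):
        self.root = root
        self.parental = parental
        if root.name is None:
            root.name = parental

    @property
    def leaves(self) -> list[str]:
        names = [n.name for n in self.root.postorder() if n.is_leaf and n is not self.root]
        return names

    def copy(self) -> "RootedTree":
        def _cp(n: Node) -> Node:
            m = Node(n.name)
            for c in n.children:
                m.add(_cp(c))
            return m

        return RootedTree(_cp(self.root), self.parental)

    # ---- clade bookkeeping -------------------------------------------------

    def clade_masks(self, bit_of: Mapping[str, int]) -> dict[int, Node]:
        """Map leaf-set bitmask -> node for every non-root node."""
        masks: dict[int, Node] = {}
        self._fill_masks(self.root, bit_of, masks)
        return masks

    def _fill_masks(self, node: Node, bit_of: Mapping[str, int], out: dict[int, Node]) -> int:
        if node.is_leaf:
            m = bit_of[node.name] if node.name in bit_of else 0
        else:
            m = 0
            for c in node.children:
                m |= self._fill_masks(c, bit_of, out)
        if node is not self.root:
            out[m] = node
        return m

    # ---- Newick ------------------------------------------------------------

    def newick(self, canonical: bool = False) -> str:
        def quote(name: str) -> str:
            if any(ch in name for ch in " ()[]{}:;,'\t"):
                return "'" + name.replace("'", "''") + "'"
            return name

        def fmt(n: Node) -> tuple[str, str]:
            if n.is_leaf:
                return quote(n.name or ""), n.name or ""
            parts = [fmt(c) for c in n.children]
            if canonical:
                parts.sort(key=lambda p: p[1])
            text = "(" + ",".join(p[0] for p in parts) + ")"
            label = quote(n.name) if n.name else ""
            return text + label, min(p[1] for p in parts)

        return fmt(self.root)[0] + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"RootedTree({self.newick()})"


@dataclass
class SearchResult:
    """Outcome of a parsimony search."""

    best_score: int
    mpt_set: list[RootedTree]
    method: str
    seed: int | None = None
    cap_hit: bool = False
    n_optimal: int | None = None

    def __post_init__(self) -> None:
        if self.n_optimal is None:
            self.n_optimal = len(self.mpt_set)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _node_mask_pairs(
    tree: RootedTree, bit_of: Mapping[str, int], sentinel: int
) -> list[tuple[int, int, Node]]:
    """(mask, parent_mask, node) for every non-root node.

    Children of the root get ``sentinel`` as parent mask: the root is the
    parental genotype with state 0 for every character, so it never counts
    as an all-derived subtree.
    """
    pairs: list[tuple[int, int, Node]] = []

    def walk(node: Node) -> int:
        if node.is_leaf:
            m = bit_of.get(node.name, 0)
        else:
            m = 0
            for c in node.children:
                m |= walk(c)
        if node.parent is not None:
            pairs.append((m, 0, node))
        return m

    walk(tree.root)
    # second pass to fill parent masks
    mask_of: dict[int, int] = {}
    for m, _, node in pairs:
        mask_of[id(node)] = m
    out = []
    for m, _, node in pairs:
        p = node.parent
        pm = sentinel if p is tree.root else mask_of[id(p)]
        out.append((m, pm, node))
    return out


def _bits(taxa: Sequence[str]) -> dict[str, int]:
    return {t: 1 << i for i, t in enumerate(taxa)}


def min_gains(
    tree: RootedTree, character: Mapping[str, int]
) -> tuple[int, set[frozenset[str]]]:
    """Minimum number of 0→1 gains for one binary character on ``tree``.

    ``character`` maps every leaf to 0/1 (the parental root is fixed at 0).
    Returns the gain count and the gain edges, each edge identified by the
    frozenset of leaves below it.  The count is the number of maximal
    subtrees whose leaves are all state 1; this is provably minimal over
    all internal labelings with no 1→0 transition and root state 0.
    """
    leaves = tree.leaves
    missing = [l for l in leaves if l not in character]
    if missing:
        raise ValueError(f"leaves without a state: {missing}")
    if character.get(tree.parental, 0) == 1:
        raise ValueError("character assigns state 1 to the parental root")
    bit_of = _bits(leaves)
    full = (1 << len(leaves)) - 1
    sentinel = 1 << len(leaves)
    c = 0
    for l in leaves:
        if character[l]:
            c |= bit_of[l]
    if c == 0:
        return 0, set()
    edges: set[frozenset[str]] = set()
    count = 0
    for m, pm, node in _node_mask_pairs(tree, bit_of, sentinel):
        if m and (m & c) == m and (pm & c) != pm:
            count += 1
            edges.add(frozenset(_names_of_mask(m, leaves)))
    return count, edges


def _names_of_mask(mask: int, taxa: Sequence[str]) -> list[str]:
    return [t for i, t in enumerate(taxa) if mask >> i & 1]


def _char_masks(matrix: EventMatrix, taxa: Sequence[str]) -> list[int]:
    bit_of = _bits(taxa)
    masks = []
    arr = matrix.df.loc[list(taxa)].to_numpy()
    for j in range(arr.shape[1]):
        c = 0
        for i in range(arr.shape[0]):
            if arr[i, j]:
                c |= bit_of[taxa[i]]
        masks.append(c)
    return masks


def _score_masks(
    node_pairs: Sequence[tuple[int, int]], chars: Sequence[int], cutoff: int | None = None
) -> int:
    total = 0
    for c in chars:
        if c == 0:
            continue
        for m, pm in node_pairs:
            if (m & c) == m and (pm & c) != pm:
                total += 1
        if cutoff is not None and total > cutoff:
            return total
    return total


def _check_leaf_match(tree: RootedTree, matrix: EventMatrix) -> None:
    t = set(tree.leaves)
    s = set(matrix.taxa)
    if t != s:
        raise ValueError(
            f"tree leaves and matrix strains differ; only in tree: "
            f"{sorted(t - s)}, only in matrix: {sorted(s - t)}"
        )


def tree_score(tree: RootedTree, matrix: EventMatrix) -> int:
    """Total Camin–Sokal gains of ``matrix`` on ``tree`` (sum over events)."""
    _check_leaf_match(tree, matrix)
    taxa = matrix.taxa
    bit_of = _bits(taxa)
    sentinel = 1 << len(taxa)
    pairs = [(m, pm) for m, pm, _ in _node_mask_pairs(tree, bit_of, sentinel)]
    return _score_masks(pairs, _char_masks(matrix, taxa))


# ---------------------------------------------------------------------------
# search machinery (mutable binary trees over taxon bitmasks)
# ---------------------------------------------------------------------------


class _SNode:
    __slots__ = ("mask", "left", "right", "parent")

    def __init__(self, mask: int = 0):
        self.mask = mask
        self.left: _SNode | None = None
        self.right: _SNode | None = None
        self.parent: _SNode | None = None


def _collect_edges(top: _SNode) -> list[_SNode]:
    out, stack = [], [top]
    while stack:
        n = stack.pop()
        out.append(n)
        if n.left is not None:
            stack.append(n.left)
            stack.append(n.right)
    return out


def _snode_pairs(top: _SNode, sentinel: int) -> tuple[np.ndarray, np.ndarray]:
    """Node and parent bitmasks as uint64 arrays (root parent = sentinel)."""
    nodes = _collect_edges(top)
    masks = np.fromiter((n.mask for n in nodes), dtype=np.uint64, count=len(nodes))
    pmasks = np.fromiter(
        (sentinel if n.parent is None else n.parent.mask for n in nodes),
        dtype=np.uint64,
        count=len(nodes),
    )
    return masks, pmasks


def _score_pairs(
    masks: np.ndarray, pmasks: np.ndarray, chars: np.ndarray
) -> int:
    """Vectorized Camin–Sokal score: gains summed over all characters.

    A node contributes a gain for character c when its subtree is all
    derived (mask ⊆ c) and its parent's is not.  chars == 0 columns
    contribute nothing (no node has an empty mask).
    """
    sub = (masks[:, None] & chars[None, :]) == masks[:, None]
    psub = (pmasks[:, None] & chars[None, :]) == pmasks[:, None]
    return int(np.count_nonzero(sub & ~psub))


def _insert_above(node: _SNode, leaf: _SNode) -> _SNode:
    """Insert ``leaf`` on the edge above ``node``; return the new internal node."""
    parent = node.parent
    joint = _SNode(node.mask | leaf.mask)
    joint.left, joint.right = node, leaf
    node.parent = leaf.parent = joint
    joint.parent = parent
    if parent is not None:
        if parent.left is node:
            parent.left = joint
        else:
            parent.right = joint
    return joint


def _remove_joint(joint: _SNode, leaf: _SNode) -> _SNode:
    """Undo :func:`_insert_above`; returns the surviving child."""
    node = joint.left if joint.right is leaf else joint.right
    parent = joint.parent
    node.parent = parent
    if parent is not None:
        if parent.left is joint:
            parent.left = node
        else:
            parent.right = node
    return node


def _update_masks_up(node: _SNode | None) -> None:
    while node is not None:
        node.mask = node.left.mask | node.right.mask
        node = node.parent


def _stree_to_rooted(top: _SNode, taxa: Sequence[str], parental: str) -> RootedTree:
    def build(n: _SNode) -> Node:
        if n.left is None:
            names = _names_of_mask(n.mask, taxa)
            return Node(names[0])
        return Node(None, [build(n.left), build(n.right)])

    root = Node(parental)
    root.add(build(top))
    return RootedTree(root, parental)


def _search_order(matrix: EventMatrix) -> list[str]:
    # insert mutation-rich strains first: conflicts surface early, bound bites
    sums = matrix.df.sum(axis=1)
    taxa = matrix.taxa
    return sorted(taxa, key=lambda t: (-int(sums[t]), t))


def _collapse_duplicates(matrix: EventMatrix) -> tuple[EventMatrix, dict[str, list[str]]]:
    """Group strains with identical genotypes; keep one representative each."""
    groups: dict[tuple, list[str]] = {}
    for t in matrix.taxa:
        key = tuple(matrix.df.loc[t].to_numpy().tolist())
        groups.setdefault(key, []).append(t)
    rep_of: dict[str, list[str]] = {}
    keep = [matrix.parental]
    for members in groups.values():
        rep = members[0]
        rep_of[rep] = members
        keep.append(rep)
    if len(keep) - 1 == len(matrix.taxa):
        return matrix, {t: [t] for t in matrix.taxa}
    sub = EventMatrix(
        matrix.df.loc[keep], matrix.events, matrix.parental, matrix.stage_temps
    )
    return sub, rep_of


def _expand_duplicates(tree: RootedTree, rep_of: dict[str, list[str]]) -> RootedTree:
    def walk(n: Node) -> Node:
        if n.is_leaf and n.name in rep_of and len(rep_of[n.name]) > 1:
            clone = Node(None)
            for name in rep_of[n.name]:
                clone.add(Node(name))
            return clone
        m = Node(n.name)
        for c in n.children:
            m.add(walk(c))
        return m

    root = walk(tree.root)
    root.name = tree.parental
    return RootedTree(root, tree.parental)


def _stepwise_insert_all(
    taxa: Sequence[str],
    order: Sequence[int],
    chars: Sequence[int],
    sentinel: int,
    rng: np.random.Generator | None = None,
) -> _SNode:
    """Greedy stepwise addition; returns the completed binary tree."""
    top = _SNode(1 << order[0])
    for idx in order[1:]:
        leaf = _SNode(1 << idx)
        added_mask = top.mask | leaf.mask
        sub = chars & np.uint64(added_mask)
        best_edge, best_sc = None, None
        edges = _collect_edges(top)
        if rng is not None:
            perm = rng.permutation(len(edges))
            edges = [edges[i] for i in perm]
        for node in edges:
            joint = _insert_above(node, leaf)
            _update_masks_up(joint.parent)
            new_top = top if top.parent is None else joint
            sc = _score_pairs(*_snode_pairs(new_top, sentinel), sub)
            if best_sc is None or sc < best_sc:
                best_sc, best_edge = sc, node
            _remove_joint(joint, leaf)
            _update_masks_up(node.parent)
        joint = _insert_above(best_edge, leaf)
        _update_masks_up(joint.parent)
        if top.parent is not None:
            top = joint
    return top


def _nni_moves(top: _SNode) -> Iterable[tuple[_SNode, _SNode]]:
    """Yield (internal node v, grandchild g) pairs: swap g with v's sibling."""
    for v in _collect_edges(top):
        if v.left is None or v.parent is None:
            continue
        yield v, v.left
        yield v, v.right


def _apply_nni(v: _SNode, g: _SNode) -> tuple[_SNode, _SNode]:
    """Swap grandchild ``g`` (child of v) with v's sibling; return undo info."""
    p = v.parent
    sib = p.left if p.right is v else p.right
    # replace g under v with sib
    if v.left is g:
        v.left = sib
    else:
        v.right = sib
    sib.parent = v
    # replace sib under p with g
    if p.left is sib:
        p.left = g
    else:
        p.right = g
    g.parent = p
    v.mask = v.left.mask | v.right.mask
    _update_masks_up(p)
    return sib, g


def _copy_stree(top: _SNode) -> _SNode:
    def cp(n: _SNode) -> _SNode:
        m = _SNode(n.mask)
        if n.left is not None:
            m.left = cp(n.left)
            m.right = cp(n.right)
            m.left.parent = m.right.parent = m
        return m

    return cp(top)


def _canonical_key(top: _SNode) -> tuple:
    def key(n: _SNode) -> tuple:
        if n.left is None:
            return (n.mask,)
        a, b = key(n.left), key(n.right)
        return (n.mask,) + tuple(sorted((a, b)))

    return key(top)


def heuristic_search(
    matrix: EventMatrix,
    n_restarts: int = 10,
    seed: int = 0,
    cap: int = DEFAULT_MPT_CAP,
    nni: bool = True,
    collapse_duplicates: bool = True,
) -> SearchResult:
    """Stepwise addition with random order + NNI hill climbing.

    Deterministic given ``seed``; the reported score is an upper bound on
    the true optimum (no optimality guarantee).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    work, rep_of = (
        _collapse_duplicates(matrix) if collapse_duplicates else (matrix, None)
    )
    taxa = work.taxa
    if len(taxa) == 0:
        raise ValueError("matrix has no non-parental strains")
    if len(taxa) == 1:
        tree = RootedTree(Node(matrix.parental, [Node(taxa[0])]), matrix.parental)
        if rep_of:
            tree = _expand_duplicates(tree, rep_of)
        return SearchResult(tree_score(tree, matrix), [tree], "heuristic", seed)
    chars = np.array(_char_masks(work, taxa), dtype=np.uint64)
    sentinel = 1 << len(taxa)
    rng = np.random.default_rng(seed)
    best_sc: int | None = None
    best_keys: set[tuple] = set()
    best_trees: list[_SNode] = []
    cap_hit = False
    for _ in range(n_restarts):
        order = list(rng.permutation(len(taxa)))
        top = _stepwise_insert_all(taxa, order, chars, sentinel, rng=rng)
        sc = _score_pairs(*_snode_pairs(top, sentinel), chars)
        if nni:
            improved = True
            while improved:
                improved = False
                for v, g in list(_nni_moves(top)):
                    sib, g2 = _apply_nni(v, g)
                    new_sc = _score_pairs(*_snode_pairs(top, sentinel), chars)
                    if new_sc < sc:
                        sc = new_sc
                        improved = True
                        break
                    _apply_nni(v, sib)  # undo: swap back
                # loop re-collects moves after an improvement
        if best_sc is None or sc < best_sc:
            best_sc = sc
            best_keys.clear()
            best_trees = []
            cap_hit = False
        if sc == best_sc:
            k = _canonical_key(top)
            if k not in best_keys:
                if len(best_trees) < cap:
                    best_keys.add(k)
                    best_trees.append(_copy_stree(top))
                else:
                    cap_hit = True
    mpts = [_stree_to_rooted(t, taxa, matrix.parental) for t in best_trees]
    if rep_of:
        mpts = [_expand_duplicates(t, rep_of) for t in mpts]
    return SearchResult(
        int(best_sc), mpts, "heuristic", seed=seed, cap_hit=cap_hit
    )


def _exhaustive_generate(
    n_taxa: int,
    chars: np.ndarray,
    sentinel: int,
    cap: int,
    upper: int | None,
    prune: bool,
) -> tuple[int, list[_SNode], bool, int]:
    """Shared engine for exact enumeration (prune=False) and B&B (prune=True)."""
    best: int | None = upper
    found: list[_SNode] = []
    n_opt = 0
    cap_hit = False
    top_holder = [_SNode(1)]
    nonempty = chars != 0

    def bound(top: _SNode, added_mask: int) -> int:
        # admissible: partial-tree score on inserted taxa + one future gain
        # for every non-empty character with no derived taxon inserted yet
        sub = chars & np.uint64(added_mask)
        pending = int(np.count_nonzero(nonempty & (sub == 0)))
        return _score_pairs(*_snode_pairs(top, sentinel), sub) + pending

    def recurse(i: int, top: _SNode, added_mask: int) -> _SNode:
        nonlocal best, found, n_opt, cap_hit
        if i == n_taxa:
            sc = _score_pairs(*_snode_pairs(top, sentinel), chars)
            if best is None or sc < best:
                best = sc
                found = []
                n_opt = 0
                cap_hit = False
            if sc == best:
                n_opt += 1
                if len(found) < cap:
                    found.append(_copy_stree(top))
                else:
                    cap_hit = True
            return top
        leaf_bit = 1 << i
        for node in _collect_edges(top):
            joint = _insert_above(node, _SNode(leaf_bit))
            leaf = joint.right
            _update_masks_up(joint.parent)
            new_top = joint if node is top else top
            nm = added_mask | leaf_bit
            descend = True
            if prune and best is not None:
                b = bound(new_top, nm)
                if b > best:
                    descend = False  # admissible bound: no completion can win
                elif b == best and len(found) >= cap:
                    # completions can only tie; the tie set is already full
                    descend = False
                    cap_hit = True
            if descend:
                recurse(i + 1, new_top, nm)
            _remove_joint(joint, leaf)
            _update_masks_up(node.parent)
        return top

    recurse(1, top_holder[0], 1)
    return int(best), found, cap_hit, n_opt


def _run_tree_search(
    matrix: EventMatrix,
    method: str,
    cap: int,
    collapse_duplicates: bool,
    seed: int | None = None,
) -> SearchResult:
    work, rep_of = (
        _collapse_duplicates(matrix) if collapse_duplicates else (matrix, None)
    )
    taxa = _search_order(work)
    n = len(taxa)
    if n == 0:
        raise ValueError("matrix has no non-parental strains")
    if n == 1:
        tree = RootedTree(Node(matrix.parental, [Node(taxa[0])]), matrix.parental)
        if rep_of:
            tree = _expand_duplicates(tree, rep_of)
        return SearchResult(tree_score(tree, matrix), [tree], method)
    chars = np.array(_char_masks(work, taxa), dtype=np.uint64)
    sentinel = 1 << n
    if method == "branch_and_bound":
        warm = heuristic_search(
            work, n_restarts=3, seed=0 if seed is None else seed, cap=1,
            collapse_duplicates=False,
        )
        upper = warm.best_score
        prune = True
    else:
        upper, prune = None, False
    best, strees, cap_hit, n_opt = _exhaustive_generate(
        n, chars, sentinel, cap, upper, prune
    )
    if cap_hit:
        warnings.warn(
            f"MPT cap of {cap} reached (at least {n_opt} optimal topologies); "
            "returned set is truncated — raise the cap to keep them all"
        )
    mpts = [_stree_to_rooted(t, taxa, matrix.parental) for t in strees]
    if rep_of:
        mpts = [_expand_duplicates(t, rep_of) for t in mpts]
    return SearchResult(best, mpts, method, seed=seed, cap_hit=cap_hit, n_optimal=n_opt)


def exact_search(
    matrix: EventMatrix,
    cap: int = DEFAULT_MPT_CAP,
    collapse_duplicates: bool = False,
) -> SearchResult:
    """Enumerate every rooted binary topology; globally optimal (n ≤ 8)."""
    n = len(matrix.taxa) if not collapse_duplicates else len(
        _collapse_duplicates(matrix)[0].taxa
    )
    if n > EXACT_MAX_N:
        raise ValueError(
            f"exact enumeration is limited to {EXACT_MAX_N} strains (got {n}); "
            "use branch_and_bound_search or heuristic_search"
        )
    return _run_tree_search(matrix, "exact", cap, collapse_duplicates)


def branch_and_bound_search(
    matrix: EventMatrix,
    cap: int = DEFAULT_MPT_CAP,
    max_n: int = BNB_MAX_N,
    collapse_duplicates: bool = True,
    seed: int | None = None,
) -> SearchResult:
    """Globally optimal search by branch and bound.

    The bound (score of the partial tree plus the number of non-empty
    characters with no derived taxon inserted yet) never exceeds the score
    of any completion, so no optimum is pruned.
    """
    n = len(_collapse_duplicates(matrix)[0].taxa) if collapse_duplicates else len(
        matrix.taxa
    )
    if n > max_n:
        raise ValueError(
            f"branch and bound limited to {max_n} distinct genotypes (got {n}); "
            "use heuristic_search"
        )
    return _run_tree_search(matrix, "branch_and_bound", cap, collapse_duplicates, seed)


def strict_consensus(mpt_set: Sequence[RootedTree]) -> RootedTree:
    """Multifurcating tree containing exactly the clades common to all MPTs."""
    if not mpt_set:
        raise ValueError("empty MPT set")
    leaf_sets = {frozenset(t.leaves) for t in mpt_set}
    if len(leaf_sets) != 1:
        raise ValueError("MPTs have mismatched leaf sets")
    parental = mpt_set[0].parental
    taxa = sorted(next(iter(leaf_sets)))
    bit_of = _bits(taxa)
    common: set[int] | None = None
    for t in mpt_set:
        masks = set(t.clade_masks(bit_of))
        common = masks if common is None else (common & masks)
    full = (1 << len(taxa)) - 1
    keep = sorted(common | {full}, key=lambda m: -bin(m).count("1"))
    root = Node(parental)
    node_of: dict[int, Node] = {}
    placed: list[int] = []
    for m in keep:
        node = Node(None)
        names = _names_of_mask(m, taxa)
        if len(names) == 1:
            node.name = names[0]
        # attach under the smallest strict superset already placed
        best_sup = None
        for pm in placed:
            if pm != m and (m & pm) == m:
                if best_sup is None or bin(pm).count("1") < bin(best_sup).count("1"):
                    best_sup = pm
        (node_of[best_sup] if best_sup is not None else root).add(node)
        node_of[m] = node
        placed.append(m)
    return RootedTree(root, parental)


def write_newick(tree: RootedTree, path: str | Path) -> None:
    """Write the tree as standard Newick (quoted labels where needed)."""
    Path(path).write_text(tree.newick() + "\n")


def read_newick(source: str | Path, parental: str | None = None) -> RootedTree:
    """Read a Newick tree (file path or string) into a :class:`RootedTree`.

    The root label, if present, names the parental strain; otherwise pass
    ``parental=`` explicitly.
    """
    import dendropy

    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    dt = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    def conv(dn) -> Node:
        label = dn.taxon.label if dn.taxon is not None else dn.label
        n = Node(label)
        for c in dn.child_nodes():
            n.add(conv(c))
        return n

    root = conv(dt.seed_node)
    name = root.name or parental
    if name is None:
        raise ValueError("root has no label; pass parental= to name the root strain")
    root.name = name
    return RootedTree(root, name)
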