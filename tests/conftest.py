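"""Shared test helpers: matrix builders, tree enumeration, and an
independent brute-force Camin–Sokal oracle (exhaustive minimization over
internal labelings), kept deliberately separate from the library's
max-subtree scorer so the two can check each other."""

from __future__ import annotations

import itertools

import pytest

from aletrace.parsimony import Node, RootedTree
from aletrace.variant_io import MutationEvent, StrainRecord, build_event_matrix


def make_matrix(strain_sets: dict[str, list[str]], parental: str = "P"):
    """Build an EventMatrix from {strain: [character names]}."""
    events: dict[str, MutationEvent] = {}
    strains = [StrainRecord(parental, "parental", frozenset())]
    for s, items in strain_sets.items():
        ids = []
        for e in items:
            if e not in events:
                events[e] = MutationEvent(chrom="chr1", pos=len(events) + 1, ref="A", alt="T")
            ids.append(events[e].event_id)
        strains.append(StrainRecord(s, "", frozenset(ids)))
    return build_event_matrix(list(events.values()), strains, parental=parental)


def event_name_map(matrix) -> dict[str, str]:
    """Map character name (by construction order = position) to event_id."""
    return {eid: eid for eid in matrix.event_ids}


def all_rooted_binary_trees(leaves: list[str], parental: str = "P"):
    """Yield every rooted binary topology on ``leaves`` exactly once.

    Trees are built by inserting leaves in order into every edge of the
    growing subtree (including the stem), the standard bijective
    enumeration giving (2n-3)!! topologies for n >= 2.
    """

    def insert_everywhere(shape, leaf):
        # shape is a leaf name or a (left, right) tuple
        yield (shape, leaf)
        if isinstance(shape, tuple):
            left, right = shape
            for new_left in insert_everywhere(left, leaf):
                yield (new_left, right)
            for new_right in insert_everywhere(right, leaf):
                yield (left, new_right)

    shapes = [leaves[0]]
    for leaf in leaves[1:]:
        shapes = [s for old in shapes for s in insert_everywhere(old, leaf)]

    def to_tree(shape):
        def build(s):
            if isinstance(s, str):
                return Node(s)
            return Node(None, [build(s[0]), build(s[1])])

        root = Node(parental)
        root.add(build(shape))
        return RootedTree(root, parental)

    for shape in shapes:
        yield to_tree(shape)


def brute_force_min_gains(tree: RootedTree, character: dict[str, int]) -> int:
    """Exhaustive minimum over all internal labelings.

    Root fixed at 0, leaf states fixed by ``character``; a labeling is
    admissible iff no edge goes 1 -> 0 (irreversibility); its cost is the
    number of 0 -> 1 edges.  Returns the minimal cost.
    """
    internal = [
        n
        for n in tree.root.postorder()
        if not n.is_leaf and n is not tree.root
    ]
    best = None
    for assignment in itertools.product([0, 1], repeat=len(internal)):
        state = {id(n): a for n, a in zip(internal, assignment)}
        state[id(tree.root)] = 0
        for n in tree.root.postorder():
            if n.is_leaf and n is not tree.root:
                state[id(n)] = character[n.name]
        ok = True
        cost = 0
        for n in tree.root.postorder():
            if n is tree.root:
                continue
            up, down = state[id(n.parent)], state[id(n)]
            if up == 1 and down == 0:
                ok = False
                break
            if up == 0 and down == 1:
                cost += 1
        if ok and (best is None or cost < best):
            best = cost
    return best


@pytest.fixture
def caterpillar5():
    """Fixed 5-leaf tree (((A,B),C),(D,E)) under the parental root."""
    ab = Node(None, [Node("A"), Node("B")])
    abc = Node(None, [ab, Node("C")])
    de = Node(None, [Node("D"), Node("E")])
    top = Node(None, [abc, de])
    root = Node("P", [top])
    return RootedTree(root, "P")


@pytest.fixture
def study_matrix():
    from aletrace.datasets import synthetic_study_matrix

    return synthetic_study_matrix()
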