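"""Independent reference implementations used to check the package.

Everything here is deliberately written in a different style from the library
(top-down recursion, exhaustive enumeration over labelings, path-sum
distances) so the two routes only agree when both are right.
"""
from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from copiievo.formats import PhyloTree, TreeNode


# ---------------------------------------------------------------------------
# local alignment by exhaustive path recursion
# ---------------------------------------------------------------------------

def sw_brute_force(a: str, b: str, scheme) -> int:
    """Best local alignment score by recursion over alignment operations.

    A gap of length k costs gap_open + k * gap_extend.  Local alignments
    never gain from boundary gaps, so paths start and may stop after any
    match/mismatch column.
    """
    m, n = len(a), len(b)
    sub = scheme.score
    go, ge = scheme.gap_open, scheme.gap_extend

    @lru_cache(maxsize=None)
    def extend(i: int, j: int, last: str) -> float:
        best = 0.0  # stopping here is always allowed
        if i < m and j < n:
            best = max(best, sub(a[i], b[j]) + extend(i + 1, j + 1, "M"))
        if i < m:
            cost = ge + (go if last != "I" else 0)
            best = max(best, cost + extend(i + 1, j, "I"))
        if j < n:
            cost = ge + (go if last != "D" else 0)
            best = max(best, cost + extend(i, j + 1, "D"))
        return best

    best = 0.0
    for i in range(m):
        for j in range(n):
            best = max(best, sub(a[i], b[j]) + extend(i + 1, j + 1, "M"))
    extend.cache_clear()
    return int(round(best))


# ---------------------------------------------------------------------------
# Dollo by exhaustive labeling enumeration
# ---------------------------------------------------------------------------

def dollo_brute_force(tree: PhyloTree, tip_states: dict[str, bool]) -> int:
    """Minimum loss count over all single-gain ancestral labelings.

    Enumerates every assignment of present/absent to internal nodes, keeps
    those with exactly one gain (a 0->1 edge, or presence at the root), and
    returns the minimum number of 1->0 edges.
    """
    internals = [n for n in tree.root.preorder() if not n.is_leaf]
    best = None
    for bits in itertools.product([False, True], repeat=len(internals)):
        state = {id(n): b for n, b in zip(internals, bits)}
        for leaf in tree.leaves():
            state[id(leaf)] = tip_states[leaf.name]
        gains = 1 if state[id(tree.root)] else 0
        losses = 0
        ok = True
        for node in tree.root.preorder():
            for child in node.children:
                if not state[id(node)] and state[id(child)]:
                    gains += 1
                elif state[id(node)] and not state[id(child)]:
                    losses += 1
            if gains > 1:
                ok = False
                break
        if ok and gains == 1:
            if best is None or losses < best:
                best = losses
    assert best is not None, "no valid single-gain labeling (no present tip?)"
    return best


# ---------------------------------------------------------------------------
# random trees and additive distance matrices
# ---------------------------------------------------------------------------

def random_rooted_tree(n_leaves: int, rng: np.random.Generator) -> PhyloTree:
    """Random rooted binary tree with uniform [0.1, 1] branch lengths."""
    nodes = [TreeNode(f"t{i}", float(rng.uniform(0.1, 1.0))) for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(None, float(rng.uniform(0.1, 1.0)), [a, b]))
    root = TreeNode(None, 0.0, nodes)
    return PhyloTree(root, rooted=True)


def random_unrooted_tree(n_leaves: int, rng: np.random.Generator) -> PhyloTree:
    """Random unrooted binary tree grown by attaching leaves to random edges."""
    assert n_leaves >= 4
    root = TreeNode(None, 0.0, [TreeNode(f"t{i}", float(rng.uniform(0.1, 1.0))) for i in range(3)])
    tree = PhyloTree(root, rooted=False)
    for i in range(3, n_leaves):
        edges = [n for n in root.preorder() if n is not root]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        split = TreeNode(None, target.length * 0.5)
        target.length *= 0.5
        parent.children[parent.children.index(target)] = split
        split.parent = parent
        split.add(target)
        split.add(TreeNode(f"t{i}", float(rng.uniform(0.1, 1.0))))
    return PhyloTree(root, rooted=False)


def path_distances(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix by explicit traversal."""
    leaves = tree.leaves()
    names = [l.name for l in leaves]
    adj: dict[int, list[tuple[TreeNode, float]]] = {}
    for node in tree.iter_nodes():
        for child in node.children:
            adj.setdefault(id(node), []).append((child, child.length))
            adj.setdefault(id(child), []).append((node, child.length))
    out = np.zeros((len(leaves), len(leaves)))
    for i, leaf in enumerate(leaves):
        dist = {id(leaf): 0.0}
        stack = [leaf]
        while stack:
            node = stack.pop()
            for nbr, length in adj.get(id(node), []):
                if id(nbr) not in dist:
                    dist[id(nbr)] = dist[id(node)] + length
                    stack.append(nbr)
        for j, other in enumerate(leaves):
            out[i, j] = dist[id(other)]
    out = (out + out.T) / 2.0  # exact symmetry despite fp path-sum order
    return names, out
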