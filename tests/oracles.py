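"""Independent test-side oracles: brute-force implementations kept
deliberately separate from the package's code paths."""

from __future__ import annotations

import itertools
import math


# ---------------------------------------------------- newick / bipartitions


def parse_newick(s: str):
    """Tiny recursive-descent Newick parser -> nested tuples / leaf labels."""
    import re

    s = re.sub(r"\[.*?\]", "", s)  # bracket comments, e.g. [&R]
    s = s.strip().rstrip(";").strip()
    pos = 0

    def parse():
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = [parse()]
            while s[pos] == ",":
                pos += 1
                children.append(parse())
            assert s[pos] == ")"
            pos += 1
            # skip internal label / branch length
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            return tuple(children)
        start = pos
        while pos < len(s) and s[pos] not in ",()":
            pos += 1
        label = s[start:pos].split(":")[0].strip()
        return label

    return parse()


def leafset(node) -> frozenset:
    if isinstance(node, str):
        return frozenset([node])
    return frozenset().union(*(leafset(c) for c in node))


def bipartitions(tree) -> set:
    """Nontrivial bipartitions of an unrooted tree given as nested tuples."""
    all_leaves = leafset(tree)
    out = set()

    def walk(node):
        if isinstance(node, str):
            return
        for child in node:
            side = leafset(child)
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(frozenset({side, all_leaves - side}))
            walk(child)

    walk(tree)
    return out


def rf_bruteforce(nwk1: str, nwk2: str) -> int:
    """Symmetric difference of bipartition sets, from first principles."""
    b1 = bipartitions(parse_newick(nwk1))
    b2 = bipartitions(parse_newick(nwk2))
    return len(b1 ^ b2)


# ----------------------------------------------- unrooted tree enumeration


def all_unrooted_trees(leaves):
    """Every unrooted binary topology on the given leaves, as newicks.

    Trees are built by inserting each successive leaf into every edge of
    every smaller tree; an unrooted tree is held as a rooted structure
    whose root is a trifurcation.  For 6 leaves this yields 105 trees.
    """
    leaves = list(leaves)
    assert len(leaves) >= 3

    def edges(node, parent_path):
        """Addresses of all edges below node (paths of child indices)."""
        out = []
        if isinstance(node, str):
            return out
        for i, child in enumerate(node):
            path = parent_path + (i,)
            out.append(path)
            out.extend(edges(child, path))
        return out

    def insert(node, path, leaf):
        if len(path) == 0:
            raise AssertionError("cannot insert at the root itself")
        i = path[0]
        children = list(node)
        if len(path) == 1:
            children[i] = (children[i], leaf)
        else:
            children[i] = insert(children[i], path[1:], leaf)
        return tuple(children)

    trees = [(leaves[0], leaves[1], leaves[2])]
    for leaf in leaves[3:]:
        nxt = []
        for t in trees:
            for path in edges(t, ()):
                nxt.append(insert(t, path, leaf))
        trees = nxt

    def to_newick(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(to_newick(c) for c in node) + ")"

    return [to_newick(t) + ";" for t in trees]


# ------------------------------------------------------ graph path algebra


def graph_paths(edges: dict, admixture: dict, leaf: str):
    """All rootward paths from a leaf as (probability, edge frozenset)."""
    parents: dict[str, list[str]] = {}
    for (p, c) in edges:
        parents.setdefault(c, []).append(p)
    root = ({p for p, _ in edges} - set(parents)).pop()

    def up(node):
        if node == root:
            return [(1.0, frozenset())]
        result = []
        for parent in parents[node]:
            if node in admixture:
                p1, p2, a = admixture[node]
                prob = a if parent == p1 else 1.0 - a
            else:
                prob = 1.0
            for pr, es in up(parent):
                result.append((prob * pr, es | {(parent, node)}))
        return result

    return up(leaf)


def f4_pathpairs(edges: dict, admixture: dict, quartet) -> float:
    """E[f4] as a sum over 4-tuples of root paths, weighted by their
    probabilities, of the signed overlap drift sums."""
    paths = {x: graph_paths(edges, admixture, x) for x in quartet}
    a, b, c, d = quartet

    def dsum(es):
        return sum(edges[e] for e in es)

    total = 0.0
    for (pa, ea), (pb, eb), (pc, ec), (pd, ed) in itertools.product(
        paths[a], paths[b], paths[c], paths[d]
    ):
        w = pa * pb * pc * pd
        total += w * (
            dsum(ea & ec) - dsum(ea & ed) - dsum(eb & ec) + dsum(eb & ed)
        )
    return total


# -------------------------------------------------------------- jackknife


def jackknife_unweighted(nums, dens):
    """Plain delete-one jackknife SE of a ratio with equal block weights."""
    g = len(nums)
    tot_n, tot_d = sum(nums), sum(dens)
    loo = [(tot_n - n) / (tot_d - d) for n, d in zip(nums, dens)]
    mean = sum(loo) / g
    var = (g - 1) / g * sum((x - mean) ** 2 for x in loo)
    return tot_n / tot_d, math.sqrt(var)
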