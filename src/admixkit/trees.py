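"""Local-tree utilities: Newick I/O, RF distances, topology counting.

Window-local gene trees are compared as unrooted topologies; an outgroup,
when given, is used only to orient triplet classification.  Robinson--
Foulds distances come from bipartition comparison (dendropy); topology
counting prunes every local tree to a focal taxon set and tallies the
resulting resolved topologies, the per-window topology-weighting summary
used to visualise discordance along the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "LocalTreeSet",
    "TreeError",
    "rf_distance",
    "topology_counts",
    "select_concordant_windows",
]


class TreeError(ValueError):
    """Raised for incompatible tree inputs."""


def _as_trees(newicks, namespace=None):
    tns = namespace or dendropy.TaxonNamespace()
    trees = []
    for nwk in newicks:
        if isinstance(nwk, dendropy.Tree):
            nwk = nwk.as_string(schema="newick")
        t = dendropy.Tree.get(
            data=nwk, schema="newick", taxon_namespace=tns,
            rooting="force-unrooted",
        )
        trees.append(t)
    return trees, tns


@dataclass
class LocalTreeSet:
    """Window-indexed local trees sharing one taxon namespace."""

    trees: list[dendropy.Tree]
    window_ids: list
    taxon_namespace: dendropy.TaxonNamespace

    @classmethod
    def from_newick_file(cls, path, window_ids=None) -> "LocalTreeSet":
        """Read one Newick tree per line; window ids default to line order."""
        with open(path) as fh:
            lines = [l.strip() for l in fh if l.strip()]
        trees, tns = _as_trees(lines)
        ids = list(window_ids) if window_ids is not None else list(range(len(trees)))
        if len(ids) != len(trees):
            raise TreeError("window_ids length does not match tree count")
        return cls(trees=trees, window_ids=ids, taxon_namespace=tns)

    @classmethod
    def from_newicks(cls, newicks, window_ids=None) -> "LocalTreeSet":
        trees, tns = _as_trees(list(newicks))
        ids = list(window_ids) if window_ids is not None else list(range(len(trees)))
        return cls(trees=trees, window_ids=ids, taxon_namespace=tns)

    def __len__(self) -> int:
        return len(self.trees)


# ------------------------------------------------------------------- RF


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {l.taxon.label for l in tree.leaf_node_iter()}


def rf_distance(tree1, tree2, normalized: bool = False) -> float:
    """Robinson--Foulds distance between two trees on identical leaf sets.

    The symmetric difference of nontrivial bipartition sets, compared
    unrooted; ``normalized`` divides by the maximum 2(n-3) for n leaves.
    Leaf-set mismatch raises rather than silently pruning.
    """
    (t1, t2), _ = _as_trees([tree1, tree2])
    l1, l2 = _leaf_labels(t1), _leaf_labels(t2)
    if l1 != l2:
        raise TreeError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    d = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
    if not normalized:
        return float(d)
    n = len(l1)
    if n <= 3:
        return 0.0
    return float(d) / (2.0 * (n - 3))


# -------------------------------------------------------------- topology


def _topology_key(tree: dendropy.Tree) -> frozenset:
    """Canonical label-set key of a tree's nontrivial bipartitions."""
    labels = sorted(_leaf_labels(tree))
    tree.encode_bipartitions()
    keys = set()
    for bp in tree.bipartition_encoding:
        taxa = {
            t.label
            for t in tree.taxon_namespace.bitmask_taxa_list(bp.leafset_bitmask)
        }
        side = frozenset(taxa)
        other = frozenset(set(labels) - taxa)
        if 1 < len(side) < len(labels) - 1:
            keys.add(frozenset({side, other}))
    return frozenset(keys)


def _prune_to(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree | None:
    t = tree.clone(depth=1)
    present = _leaf_labels(t)
    if not keep <= present:
        return None
    t.retain_taxa_with_labels(sorted(keep))
    return t


def _is_binary_unrooted(tree: dendropy.Tree) -> bool:
    n = len(list(tree.leaf_node_iter()))
    return len(_topology_key(tree)) == max(n - 3, 0)


def topology_counts(treeset: LocalTreeSet, focal_taxa, outgroup: str | None = None):
    """Proportion of windows supporting each resolved focal topology.

    Every local tree is pruned to the focal taxa (plus outgroup when
    given) and its unrooted topology tallied.  Windows whose pruned tree
    is polytomic count as unresolved; windows missing a focal taxon are
    flagged and excluded from the denominator.  Returns a dict with
    'proportions' (topology key -> fraction of classified windows),
    'counts', 'n_unresolved' and 'flagged_windows'.
    """
    focal = set(focal_taxa)
    if outgroup:
        focal = focal | {outgroup}
    if len(focal) < 3:
        raise TreeError("need at least 3 focal taxa")
    counts: dict = {}
    examples: dict = {}
    unresolved = 0
    flagged = []
    for wid, tree in zip(treeset.window_ids, treeset.trees):
        pruned = _prune_to(tree, focal)
        if pruned is None:
            flagged.append(wid)
            continue
        if not _is_binary_unrooted(pruned):
            unresolved += 1
            continue
        key = _topology_key(pruned)
        counts[key] = counts.get(key, 0) + 1
        examples.setdefault(
            key, pruned.as_string(schema="newick", suppress_rooting=True).strip()
        )
    total = sum(counts.values())
    proportions = {k: v / total for k, v in counts.items()} if total else {}
    return {
        "proportions": proportions,
        "counts": counts,
        "examples": examples,
        "n_classified": total,
        "n_unresolved": unresolved,
        "flagged_windows": flagged,
    }


def select_concordant_windows(treeset: LocalTreeSet, consensus) -> tuple[list, float]:
    """Windows whose local-tree topology matches the consensus exactly.

    Concordance means unrooted RF distance 0 (branch lengths ignored).
    Returns (retained window ids, retained fraction).
    """
    (cons,), _ = _as_trees([consensus])
    cons_key = _topology_key(cons)
    cons_leaves = _leaf_labels(cons)
    retained = []
    for wid, tree in zip(treeset.window_ids, treeset.trees):
        if _leaf_labels(tree) != cons_leaves:
            raise TreeError(f"window {wid}: leaf set differs from consensus")
        if _topology_key(tree) == cons_key:
            retained.append(wid)
    frac = len(retained) / len(treeset.trees) if len(treeset) else float("nan")
    return retained, frac
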