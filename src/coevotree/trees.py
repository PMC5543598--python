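"""Phylogenetic trees: Newick I/O, neighbor joining, rooting and comparison.

Trees are thin wrappers around :class:`dendropy.Tree`.  Topology comparison
uses unrooted bipartitions, each represented as the frozenset of leaf labels
on the side *not* containing the lexicographically smallest leaf, so that the
representation is unique regardless of edge orientation.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import dendropy
import numpy as np


class NewickParseError(ValueError):
    pass


class PhyloTree:
    """A rooted or unrooted tree with uniquely labeled leaves."""

    def __init__(self, dtree: dendropy.Tree, rooted: bool = False):
        labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None and (edge.length < 0 or not np.isfinite(edge.length)):
                raise ValueError(f"branch length must be finite and >= 0, got {edge.length}")
        self._dtree = dtree
        self.rooted = rooted

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, path_or_string: str | Path, rooted: bool | None = None) -> "PhyloTree":
        """Parse Newick from a file path or a literal string.

        Missing branch lengths default to 1.0 (with a warning).  Rootedness is
        taken from a ``[&R]`` hint when present, else the tree is treated as
        rooted when its root is bifurcating.
        """
        if isinstance(path_or_string, Path) or (
            isinstance(path_or_string, str)
            and "(" not in path_or_string
            and ";" not in path_or_string
        ):
            text = Path(path_or_string).read_text()
        else:
            text = str(path_or_string)
        if ";" not in text:
            raise NewickParseError(
                f"missing semicolon at offset {len(text)}: {text[:40]!r}..."
            )
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"newick parse error: {exc}") from exc
        missing = 0
        for edge in dtree.preorder_edge_iter():
            if edge.tail_node is None:
                continue  # root edge carries no length
            if edge.length is None:
                edge.length = 1.0
                missing += 1
        if missing:
            warnings.warn(
                f"{missing} branch length(s) missing in Newick input; defaulted to 1.0",
                stacklevel=2,
            )
        if rooted is None:
            rooted = dtree.is_rooted or len(dtree.seed_node.child_nodes()) == 2
        return cls(dtree, rooted=rooted)

    def to_newick(self, precision: int = 6) -> str:
        s = self._dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=f".{precision}f",
        ).strip()
        return s

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._dtree.clone(depth=1), rooted=self.rooted)

    # -- basic accessors ---------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._dtree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def _leafset_below(self) -> dict[dendropy.Node, frozenset[str]]:
        below: dict[dendropy.Node, frozenset[str]] = {}
        for node in self._dtree.postorder_node_iter():
            if node.is_leaf():
                below[node] = frozenset([node.taxon.label])
            else:
                acc: set[str] = set()
                for child in node.child_nodes():
                    acc |= below[child]
                below[node] = frozenset(acc)
        return below

    def clade_leafsets(self) -> set[frozenset[str]]:
        """Child-side leaf sets of every non-root branch (rooted view)."""
        below = self._leafset_below()
        return {
            below[node]
            for node in self._dtree.preorder_node_iter()
            if node.parent_node is not None
        }

    def bipartitions(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Unrooted bipartitions, normalised away from the smallest leaf."""
        all_leaves = frozenset(self.leaf_labels)
        ref = min(all_leaves)
        below = self._leafset_below()
        out: set[frozenset[str]] = set()
        for node in self._dtree.preorder_node_iter():
            if node.parent_node is None:
                continue
            side = below[node]
            if ref in side:
                side = all_leaves - side
            if len(side) == 0 or len(side) == len(all_leaves):
                continue
            if not include_trivial and (len(side) == 1 or len(side) == len(all_leaves) - 1):
                continue
            out.add(side)
        return out

    # -- operations --------------------------------------------------------

    def restrict_to(self, labels: set[str]) -> "PhyloTree":
        """Prune to the given leaf subset, merging collapsed branch lengths."""
        missing = set(labels) - set(self.leaf_labels)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        dtree = self._dtree.clone(depth=1)
        dtree.retain_taxa_with_labels(sorted(labels))
        dtree.purge_taxon_namespace()
        return PhyloTree(dtree, rooted=self.rooted)

    def is_monophyletic(self, label_set: set[str]) -> bool:
        """True iff some edge's bipartition isolates exactly ``label_set``
        (unrooted convention; singletons and the full leaf set are trivially
        monophyletic)."""
        all_leaves = frozenset(self.leaf_labels)
        query = frozenset(label_set)
        unknown = query - all_leaves
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        if not query:
            raise ValueError("label set must be nonempty")
        if query == all_leaves or len(query) == 1:
            return True
        sides = self.bipartitions(include_trivial=True)
        ref = min(all_leaves)
        norm = (all_leaves - query) if ref in query else query
        return norm in sides


def read_newick(path_or_string: str | Path) -> PhyloTree:
    """Module-level convenience alias for :meth:`PhyloTree.from_newick`."""
    return PhyloTree.from_newick(path_or_string)


def is_monophyletic(tree: PhyloTree, label_set: set[str]) -> bool:
    """Functional form of :meth:`PhyloTree.is_monophyletic`."""
    return tree.is_monophyletic(label_set)


def rf_distance(tree_a: PhyloTree, tree_b: PhyloTree) -> int:
    """Unrooted Robinson-Foulds distance: non-trivial bipartitions present in
    exactly one of the two trees."""
    la, lb = set(tree_a.leaf_labels), set(tree_b.leaf_labels)
    if la != lb:
        only_a, only_b = sorted(la - lb), sorted(lb - la)
        raise ValueError(
            f"leaf sets differ: only in first {only_a}, only in second {only_b}"
        )
    return len(tree_a.bipartitions() ^ tree_b.bipartitions())


def nj_tree(D: "DistanceMatrix") -> PhyloTree:
    """Neighbor joining on the Q-criterion.

    Ties in the Q-criterion are broken by the lexicographically smallest pair
    of cluster representative labels (the minimum leaf label in each cluster).
    Negative branch-length estimates are clamped to 0 with a warning.
    """
    from .distances import DistanceMatrix  # local import avoids a cycle

    if not isinstance(D, DistanceMatrix):
        raise TypeError("nj_tree expects a DistanceMatrix")
    n0 = len(D.labels)
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    mat = np.asarray(D.matrix, dtype=float)
    if not np.allclose(mat, mat.T) or np.isnan(mat).any():
        raise ValueError("distance matrix must be symmetric and NaN-free")

    clamped = False

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    # each active cluster: (representative label, newick subtree string)
    reps = list(D.labels)
    subtrees = list(D.labels)
    d = {
        (i, j): mat[i, j]
        for i in range(n0)
        for j in range(n0)
        if i < j
    }
    active = list(range(n0))
    next_id = n0

    def dist(i: int, j: int) -> float:
        return d[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        n = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * dist(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((reps[i], reps[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = dist(i, j)
        vi_raw = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        vi = _clamp(vi_raw)
        vj = _clamp(dij - vi_raw)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            d[(min(u, k), max(u, k))] = duk
        reps.append(min(reps[i], reps[j]))
        subtrees.append(f"({subtrees[i]}:{vi:.10g},{subtrees[j]}:{vj:.10g})")
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    dij, dik, djk = dist(i, j), dist(i, k), dist(j, k)
    vi = _clamp(0.5 * (dij + dik - djk))
    vj = _clamp(0.5 * (dij + djk - dik))
    vk = _clamp(0.5 * (dik + djk - dij))
    newick = (
        f"({subtrees[i]}:{vi:.10g},{subtrees[j]}:{vj:.10g},{subtrees[k]}:{vk:.10g});"
    )
    if clamped:
        warnings.warn("negative branch-length estimate(s) clamped to 0", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PhyloTree.from_newick(newick, rooted=False)


def root_on_outgroup(tree: PhyloTree, outgroup_labels: set[str] | list[str] | str) -> PhyloTree:
    """Root on the stem edge of the outgroup (at its midpoint).

    Multiple outgroup taxa must form a monophyletic group in the unrooted
    tree; otherwise an error is raised.
    """
    if isinstance(outgroup_labels, str):
        outgroup_labels = {outgroup_labels}
    out = frozenset(outgroup_labels)
    all_leaves = frozenset(tree.leaf_labels)
    missing = out - all_leaves
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")
    if out == all_leaves:
        raise ValueError("outgroup cannot be the whole leaf set")

    work = tree.copy()
    dtree = work._dtree
    below = work._leafset_below()
    target_edge = None
    flip = False
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if below[node] == out:
            target_edge = node.edge
            break
        if below[node] == all_leaves - out:
            target_edge = node.edge
            flip = True
            break
    if target_edge is None:
        raise ValueError(f"outgroup {sorted(out)} is not monophyletic in the tree")

    child = target_edge.head_node
    parent = target_edge.tail_node
    length = target_edge.length if target_edge.length is not None else 1.0
    half = length / 2.0
    new_node = dendropy.Node()
    parent.remove_child(child)
    parent.add_child(new_node)
    new_node.edge.length = half
    new_node.add_child(child)
    child.edge.length = half
    dtree.reseed_at(
        new_node,
        update_bipartitions=False,
        collapse_unrooted_basal_bifurcation=False,
    )
    dtree.suppress_unifurcations()
    dtree.is_rooted = True
    _ = flip  # the stem edge is the same from either side
    return PhyloTree(dtree, rooted=True)
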