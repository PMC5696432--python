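"""Rooted phylogeny container, Newick I/O, node dating and edge-path queries.

Every diversity metric in this package reduces to sums over edges of a
rooted, branch-length-bearing tree: Faith PD is the summed length of the
edges spanning a community and the root, PhyloSorenson compares two such
edge sets, and the endemism metrics down-weight each edge by range size or
abundance.  The :class:`Phylogeny` class therefore stores the tree in flat
arrays indexed by node (edges are identified with their child node), which
makes the edge-set algebra cheap and vectorisable.

Branch lengths are in whatever unit the input tree carries; for trees dated
with :func:`bladj_date` that unit is millions of years (Myr).
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "read_newick",
    "read_calibration",
    "bladj_date",
]


class Phylogeny:
    """A rooted tree with branch lengths, stored as parent-pointer arrays.

    Nodes are integers ``0 .. n_nodes-1`` in preorder (the root is node 0).
    The *edge* above a node is identified with that node; the root has no
    edge and ``lengths[root] == 0``.  Polytomies are allowed everywhere.

    Parameters
    ----------
    parent :
        Integer array, ``parent[v]`` is the parent node of ``v`` and ``-1``
        for the root.  Exactly one root is required.
    lengths :
        Float array of edge lengths (length of the edge above each node,
        ``>= 0``); the root entry is ignored and stored as 0.
    labels :
        Object array of node labels.  Tips must be labelled and tip labels
        must be unique; internal labels are optional (``None``).
    ages :
        Optional float array of node ages (NaN where unknown).  Where both
        parent and child ages are known, parent age must be >= child age.
    """

    __slots__ = (
        "parent",
        "lengths",
        "labels",
        "is_tip",
        "ages",
        "children",
        "_tip_index",
        "_preorder",
        "_postorder",
    )

    def __init__(self, parent, lengths, labels, ages=None):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float).copy()
        self.labels = np.asarray(labels, dtype=object)
        n = self.parent.size
        if self.lengths.size != n or self.labels.size != n:
            raise ValueError("parent, lengths and labels must have equal size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        self.lengths[roots[0]] = 0.0
        if np.any(self.lengths < 0):
            raise ValueError("negative branch length")

        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = self.parent[v]
            if p >= 0:
                self.children[p].append(v)
        self.is_tip = np.fromiter(
            (len(c) == 0 for c in self.children), dtype=bool, count=n
        )

        tip_labels = [self.labels[v] for v in np.flatnonzero(self.is_tip)]
        if any(lbl is None for lbl in tip_labels):
            raise ValueError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            seen, dups = set(), set()
            for lbl in tip_labels:
                (dups if lbl in seen else seen).add(lbl)
            raise ValueError(f"duplicate tip names: {sorted(dups)}")
        self._tip_index = {
            self.labels[v]: int(v) for v in np.flatnonzero(self.is_tip)
        }

        # preorder / postorder via iterative DFS (children in stored order)
        pre, post = [], []
        stack = [(int(roots[0]), False)]
        while stack:
            v, done = stack.pop()
            if done:
                post.append(v)
                continue
            pre.append(v)
            stack.append((v, True))
            for c in reversed(self.children[v]):
                stack.append((c, False))
        self._preorder = np.array(pre, dtype=np.int64)
        self._postorder = np.array(post, dtype=np.int64)

        if ages is None:
            self.ages = None
        else:
            self.ages = np.asarray(ages, dtype=float).copy()
            known = ~np.isnan(self.ages)
            for v in range(n):
                p = self.parent[v]
                if p >= 0 and known[v] and known[p]:
                    if self.ages[p] < self.ages[v] - 1e-9:
                        raise ValueError(
                            f"node {v} is older ({self.ages[v]}) than its "
                            f"parent ({self.ages[p]})"
                        )

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    @property
    def root(self) -> int:
        return int(self._preorder[0])

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_names(self) -> list[str]:
        return [self.labels[v] for v in np.flatnonzero(self.is_tip)]

    @property
    def preorder(self) -> np.ndarray:
        return self._preorder

    @property
    def postorder(self) -> np.ndarray:
        return self._postorder

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def tip_node(self, name: str) -> int:
        try:
            return self._tip_index[name]
        except KeyError:
            raise KeyError(f"unknown taxon: {name!r}") from None

    def node_id(self, v: int) -> str:
        """Label of node ``v``; unlabelled internals get the stable id N<v>."""
        lbl = self.labels[v]
        return lbl if lbl is not None else f"N{v}"

    def depths(self) -> np.ndarray:
        """Distance (sum of edge lengths) from the root to every node."""
        d = np.zeros(self.n_nodes)
        for v in self._preorder[1:]:
            d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    # ------------------------------------------------------------------
    # edge-set queries
    # ------------------------------------------------------------------
    def spanning_edges(self, taxa: Iterable[str]) -> np.ndarray:
        """Edges (child-node ids) on the union of root-to-tip paths.

        The minimum spanning path connecting `taxa` to the root; the stem
        edges between the taxa's MRCA and the root are included.
        """
        taxa = list(taxa)
        if not taxa:
            raise ValueError("taxa set is empty")
        mark = np.zeros(self.n_nodes, dtype=bool)
        for name in taxa:
            v = self.tip_node(name)
            while v >= 0 and not mark[v]:
                mark[v] = True
                v = int(self.parent[v])
        mark[self.root] = False
        return np.flatnonzero(mark)

    def ancestry_matrix(self) -> np.ndarray:
        """Boolean (n_tips, n_nodes) matrix: A[t, v] iff edge v lies on the
        path from tip t to the root (i.e. v is t or an ancestor of t,
        excluding the root)."""
        tips = np.flatnonzero(self.is_tip)
        A = np.zeros((tips.size, self.n_nodes), dtype=bool)
        for row, t in enumerate(tips):
            v = int(t)
            while v >= 0:
                A[row, v] = True
                v = int(self.parent[v])
        A[:, self.root] = False
        return A

    def distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between all pairs of tips.

        Returns the tip names (in tip order) and the symmetric matrix with a
        zero diagonal.  For two tips i, j the distance is
        ``depth(i) + depth(j) - 2 * depth(mrca(i, j))``; the computation
        merges tip groups bottom-up so each pair is assigned exactly once at
        its MRCA.
        """
        tips = np.flatnonzero(self.is_tip)
        row_of = {int(t): r for r, t in enumerate(tips)}
        depth = self.depths()
        tip_depth = depth[tips]
        n = tips.size
        D = np.zeros((n, n))
        groups: dict[int, np.ndarray] = {}
        for v in self._postorder:
            v = int(v)
            if self.is_tip[v]:
                groups[v] = np.array([row_of[v]], dtype=np.int64)
                continue
            kid_groups = [groups.pop(c) for c in self.children[v]]
            for i in range(len(kid_groups)):
                for j in range(i + 1, len(kid_groups)):
                    a, b = kid_groups[i], kid_groups[j]
                    d = (
                        tip_depth[a][:, None]
                        + tip_depth[b][None, :]
                        - 2.0 * depth[v]
                    )
                    D[np.ix_(a, b)] = d
                    D[np.ix_(b, a)] = d.T
            groups[v] = np.concatenate(kid_groups)
        names = [self.labels[t] for t in tips]
        return names, D

    def mrca(self, taxa: Iterable[str]) -> int:
        """Most recent common ancestor node of the given tips."""
        nodes = [self.tip_node(t) for t in taxa]
        if not nodes:
            raise ValueError("taxa set is empty")
        paths = []
        for v in nodes:
            path = []
            while v >= 0:
                path.append(v)
                v = int(self.parent[v])
            paths.append(path[::-1])
        k = 0
        while all(len(p) > k for p in paths) and len({p[k] for p in paths}) == 1:
            k += 1
        return paths[0][k - 1]

    # ------------------------------------------------------------------
    # pruning
    # ------------------------------------------------------------------
    def prune_to(self, taxa: Iterable[str], keep_root: bool = True) -> "Phylogeny":
        """Prune the tree down to the given tips.

        Internal nodes left with a single child are suppressed (their edge
        lengths summed) so path lengths between retained nodes are
        preserved.  With ``keep_root=True`` the original root is retained
        even if it ends up with one child, so root-to-tip path lengths are
        unchanged; with ``keep_root=False`` the new root is the MRCA of the
        retained tips.
        """
        keep = set(taxa)
        if not keep:
            raise ValueError("taxa set is empty")
        unknown = keep - set(self._tip_index)
        if unknown:
            raise KeyError(f"unknown taxa: {sorted(unknown)}")

        # (parent_new, length, label, age) accumulated in preorder
        parent_new: list[int] = []
        lengths_new: list[float] = []
        labels_new: list[object] = []
        ages_new: list[float] = []
        have_ages = self.ages is not None

        retained = np.zeros(self.n_nodes, dtype=bool)
        for t in keep:
            v = self.tip_node(t)
            while v >= 0 and not retained[v]:
                retained[v] = True
                v = int(self.parent[v])

        def n_kept_children(v: int) -> int:
            return sum(retained[c] for c in self.children[v])

        def emit(v: int, parent_idx: int, acc_len: float) -> None:
            # follow chains of single-kept-child internals
            while (not self.is_tip[v]) and n_kept_children(v) == 1 and not (
                parent_idx == -1 and keep_root and v == self.root
            ):
                (c,) = [c for c in self.children[v] if retained[c]]
                acc_len += self.lengths[c]
                v = c
            idx = len(parent_new)
            parent_new.append(parent_idx)
            lengths_new.append(acc_len)
            labels_new.append(self.labels[v])
            if have_ages:
                ages_new.append(self.ages[v])
            for c in self.children[v]:
                if retained[c]:
                    emit(c, idx, self.lengths[c])

        if keep_root:
            start = self.root
        else:
            start = self.mrca(keep)
        emit(start, -1, 0.0)
        return Phylogeny(
            parent_new,
            lengths_new,
            labels_new,
            ages=np.array(ages_new) if have_ages else None,
        )

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        labels = np.empty(n, dtype=object)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                lbl = nd.taxon.label if nd.taxon is not None else nd.label
                if lbl is None:
                    raise ValueError("unlabelled tip in newick input")
                labels[i] = lbl.replace(" ", "_")
            else:
                lbl = nd.label
                if lbl is None and nd.taxon is not None:
                    lbl = nd.taxon.label
                labels[i] = lbl.replace(" ", "_") if lbl is not None else None
        return cls(parent, lengths, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            nd = dnodes[v]
            if self.is_tip[v]:
                nd.taxon = taxa.new_taxon(label=self.labels[v])
            elif self.labels[v] is not None:
                nd.label = self.labels[v]
            if self.parent[v] >= 0:
                nd.edge.length = float(self.lengths[v])
        for v in range(self.n_nodes):
            for c in self.children[v]:
                dnodes[v].add_child(dnodes[c])
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = dnodes[self.root]
        return tree

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip() + ("" if s.strip().endswith(";") else ";")

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes, "
            f"total length {self.total_length:.4g}>"
        )


def read_newick(source) -> Phylogeny:
    """Read a single rooted tree from a Newick string, path or file object.

    Underscores in labels are preserved; spaces inside quoted labels are
    converted to underscores so tip names match community-table headers.
    """
    if isinstance(source, str) and ("(" in source or ";" in source):
        data = source
    elif hasattr(source, "read"):
        data = source.read()
    else:
        with open(source) as fh:
            data = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=data,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise ValueError(f"duplicate tip names in newick: {exc}") from exc
        raise ValueError(f"malformed newick: {exc}") from exc
    return Phylogeny.from_dendropy(dtree)


# ----------------------------------------------------------------------
# node dating
# ----------------------------------------------------------------------
def read_calibration(source) -> dict[str, float]:
    """Read a 2-column CSV (node_label, age_Myr) into a calibration map."""
    import pandas as pd

    df = pd.read_csv(source)
    if df.shape[1] < 2:
        raise ValueError("calibration table needs two columns: label, age")
    calib = {}
    for lbl, age in zip(df.iloc[:, 0], df.iloc[:, 1]):
        age = float(age)
        if age < 0:
            raise ValueError(f"negative calibration age for {lbl!r}")
        calib[str(lbl)] = age
    return calib


def bladj_date(tree: Phylogeny, calibration: Mapping[str, float]) -> Phylogeny:
    """Assign node ages by even interpolation between calibrated nodes.

    Re-implements the branch-length adjustment used by Phylocom's BLADJ:
    calibrated node ages (plus tip ages of zero) are fixed, and every
    undated node is placed evenly, in age, between its nearest dated
    ancestor and the first dated node or tip below it; branch lengths are
    then recomputed as parent age minus child age.  Existing branch lengths
    are ignored — only the node counts along each path matter.

    The root must be calibrated.  Traversal is depth-first from the root in
    child order, so dated nodes high in the tree anchor interpolation before
    deeper ones; where a branching undated node lies on several paths, the
    first path visited fixes its age and later paths interpolate around it.

    Raises ``ValueError`` for an uncalibrated root, a calibration that
    violates ancestry order, or labels that match no node.
    """
    n = tree.n_nodes
    ages = np.full(n, np.nan)
    fixed = np.zeros(n, dtype=bool)

    by_label: dict[str, int] = {}
    for v in range(n):
        by_label.setdefault(tree.node_id(v), int(v))
    for lbl, age in calibration.items():
        if lbl not in by_label:
            raise ValueError(f"calibration label {lbl!r} matches no node")
        v = by_label[lbl]
        if float(age) < 0:
            raise ValueError(f"negative age for node {lbl!r}")
        ages[v] = float(age)
        fixed[v] = True
    for v in np.flatnonzero(tree.is_tip):
        if not fixed[v]:
            ages[v] = 0.0
            fixed[v] = True

    root = tree.root
    if not fixed[root]:
        raise ValueError("root age must be calibrated")

    # ancestry-order check among calibrated nodes
    for v in range(n):
        if not fixed[v]:
            continue
        p = int(tree.parent[v])
        while p >= 0:
            if fixed[p]:
                if ages[p] < ages[v] - 1e-12:
                    raise ValueError(
                        f"calibration violates ancestry: node {tree.node_id(v)} "
                        f"({ages[v]}) older than ancestor {tree.node_id(p)} "
                        f"({ages[p]})"
                    )
                break
            p = int(tree.parent[p])

    def interpolate(anchor: int, terminal: int, chain: list[int]) -> None:
        """Spread ages along anchor -> chain -> terminal, segment-wise
        between already-fixed elements so first assignments win."""
        seq = [anchor] + chain + [terminal]
        seg_start = 0
        for k in range(1, len(seq)):
            if fixed[seq[k]]:
                a, b = seq[seg_start], seq[k]
                gap = k - seg_start
                for j in range(1, gap):
                    m = seq[seg_start + j]
                    ages[m] = ages[a] + (ages[b] - ages[a]) * j / gap
                    fixed[m] = True
                seg_start = k

    def chase(v: int, anchor: int, chain: list[int]) -> None:
        if fixed[v]:
            interpolate(anchor, v, chain)
            for c in tree.children[v]:
                chase(c, v, [])
        else:
            for c in tree.children[v]:
                chase(c, anchor, chain + [v])

    for c in tree.children[root]:
        chase(c, root, [])

    new_lengths = np.zeros(n)
    for v in range(n):
        p = int(tree.parent[v])
        if p >= 0:
            L = ages[p] - ages[v]
            if L < -1e-9:
                raise ValueError(
                    "interpolated ages inconsistent with calibration "
                    f"(negative branch above node {tree.node_id(v)})"
                )
            new_lengths[v] = max(L, 0.0)
    return Phylogeny(tree.parent, new_lengths, tree.labels, ages=ages)
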