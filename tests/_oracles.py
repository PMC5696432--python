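"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's edge-set algebra: they operate on
dendropy node objects with naive descendant-set logic, so agreement with
the package is a genuine dual-route check rather than a re-run of the same
code.
"""

from __future__ import annotations

import dendropy


def parse(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def _tips_under(nd) -> set[str]:
    return {leaf.taxon.label for leaf in nd.leaf_iter()}


def edge_table(tree: dendropy.Tree):
    """(length, descendant-tip-set) for every non-root edge."""
    out = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        out.append((nd.edge.length or 0.0, _tips_under(nd)))
    return out


def pd_oracle(tree: dendropy.Tree, taxa: set[str]) -> float:
    """Faith PD by marking every edge with a descendant in the set."""
    return sum(L for L, desc in edge_table(tree) if desc & taxa)


def phylosor_oracle(tree: dendropy.Tree, set1: set[str], set2: set[str]) -> float:
    """1 - PhyloSorenson from explicit edge sets."""
    bl1 = bl2 = shared = 0.0
    for L, desc in edge_table(tree):
        in1 = bool(desc & set1)
        in2 = bool(desc & set2)
        bl1 += L * in1
        bl2 += L * in2
        shared += L * (in1 and in2)
    return 1.0 - 2.0 * shared / (bl1 + bl2)


def wpe_oracle(
    tree: dendropy.Tree, plot_sets: dict[str, set[str]], plot: str
) -> float:
    """Weighted phylogenetic endemism with naive per-edge occupancy counts."""
    target = plot_sets[plot]
    total = 0.0
    for L, desc in edge_table(tree):
        if not desc & target:
            continue
        r = sum(1 for s in plot_sets.values() if desc & s)
        total += L / r
    return total


def aed_oracle(tree: dendropy.Tree, abund: dict[str, float]) -> dict[str, float]:
    """Per-species AED by walking each leaf-to-root path."""
    present = {s for s, n in abund.items() if n > 0}
    out = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name not in present:
            continue
        total = 0.0
        nd = leaf
        while nd.parent_node is not None:
            n_e = sum(abund.get(t, 0) for t in _tips_under(nd) if t in present)
            total += (nd.edge.length or 0.0) / n_e
            nd = nd.parent_node
        out[name] = total
    return out


def iac_oracle(tree: dendropy.Tree, abund: dict[str, float]) -> float:
    """Imbalance of abundances via recursive even splitting among the
    children that retain present descendants (implicit pruning)."""
    present = {s for s, n in abund.items() if n > 0}
    N = float(sum(abund[s] for s in present))
    expected: dict[str, float] = {}
    splits = [0]

    def has_present(nd) -> bool:
        return bool(_tips_under(nd) & present)

    def rec(nd, share: float) -> None:
        if nd.is_leaf():
            expected[nd.taxon.label] = share * N
            return
        kids = [c for c in nd.child_nodes() if has_present(c)]
        if len(kids) >= 2:
            splits[0] += 1
            for c in kids:
                rec(c, share / len(kids))
        else:
            for c in kids:
                rec(c, share)

    rec(tree.seed_node, 1.0)
    if splits[0] == 0:
        return 0.0
    dev = sum(abs(abund[s] - expected[s]) for s in present)
    return dev / splits[0]


def patristic_oracle(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """All pairwise tip distances via dendropy's own distance matrix."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            d = pdm.patristic_distance(t1, t2)
            out[(t1.label, t2.label)] = d
            out[(t2.label, t1.label)] = d
    return out
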