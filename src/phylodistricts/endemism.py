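"""Phylogenetic endemism, evolutionary distinctiveness and clade imbalance.

Three complementary per-plot summaries of how branch length and abundance
are distributed over a community:

* **WPE** (weighted phylogenetic endemism) — Faith PD with each edge
  down-weighted by the geographic range of its subtended clade:
  ``WPE(plot) = sum over spanning edges e of lambda_e / R_e`` where ``R_e``
  counts the spatial units (plots, or grid cells) occupied by any species
  descending from e.  High values flag concentrations of range-restricted
  lineages.  Units: Myr per range-unit.

* **AED** (abundance-weighted evolutionary distinctiveness) — each edge's
  length is split equally among the individuals descending from it inside
  the plot: ``AED_i = sum over edges e on the root path of species i of
  lambda_e / n_e`` with ``n_e`` the plot abundance under e.  Because every
  edge is partitioned across exactly its ``n_e`` individuals,
  ``sum_i n_i * AED_i`` recovers the plot's Faith PD exactly — the primary
  correctness identity for this metric.  Units: Myr per individual.

* **IAC** (imbalance of abundances at clade level) — mean absolute
  deviation of species abundances from the null expectation that the
  plot's N individuals split evenly at every node of the plot-pruned tree:
  ``n_hat_i = N * prod over splits k on the root path of (1 / d_k)`` with
  ``d_k`` the number of daughter lineages at k, and
  ``IAC = sum_i |n_i - n_hat_i| / v`` over the v split nodes.  Polytomies
  split 1/d_k.  IAC = 0 iff abundances match the even-split expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .spatial import GridSpec
from .tree import Phylogeny

__all__ = [
    "clade_ranges",
    "weighted_phylogenetic_endemism",
    "aed",
    "aed_table",
    "iac",
    "endemism_table",
]


def _tip_rows(tree: Phylogeny, species: list[str]) -> list[int]:
    tip_row = {tree.labels[t]: r for r, t in enumerate(np.flatnonzero(tree.is_tip))}
    try:
        return [tip_row[s] for s in species]
    except KeyError as exc:
        raise KeyError(f"species not in tree: {exc.args[0]!r}") from None


def clade_ranges(
    tree: Phylogeny,
    cm: CommunityMatrix,
    unit: str = "plots",
    coords: pd.DataFrame | None = None,
    grid: GridSpec | None = None,
) -> np.ndarray:
    """Geographic range size R_e of the clade subtending each edge.

    Returns an array indexed by node id (edge = node above which it hangs);
    R_e is the number of distinct spatial units containing at least one
    individual of any tip descending from edge e.  Units are plots
    (default) or 0.5-degree grid cells (``unit="grid-cells"``, requiring
    plot coordinates).  R_e is monotonically non-decreasing root-ward.
    """
    if unit not in ("plots", "grid-cells"):
        raise ValueError("unit must be 'plots' or 'grid-cells'")
    P = cm.presence()
    if unit == "grid-cells":
        if coords is None:
            raise ValueError("grid-cell ranges require plot coordinates")
        grid = grid or GridSpec.from_points(
            coords["lon"].to_numpy(), coords["lat"].to_numpy()
        )
        cells = [
            grid.assign_cell(coords.loc[p, "lon"], coords.loc[p, "lat"])
            for p in cm.plot_ids
        ]
        cell_ids = sorted(set(cells))
        cell_row = {c: i for i, c in enumerate(cell_ids)}
        U = np.zeros((len(cell_ids), P.shape[1]), dtype=np.uint8)
        for p_idx, cell in enumerate(cells):
            U[cell_row[cell]] |= P[p_idx]
    else:
        U = P
    A = tree.ancestry_matrix()[_tip_rows(tree, cm.species)]
    occupied = (U.astype(np.float64) @ A.astype(np.float64)) > 0.5
    return occupied.sum(axis=0).astype(np.int64)


def weighted_phylogenetic_endemism(
    tree: Phylogeny, cm: CommunityMatrix, ranges: np.ndarray | None = None
) -> pd.Series:
    """WPE per plot: spanning branch lengths down-weighted by clade range.

    With every range equal to 1 (a single-plot landscape) WPE reduces to
    Faith PD, and WPE <= PD always since R_e >= 1 on spanning edges.
    """
    if ranges is None:
        ranges = clade_ranges(tree, cm)
    ranges = np.asarray(ranges)
    out = {}
    for plot in cm.plot_ids:
        edges = tree.spanning_edges(cm.plot_species(plot))
        r = ranges[edges]
        if np.any(r < 1):
            raise ValueError("range table does not cover all spanning edges")
        out[plot] = float((tree.lengths[edges] / r).sum())
    return pd.Series(out, name="WPE").rename_axis("plot_id")


def aed(tree: Phylogeny, cm: CommunityMatrix, plot_id: str) -> pd.Series:
    """AED per species present in one plot (Myr per individual)."""
    abund = cm.plot_abundances(plot_id)
    if abund.empty:
        raise ValueError(f"plot {plot_id!r} has no individuals")
    rows = _tip_rows(tree, list(abund.index))
    A = tree.ancestry_matrix()
    n_e = abund.to_numpy(dtype=float) @ A[rows]  # individuals under each edge
    out = {}
    for sp, row in zip(abund.index, rows):
        path = np.flatnonzero(A[row])
        out[sp] = float((tree.lengths[path] / n_e[path]).sum())
    return pd.Series(out, name="AED").rename_axis("species")


def aed_table(tree: Phylogeny, cm: CommunityMatrix) -> pd.DataFrame:
    """Long-format AED for all plots: plot_id, species, abundance, AED."""
    frames = []
    for plot in cm.plot_ids:
        s = aed(tree, cm, plot)
        ab = cm.plot_abundances(plot)
        frames.append(
            pd.DataFrame(
                {
                    "plot_id": plot,
                    "species": s.index,
                    "abundance": ab.loc[s.index].to_numpy(),
                    "AED": s.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def iac(tree: Phylogeny, cm: CommunityMatrix, plot_id: str) -> float:
    """Imbalance of abundances at clade level for one plot.

    Computed on the tree pruned to the plot's species; nodes with a single
    retained child contribute no split (factor 1), and the split count v
    includes only nodes with >= 2 daughters.
    """
    abund = cm.plot_abundances(plot_id)
    if abund.empty:
        raise ValueError(f"plot {plot_id!r} has no individuals")
    N = float(abund.sum())
    pruned = tree.prune_to(list(abund.index), keep_root=True)
    if pruned.n_tips == 1:
        # no splits: the single species is expected to hold all N
        return 0.0
    n_children = np.array([len(c) for c in pruned.children])
    split = n_children >= 2
    v = int(split.sum())
    expected = {}
    frac = np.ones(pruned.n_nodes)
    for vtx in pruned.preorder:
        p = pruned.parent[vtx]
        if p < 0:
            frac[vtx] = 1.0
        else:
            frac[vtx] = frac[p] / (n_children[p] if split[p] else 1.0)
        if pruned.is_tip[vtx]:
            expected[pruned.labels[vtx]] = N * frac[vtx]
    dev = sum(abs(float(abund[sp]) - expected[sp]) for sp in abund.index)
    return float(dev / v)


@dataclass
class EndemismTables:
    per_plot: pd.DataFrame  # plot_id -> WPE, IAC
    per_species: pd.DataFrame  # plot_id, species, abundance, AED


def endemism_table(
    tree: Phylogeny,
    cm: CommunityMatrix,
    unit: str = "plots",
    coords: pd.DataFrame | None = None,
    grid: GridSpec | None = None,
) -> EndemismTables:
    """All endemism/distinctiveness metrics for an aligned tree and matrix."""
    ranges = clade_ranges(tree, cm, unit=unit, coords=coords, grid=grid)
    wpe = weighted_phylogenetic_endemism(tree, cm, ranges)
    iac_vals = pd.Series(
        {p: iac(tree, cm, p) for p in cm.plot_ids}, name="IAC"
    ).rename_axis("plot_id")
    per_plot = pd.concat([wpe, iac_vals], axis=1)
    return EndemismTables(per_plot=per_plot, per_species=aed_table(tree, cm))
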