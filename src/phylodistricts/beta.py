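"""Pairwise taxonomic and phylogenetic dissimilarity and their null models.

Taxonomic beta diversity (TBD) is 1 - Sorenson: for two plots sharing `a`
species with `b` and `c` unique to each, TBD = 1 - 2a/(2a+b+c).  The
phylogenetic analogue (PBD, 1 - PhyloSorenson) replaces shared species
counts with shared branch length: each plot spans a set of edges between
its species and the root, and PBD = 1 - 2*BL_shared / (BL_1 + BL_2).
Both indices are incidence-based.

The null expectation of PBD randomizes the presence/absence matrix with
the independent-swap algorithm (occurrence frequencies and plot richness
held fixed) once per replicate, so all plot pairs share each replicate and
the joint co-occurrence structure of the null is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .alpha import independent_swap
from .community import CommunityMatrix
from .tree import Phylogeny

__all__ = [
    "DissimilarityMatrix",
    "sorenson_matrix",
    "bray_curtis_matrix",
    "phylosor_matrix",
    "null_phylosor",
    "NullPhyloSorResult",
    "mean_row_dissimilarity",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric plot-by-plot dissimilarity in [0, 1] with a metric label."""

    values: np.ndarray
    plot_ids: list[str]
    label: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if v.shape[0] != len(self.plot_ids):
            raise ValueError("plot_ids length does not match matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("dissimilarity diagonal must be zero")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("dissimilarities must lie in [0, 1]")
        v = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.plot_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.plot_ids, columns=self.plot_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="plot_id")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str) -> "DissimilarityMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), label)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DissimilarityMatrix {self.label} {self.n}x{self.n}>"


def _require_plots(cm: CommunityMatrix) -> None:
    if len(cm.plot_ids) < 2:
        raise ValueError("need at least two plots")


def sorenson_matrix(cm: CommunityMatrix) -> DissimilarityMatrix:
    """Taxonomic dissimilarity (1 - Sorenson), presence-based."""
    _require_plots(cm)
    P = cm.presence().astype(bool)
    # Dice dissimilarity == (b+c)/(2a+b+c) == 1 - Sorenson similarity
    d = pdist(P, metric="dice")
    return DissimilarityMatrix(squareform(d), cm.plot_ids, "TBD")


def bray_curtis_matrix(cm: CommunityMatrix) -> DissimilarityMatrix:
    """Abundance-based Bray-Curtis dissimilarity (not an incidence index;
    provided as a labelled extra alongside the Sorenson family)."""
    _require_plots(cm)
    d = pdist(cm.counts.astype(float), metric="braycurtis")
    return DissimilarityMatrix(squareform(d), cm.plot_ids, "BrayCurtis")


def _edge_incidence(tree: Phylogeny, cm: CommunityMatrix) -> np.ndarray:
    """Boolean (plots x nodes) matrix: plot spans the edge above each node."""
    A = tree.ancestry_matrix()
    tip_row = {tree.labels[t]: r for r, t in enumerate(np.flatnonzero(tree.is_tip))}
    try:
        rows = [tip_row[s] for s in cm.species]
    except KeyError as exc:
        raise KeyError(f"species not in tree: {exc.args[0]!r}") from None
    return _presence_to_edges(cm.presence(), A[rows])


def _presence_to_edges(P: np.ndarray, Atips: np.ndarray) -> np.ndarray:
    return (P.astype(np.float32) @ Atips.astype(np.float32)) > 0.5


def _phylosor_from_edges(E: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    W = E * lengths[None, :]
    bl = W.sum(axis=1)
    shared = W @ E.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 2.0 * shared / (bl[:, None] + bl[None, :])
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def phylosor_matrix(tree: Phylogeny, cm: CommunityMatrix) -> DissimilarityMatrix:
    """Phylogenetic dissimilarity (1 - PhyloSorenson) between all plot pairs.

    Plot branch lengths include the stem path to the root, consistent with
    the rooted Faith PD used for alpha diversity.
    """
    _require_plots(cm)
    E = _edge_incidence(tree, cm)
    d = _phylosor_from_edges(E, tree.lengths)
    return DissimilarityMatrix(d, cm.plot_ids, "PBD")


@dataclass
class NullPhyloSorResult:
    """Observed PBD against its independent-swap null distribution."""

    observed: DissimilarityMatrix
    expected: DissimilarityMatrix
    deviation: np.ndarray  # observed - expected
    quantiles: np.ndarray  # +1-corrected rank of observed within the null
    n_null: int

    def deviation_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.deviation,
            index=self.observed.plot_ids,
            columns=self.observed.plot_ids,
        )


def null_phylosor(
    tree: Phylogeny,
    cm: CommunityMatrix,
    n_null: int = 999,
    seed: int | None = None,
    swaps_per_presence: int = 10,
) -> NullPhyloSorResult:
    """Expected PBD under random draws from the regional pool.

    Each of the ``n_null`` replicates swaps the full presence/absence
    matrix in an independent chain burnt in from the observed matrix, then
    recomputes the whole PhyloSorenson matrix.  Observed minus expected
    deviations below zero mean plot pairs share more branch length than
    random draws with the same richness and occupancy would; above zero,
    less.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    observed = phylosor_matrix(tree, cm)

    A = tree.ancestry_matrix()
    tip_row = {tree.labels[t]: r for r, t in enumerate(np.flatnonzero(tree.is_tip))}
    Atips = A[[tip_row[s] for s in cm.species]]
    P = cm.presence()
    n_swaps = int(swaps_per_presence * P.sum())
    seeds = np.random.SeedSequence(seed).generate_state(n_null)

    total = np.zeros_like(observed.values)
    le_count = np.zeros_like(observed.values)
    for k in range(n_null):
        Pk, _ = independent_swap(P, n_swaps, seed=int(seeds[k]))
        Ek = _presence_to_edges(Pk, Atips)
        dk = _phylosor_from_edges(Ek, tree.lengths)
        total += dk
        le_count += dk <= observed.values
    expected_vals = total / n_null
    np.fill_diagonal(expected_vals, 0.0)
    expected = DissimilarityMatrix(expected_vals, cm.plot_ids, "nullPBD")
    quantiles = (le_count + 1.0) / (n_null + 1.0)
    np.fill_diagonal(quantiles, np.nan)
    return NullPhyloSorResult(
        observed=observed,
        expected=expected,
        deviation=observed.values - expected.values,
        quantiles=quantiles,
        n_null=n_null,
    )


def mean_row_dissimilarity(D: DissimilarityMatrix) -> pd.Series:
    """Mean dissimilarity of each plot to every other plot.

    This per-plot summary is the quantity interpolated across the region
    by the spatial module.
    """
    if D.n < 2:
        raise ValueError("need at least two plots")
    sums = D.values.sum(axis=1)
    means = sums / (D.n - 1)
    return pd.Series(means, index=pd.Index(D.plot_ids, name="plot_id"),
                     name=f"mean_{D.label}")
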