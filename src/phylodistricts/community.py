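"""Community-matrix and coordinate handling, reconciliation, Fisher's alpha.

The community matrix is a plots-by-species table of integer stem counts
(trees with dbh >= 10 cm in the motivating design).  Rows are plots,
columns are species; a plot's total N and richness S drive Fisher's alpha,
and the presence/absence reduction of the matrix drives the incidence-based
beta-diversity and null-model machinery.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .tree import Phylogeny

__all__ = [
    "CommunityMatrix",
    "read_community",
    "read_coordinates",
    "filter_morphospecies",
    "align_tree_matrix",
    "AlignmentReport",
    "fisher_alpha",
]


@dataclass
class CommunityMatrix:
    """Plots x species abundance counts backed by a pandas DataFrame."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate plot IDs: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species names: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("community matrix must be numeric")
        if np.any(values < 0):
            raise ValueError("negative abundance")
        if np.any(values != np.round(values)):
            bad = np.argwhere(values != np.round(values))[0]
            raise ValueError(
                f"non-integer abundance at plot {df.index[bad[0]]!r}, "
                f"species {df.columns[bad[1]]!r}"
            )
        self.data = df.astype(np.int64)
        self.data.index = self.data.index.rename("plot_id")
        empty = self.totals == 0
        if empty.any():
            plots = list(self.data.index[empty])
            raise ValueError(f"plot has zero individuals: {plots}")

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def totals(self) -> np.ndarray:
        """Individuals per plot (N)."""
        return self.data.to_numpy().sum(axis=1)

    @property
    def richness(self) -> np.ndarray:
        """Species per plot (S)."""
        return (self.data.to_numpy() > 0).sum(axis=1)

    def presence(self) -> np.ndarray:
        """Binary (plots x species) occurrence matrix as uint8."""
        return (self.data.to_numpy() > 0).astype(np.uint8)

    def plot_species(self, plot_id: str) -> list[str]:
        row = self.data.loc[plot_id]
        return list(row.index[row > 0])

    def plot_abundances(self, plot_id: str) -> pd.Series:
        row = self.data.loc[plot_id]
        return row[row > 0]

    def subset_species(self, species: list[str]) -> "CommunityMatrix":
        return CommunityMatrix(self.data.loc[:, species].copy())

    def to_csv(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index_label="plot_id")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CommunityMatrix {len(self.plot_ids)} plots x "
            f"{len(self.species)} species>"
        )


def read_community(source, sep: str | None = None) -> CommunityMatrix:
    """Read a plots-x-species count table (CSV or TSV, first column = plot id).

    Blank cells become zeros.  Non-integer cells and duplicate plot ids are
    errors (reported with their position).
    """
    if sep is None:
        sep_opts = dict(sep=None, engine="python")
    else:
        sep_opts = dict(sep=sep)
    df = pd.read_csv(source, index_col=0, **sep_opts)
    df = df.fillna(0)
    return CommunityMatrix(df)


def read_coordinates(source) -> pd.DataFrame:
    """Read plot coordinates (plot_id, lon, lat in WGS84 decimal degrees)."""
    df = pd.read_csv(source)
    cols = {c.lower(): c for c in df.columns}
    try:
        df = df.rename(
            columns={cols["plot_id"]: "plot_id", cols["lon"]: "lon", cols["lat"]: "lat"}
        )
    except KeyError:
        raise ValueError("coordinates file needs columns plot_id, lon, lat")
    df = df.set_index("plot_id")[["lon", "lat"]].astype(float)
    if df.index.duplicated().any():
        raise ValueError("duplicate plot IDs in coordinates")
    if (df["lon"].abs() > 180).any() or (df["lat"].abs() > 90).any():
        raise ValueError("coordinates outside WGS84 bounds")
    return df


_DEFAULT_MORPHO = re.compile(r"(?:sp[._]|indet)", flags=re.IGNORECASE)


def filter_morphospecies(
    cm: CommunityMatrix, pattern: str | re.Pattern = _DEFAULT_MORPHO
) -> tuple[CommunityMatrix, list[str]]:
    """Drop unnamed-morphospecies columns whose name matches `pattern`.

    Which names count as morphospecies is dataset-dependent, so the pattern
    is configurable; the default catches the usual "Genus sp.1" and
    "indet" placeholders.
    """
    rx = re.compile(pattern) if isinstance(pattern, str) else pattern
    dropped = [s for s in cm.species if rx.search(s)]
    kept = [s for s in cm.species if s not in dropped]
    if not kept:
        raise ValueError("morphospecies filter removed every species")
    return CommunityMatrix(cm.data.loc[:, kept].copy()), dropped


@dataclass
class AlignmentReport:
    """Species dropped from the matrix and tips pruned from the tree."""

    dropped_species: list[str] = field(default_factory=list)
    pruned_tips: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.dropped_species and not self.pruned_tips


def align_tree_matrix(
    tree: Phylogeny, cm: CommunityMatrix
) -> tuple[Phylogeny, CommunityMatrix, AlignmentReport]:
    """Reconcile a phylogeny and a community matrix onto a shared species set.

    Species absent from the tree are dropped from the matrix; tips absent
    from the matrix are pruned from the tree (the original root is kept so
    root-to-tip path lengths are unchanged).  Raises if the intersection is
    empty or if dropping species empties a plot.
    """
    tree_tips = set(tree.tip_names)
    matrix_sp = set(cm.species)
    shared = tree_tips & matrix_sp
    if not shared:
        raise ValueError("tree and community matrix share no species")
    report = AlignmentReport(
        dropped_species=sorted(matrix_sp - tree_tips),
        pruned_tips=sorted(tree_tips - matrix_sp),
    )
    new_cm = cm
    if report.dropped_species:
        kept = [s for s in cm.species if s in shared]
        new_cm = CommunityMatrix(cm.data.loc[:, kept].copy())
    new_tree = tree
    if report.pruned_tips:
        new_tree = tree.prune_to(shared, keep_root=True)
    return new_tree, new_cm, report


def fisher_alpha(S: float, N: float) -> float:
    """Invert the log-series species-individuals relation S = a*ln(1 + N/a).

    Fisher's alpha is the diversity parameter of the log-series abundance
    model; it is the unique positive root of the relation above.  S(a) is
    strictly increasing in a, so bracketed root-finding on [1e-6, 1e8]
    followed by a Newton polish is safe and accurate to |residual| < 1e-9.
    Requires 1 <= S < N; at S = N the relation has no finite solution.
    """
    S = float(S)
    N = float(N)
    if S < 1:
        raise ValueError("need at least one species")
    if S >= N:
        raise ValueError("no finite alpha: S must be < N")

    def f(a):
        return a * np.log1p(N / a) - S

    lo, hi = 1e-6, 1e8
    if f(hi) < 0:
        raise ValueError("alpha out of bracket range")
    alpha = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    # Newton polish for |residual| < 1e-9
    for _ in range(3):
        r = alpha * np.log1p(N / alpha) - S
        if abs(r) < 1e-12:
            break
        dr = np.log1p(N / alpha) - N / (alpha + N)
        alpha -= r / dr
    return float(alpha)
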