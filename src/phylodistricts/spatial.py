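"""0.5-degree gridding and Loess surface interpolation of per-plot metrics.

Plot networks never cover a region wall-to-wall, so per-plot summaries
(mean dissimilarity, WPE, IAC, ...) are carried onto a regular grid by
locally weighted polynomial regression (Loess): at each cell centre the
nearest ``ceil(span * n)`` plots are fit with a weighted degree-2
polynomial in (lon, lat) under tricube weights, and the fitted value at
the centre is the cell's prediction.  Distances are Euclidean in raw
degrees — the intended study windows span a few degrees near the equator,
where the planar approximation is tolerable.

Cells whose centres fall outside the convex hull of the plots are still
predicted (the method extrapolates smoothly) but carry an
``extrapolated`` flag so downstream maps can be honest about them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "loess_predict",
    "LoessFit",
    "interpolate_metric_surface",
    "GridSurface",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid: cell index = floor(coordinate / cell_size).

    Cells are half-open: a point exactly on an edge belongs to the cell on
    its upper-right side.  Anchoring is at integer multiples of the cell
    size (not data-driven).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_size: float = 0.5

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("degenerate bounding box")

    @classmethod
    def from_points(
        cls, lon: np.ndarray, lat: np.ndarray, cell_size: float = 0.5
    ) -> "GridSpec":
        """Smallest grid-aligned box containing the points."""
        cs = cell_size
        return cls(
            lon_min=math.floor(np.min(lon) / cs) * cs,
            lon_max=math.floor(np.max(lon) / cs) * cs + cs,
            lat_min=math.floor(np.min(lat) / cs) * cs,
            lat_max=math.floor(np.max(lat) / cs) * cs + cs,
            cell_size=cs,
        )

    def assign_cell(self, lon: float, lat: float) -> tuple[int, int]:
        if not (self.lon_min <= lon <= self.lon_max) or not (
            self.lat_min <= lat <= self.lat_max
        ):
            raise ValueError(f"coordinate ({lon}, {lat}) outside bounding box")
        return (
            int(math.floor(lon / self.cell_size)),
            int(math.floor(lat / self.cell_size)),
        )

    def cell_center(self, ix: int, iy: int) -> tuple[float, float]:
        return (
            (ix + 0.5) * self.cell_size,
            (iy + 0.5) * self.cell_size,
        )

    def cells(self) -> list[tuple[int, int]]:
        """All cells whose centres lie inside the bounding box."""
        eps = 1e-9
        ix0 = int(math.floor((self.lon_min + eps) / self.cell_size))
        ix1 = int(math.ceil((self.lon_max - eps) / self.cell_size))
        iy0 = int(math.floor((self.lat_min + eps) / self.cell_size))
        iy1 = int(math.ceil((self.lat_max - eps) / self.cell_size))
        out = []
        for ix in range(ix0, ix1):
            for iy in range(iy0, iy1):
                cx, cy = self.cell_center(ix, iy)
                if self.lon_min <= cx <= self.lon_max and self.lat_min <= cy <= self.lat_max:
                    out.append((ix, iy))
        return out


def assign_grid_cell(lon: float, lat: float, spec: GridSpec) -> tuple[int, int]:
    """Functional alias for :meth:`GridSpec.assign_cell`."""
    return spec.assign_cell(lon, lat)


@dataclass
class LoessFit:
    value: float
    degree_used: int  # 2, 1, or 0 (weighted mean fallback)
    fallback: bool


def _design(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(x)]
    if degree >= 1:
        cols += [x, y]
    if degree >= 2:
        cols += [x * x, x * y, y * y]
    return np.column_stack(cols)


def loess_predict(
    points: np.ndarray,
    values: np.ndarray,
    query: tuple[float, float],
    span: float = 0.75,
    degree: int = 2,
) -> LoessFit:
    """Loess prediction at one query location.

    ``points`` is (n, 2) lon/lat, ``values`` the metric at each point.  The
    ``ceil(span * n)`` nearest points (Euclidean in degrees) form the
    neighbourhood; tricube weights ``(1 - (d/d_max)^3)^3`` feed a weighted
    least-squares fit of a full degree-``degree`` polynomial centred on the
    query, whose intercept is the prediction.  Centring makes predictions
    exactly invariant to translating all coordinates.  A rank-deficient
    local design triggers a fallback to degree 1 and then to the weighted
    mean, flagged in the result.
    """
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n = pts.shape[0]
    k = max(int(math.ceil(span * n)), 1)
    qx, qy = float(query[0]), float(query[1])
    dx = pts[:, 0] - qx
    dy = pts[:, 1] - qy
    dist = np.hypot(dx, dy)
    nearest = np.argsort(dist, kind="stable")[:k]
    d = dist[nearest]
    dmax = d.max()
    if dmax <= 0:
        return LoessFit(float(vals[nearest].mean()), 0, True)
    w = np.clip(1.0 - (d / dmax) ** 3, 0.0, 1.0) ** 3
    w = np.where(d >= dmax, np.maximum(w, 1e-9), w)  # keep boundary points
    x = dx[nearest]
    y = dy[nearest]
    v = vals[nearest]
    sw = np.sqrt(w)
    min_pts = {1: 3, 2: 6}
    for deg in ([2, 1] if degree == 2 else [1]):
        if k < min_pts[deg]:
            continue
        X = _design(x, y, deg)
        Xw = X * sw[:, None]
        vw = v * sw
        coef, _, rank, _ = np.linalg.lstsq(Xw, vw, rcond=None)
        if rank == X.shape[1]:
            return LoessFit(float(coef[0]), deg, deg != degree)
    wm = float(np.average(v, weights=np.maximum(w, 1e-12)))
    return LoessFit(wm, 0, True)


@dataclass
class GridSurface:
    """Interpolated metric values on a regular grid."""

    table: pd.DataFrame  # cell_ix, cell_iy, lon_center, lat_center, value, ...
    label: str
    span: float
    degree: int
    spec: GridSpec = field(repr=False, default=None)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _convex_hull_mask(points: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """True where a query lies inside the convex hull of the points."""
    from scipy.spatial import Delaunay, QhullError

    try:
        tri = Delaunay(points)
    except QhullError:
        # degenerate (e.g. collinear) plots: fall back to the bounding box
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        return np.all((queries >= lo) & (queries <= hi), axis=1)
    return tri.find_simplex(queries) >= 0


def interpolate_metric_surface(
    metric: pd.Series,
    coords: pd.DataFrame,
    spec: GridSpec | None = None,
    span: float = 0.75,
    degree: int = 2,
    label: str | None = None,
) -> GridSurface:
    """Loess-interpolate a per-plot metric onto every grid-cell centre.

    ``metric`` is indexed by plot id; ``coords`` provides lon/lat per plot.
    Requires at least 10 plots — fewer leave the local regressions badly
    underdetermined.
    """
    plots = [p for p in metric.index if p in coords.index]
    if len(plots) < len(metric):
        missing = sorted(set(metric.index) - set(plots))
        raise ValueError(f"plots without coordinates: {missing}")
    if len(plots) < 10:
        raise ValueError("need at least 10 plots for surface interpolation")
    pts = coords.loc[plots, ["lon", "lat"]].to_numpy(dtype=float)
    vals = metric.loc[plots].to_numpy(dtype=float)
    spec = spec or GridSpec.from_points(pts[:, 0], pts[:, 1])

    cells = spec.cells()
    centers = np.array([spec.cell_center(ix, iy) for ix, iy in cells])
    inside = _convex_hull_mask(pts, centers)
    rows = []
    for (ix, iy), (cx, cy), inh in zip(cells, centers, inside):
        fit = loess_predict(pts, vals, (cx, cy), span=span, degree=degree)
        rows.append(
            {
                "cell_ix": ix,
                "cell_iy": iy,
                "lon_center": cx,
                "lat_center": cy,
                "value": fit.value,
                "extrapolated": not bool(inh),
                "fallback_degree": fit.degree_used if fit.fallback else degree,
            }
        )
    table = pd.DataFrame(rows)
    if not np.all(np.isfinite(table["value"].to_numpy())):
        raise ValueError("non-finite prediction on the surface")
    return GridSurface(
        table=table,
        label=label or metric.name or "metric",
        span=span,
        degree=degree,
        spec=spec,
    )
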