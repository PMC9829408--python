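"""Sparse/dense point classification.

Each group's points are partitioned into members of visually contiguous
dense clusters (which receive coarse region hatching) and sparse singletons
(which receive per-marker pattern glyphs).  The detector works on a square
occupancy grid whose cell size tracks the rendered marker diameter, so the
classification mirrors what a reader sees: markers that would merge into a
solid blob on the page form a dense region, isolated markers stay sparse.

Algorithm, per group independently:

1. bin the group's points into square cells of side ``bin_size``
   (half-open cells, left/bottom edge inclusive);
2. a cell *qualifies* when the same-group point count summed over its 3x3
   cell neighborhood reaches ``density_threshold``;
3. qualifying cells are grouped into 8-connected components, and components
   smaller than ``min_cluster_cells`` cells are discarded;
4. a point is **dense** iff its cell belongs to a surviving component;
   every other point is **sparse**.

Raising ``density_threshold`` can only shrink the dense set (monotonicity),
and groups never influence each other's labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .io import PointTable, SparseOverride

__all__ = [
    "GridConfig",
    "OccupancyGrid",
    "SparsityLabels",
    "build_occupancy_grid",
    "classify_sparse_dense",
    "apply_sparse_override",
]

#: default canvas in typographic points (6.4 x 4.8 inch figure)
DEFAULT_CANVAS_PT = (460.8, 345.6)
#: default rendered marker diameter in points, sized for ~10^4-point panels
DEFAULT_POINT_DIAMETER_PT = 3.0

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass(frozen=True)
class GridConfig:
    """Detector configuration.

    ``bin_size`` is the grid cell side in data units.  When None it is
    derived from the rendered geometry: ``bin_factor`` x the marker diameter,
    converted from display points to data units with the canvas dimensions
    (the data-unit fallback for headless use is to pass ``bin_size``
    explicitly).
    """

    bin_size: float | None = None
    bin_factor: float = 1.5
    point_diameter: float = DEFAULT_POINT_DIAMETER_PT
    canvas: tuple = DEFAULT_CANVAS_PT
    density_threshold: int = 4
    min_cluster_cells: int = 2

    def __post_init__(self):
        if self.bin_size is not None and not self.bin_size > 0:
            raise ParameterError("bin_size must be > 0")
        if self.bin_factor <= 0:
            raise ParameterError("bin_factor must be > 0")
        if self.density_threshold < 1:
            raise ParameterError("density_threshold must be >= 1")
        if self.min_cluster_cells < 1:
            raise ParameterError("min_cluster_cells must be >= 1")

    def resolve_bin_size(self, points: PointTable) -> float:
        """Data-unit cell size for this table (explicit value wins)."""
        if self.bin_size is not None:
            return float(self.bin_size)
        xmin, ymin, xmax, ymax = points.bounds()
        w_pt, h_pt = self.canvas
        # data units per display point, on the more compressed axis
        span = max((xmax - xmin) / w_pt, (ymax - ymin) / h_pt)
        if span <= 0:  # degenerate: all points coincide
            span = 1.0 / max(w_pt, h_pt)
        return self.bin_factor * self.point_diameter * span


@dataclass(frozen=True)
class OccupancyGrid:
    """Per-group point counts on a shared square grid.

    ``counts`` maps group label -> {(i, j): count} with i the column index
    along x and j the row index along y.  Cells are half-open:
    point p falls in cell (floor((p.x-x0)/b), floor((p.y-y0)/b)).
    """

    origin: tuple
    bin_size: float
    counts: dict
    point_cells: dict  # group -> (n_group, 2) int array, aligned w/ group rows

    def group_total(self, label) -> int:
        return sum(self.counts.get(label, {}).values())


def cell_indices(x, y, origin, bin_size) -> np.ndarray:
    """Half-open cell assignment; returns an (n, 2) int array of (i, j)."""
    i = np.floor((np.asarray(x) - origin[0]) / bin_size).astype(int)
    j = np.floor((np.asarray(y) - origin[1]) / bin_size).astype(int)
    return np.column_stack([i, j])


def build_occupancy_grid(
    points: PointTable,
    canvas_bounds: tuple | None = None,
    bin_size: float = 1.0,
) -> OccupancyGrid:
    """Bin each group's points into square cells of side ``bin_size``.

    ``canvas_bounds`` is (xmin, ymin, xmax, ymax); defaults to the data
    bounds.  Counts are conserved: each point lands in exactly one cell.
    """
    if not bin_size > 0:
        raise ParameterError("bin_size must be > 0")
    if canvas_bounds is None:
        canvas_bounds = points.bounds()
    origin = (float(canvas_bounds[0]), float(canvas_bounds[1]))
    counts: dict = {}
    point_cells: dict = {}
    for label in points.groups():
        idx = points.group_indices(label)
        cells = cell_indices(points.x[idx], points.y[idx], origin, bin_size)
        point_cells[label] = cells
        uniq, cnt = np.unique(cells, axis=0, return_counts=True)
        counts[label] = {(int(i), int(j)): int(c) for (i, j), c in zip(uniq, cnt)}
    return OccupancyGrid(
        origin=origin, bin_size=float(bin_size), counts=counts, point_cells=point_cells
    )


@dataclass(frozen=True)
class SparsityLabels:
    """Per-point dense/sparse labels for a PointTable.

    ``sparse`` is a boolean array aligned with the table's row order
    (True = sparse).  ``provenance`` records whether the labels came from
    the detector or from a user override.  The grid used (if any) is kept so
    downstream region hatching bins dense points identically.
    """

    sparse: np.ndarray
    provenance: str  # "detector" | "override"
    config: GridConfig | None = None
    bin_size: float | None = None
    origin: tuple | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "sparse", np.asarray(self.sparse, dtype=bool).copy()
        )

    @property
    def n_sparse(self) -> int:
        return int(self.sparse.sum())

    @property
    def n_dense(self) -> int:
        return int((~self.sparse).sum())


def _qualifying_cells(group_counts: dict, k: int) -> dict:
    """Map occupied cell -> True iff its 3x3 neighborhood count >= k."""
    if not group_counts:
        return {}
    cells = np.array(list(group_counts.keys()), dtype=int)
    vals = np.array(list(group_counts.values()), dtype=int)
    imin, jmin = cells.min(axis=0)
    imax, jmax = cells.max(axis=0)
    arr = np.zeros((imax - imin + 3, jmax - jmin + 3), dtype=int)  # 1-cell pad
    arr[cells[:, 0] - imin + 1, cells[:, 1] - jmin + 1] = vals
    nbhd = ndimage.convolve(arr, _EIGHT, mode="constant", cval=0)
    out = {}
    for (i, j), _ in group_counts.items():
        out[(i, j)] = bool(nbhd[i - imin + 1, j - jmin + 1] >= k)
    return out


def dense_cells_for_group(group_counts: dict, k: int, min_cluster_cells: int) -> dict:
    """Cells of the group's kept dense components: cell -> component id.

    Component ids are assigned deterministically: components ordered
    row-major by their minimal (j, i) cell, numbered from 0.
    """
    qual = {c for c, ok in _qualifying_cells(group_counts, k).items() if ok}
    if not qual:
        return {}
    cells = np.array(sorted(qual), dtype=int)
    imin, jmin = cells.min(axis=0)
    imax, jmax = cells.max(axis=0)
    arr = np.zeros((imax - imin + 1, jmax - jmin + 1), dtype=int)
    arr[cells[:, 0] - imin, cells[:, 1] - jmin] = 1
    lab, nlab = ndimage.label(arr, structure=_EIGHT)
    comp_cells: dict = {}
    for i, j in cells:
        comp_cells.setdefault(lab[i - imin, j - jmin], []).append((int(i), int(j)))
    kept = {
        c: members
        for c, members in comp_cells.items()
        if len(members) >= min_cluster_cells
    }
    # deterministic renumbering: row-major by minimal (j, i)
    order = sorted(kept, key=lambda c: min((j, i) for i, j in kept[c]))
    out = {}
    for new_id, old in enumerate(order):
        for cell in kept[old]:
            out[cell] = new_id
    return out


def classify_sparse_dense(
    points: PointTable, config: GridConfig | None = None
) -> SparsityLabels:
    """Run the sparse point detector over every group independently."""
    if config is None:
        config = GridConfig()
    b = config.resolve_bin_size(points)
    grid = build_occupancy_grid(points, bin_size=b)
    sparse = np.ones(len(points), dtype=bool)
    for label in points.groups():
        dense = dense_cells_for_group(
            grid.counts[label], config.density_threshold, config.min_cluster_cells
        )
        idx = points.group_indices(label)
        cells = grid.point_cells[label]
        for row, (i, j) in zip(idx, cells):
            if (int(i), int(j)) in dense:
                sparse[row] = False
    return SparsityLabels(
        sparse=sparse,
        provenance="detector",
        config=config,
        bin_size=b,
        origin=grid.origin,
    )


def apply_sparse_override(
    points: PointTable, override: SparseOverride
) -> SparsityLabels:
    """Bypass the detector: listed ids sparse, everything else dense."""
    override.validate_against(points)
    sparse = np.array([pid in override.ids for pid in points.ids], dtype=bool)
    return SparsityLabels(sparse=sparse, provenance="override", config=None)
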