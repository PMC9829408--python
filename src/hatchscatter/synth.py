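"""Synthetic point tables emulating the two demonstration regimes.

Two generators cover the structures a hatched scatter plot has to handle:

* :func:`make_embedding_fixture` — a UMAP-like embedding: per group, a
  compact isotropic Gaussian blob (the dense cluster) plus a diffuse uniform
  halo of stragglers (the sparse points).  Blob centers sit at equal angles
  on a circle, so the layout is deterministic apart from the seeded draws.
* :func:`make_spatial_fixture` — an in-situ spatial plot: a tiled grid of
  microscopy frames, each frame one group with points uniform in its tile
  (the many-small-groups regime, e.g. 82 frames).

Both are fully determined by their seed and return ordinary
:class:`~hatchscatter.io.PointTable` objects, so every downstream stage is
testable without external data.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .io import PointTable

__all__ = ["make_embedding_fixture", "make_spatial_fixture"]

#: halo inner edge as a fraction of the halo radius (keeps the sparse
#: annulus clear of the blob tail)
_INNER_FRACTION = 0.4
#: blob centers sit on a circle of this multiple of the halo radius
_CENTER_FACTOR = 1.2


def make_embedding_fixture(
    n_groups: int = 4,
    n_dense_per_group: int = 2400,
    n_sparse_per_group: int = 100,
    blob_sd: float = 1.0,
    halo_radius: float = 12.0,
    seed: int = 0,
    return_truth: bool = False,
):
    """Gaussian blobs with sparse halos, one blob per group.

    Defaults emulate a 10,000-cell embedding in four clusters (2400 dense +
    100 halo points each) with a 12:1 halo-to-blob scale separation, enough
    for the density detector to recover the planted labels.

    With ``return_truth=True`` also returns the planted per-point sparse
    flag (True = halo point), aligned with table rows.
    """
    if n_groups < 1:
        raise ParameterError("n_groups must be >= 1")
    if n_dense_per_group < 0 or n_sparse_per_group < 0:
        raise ParameterError("point counts must be >= 0")
    if n_dense_per_group + n_sparse_per_group == 0:
        raise ParameterError("each group needs at least one point")
    rng = np.random.default_rng(seed)
    center_r = _CENTER_FACTOR * halo_radius
    r_in = _INNER_FRACTION * halo_radius
    ids, xs, ys, groups, planted_sparse = [], [], [], [], []
    for g in range(n_groups):
        theta = 2.0 * np.pi * g / n_groups
        cx, cy = center_r * np.cos(theta), center_r * np.sin(theta)
        label = f"cluster{g + 1}"
        bx = rng.normal(cx, blob_sd, n_dense_per_group)
        by = rng.normal(cy, blob_sd, n_dense_per_group)
        for k in range(n_dense_per_group):
            ids.append(f"g{g}_d{k}")
            xs.append(bx[k])
            ys.append(by[k])
            groups.append(label)
            planted_sparse.append(False)
        # area-uniform draw in the annulus [r_in, halo_radius]
        u = rng.uniform(size=n_sparse_per_group)
        rr = np.sqrt(u * (halo_radius**2 - r_in**2) + r_in**2)
        ang = rng.uniform(0.0, 2.0 * np.pi, n_sparse_per_group)
        for k in range(n_sparse_per_group):
            ids.append(f"g{g}_s{k}")
            xs.append(cx + rr[k] * np.cos(ang[k]))
            ys.append(cy + rr[k] * np.sin(ang[k]))
            groups.append(label)
            planted_sparse.append(True)
    table = PointTable(
        ids=tuple(ids),
        x=np.array(xs),
        y=np.array(ys),
        group=tuple(groups),
    )
    if return_truth:
        return table, np.array(planted_sparse, dtype=bool)
    return table


def make_spatial_fixture(
    n_frames_x: int = 41,
    n_frames_y: int = 2,
    cells_per_frame: int = 50,
    frame_size: float = 1.0,
    seed: int = 0,
) -> PointTable:
    """Tiled spatial grid of frames, one group per frame.

    The default 41 x 2 grid gives 82 frames, the many-group spatial regime.
    Frames are numbered row-major from 1; each frame's points are uniform in
    its own tile.
    """
    if n_frames_x < 1 or n_frames_y < 1:
        raise ParameterError("frame grid dimensions must be >= 1")
    if cells_per_frame < 1:
        raise ParameterError("cells_per_frame must be >= 1")
    rng = np.random.default_rng(seed)
    ids, xs, ys, groups = [], [], [], []
    frame = 0
    for fy in range(n_frames_y):
        for fx in range(n_frames_x):
            frame += 1
            label = f"frame{frame}"
            px = rng.uniform(fx * frame_size, (fx + 1) * frame_size, cells_per_frame)
            py = rng.uniform(fy * frame_size, (fy + 1) * frame_size, cells_per_frame)
            for k in range(cells_per_frame):
                ids.append(f"f{frame}_c{k}")
                xs.append(px[k])
                ys.append(py[k])
                groups.append(label)
    return PointTable(
        ids=tuple(ids), x=np.array(xs), y=np.array(ys), group=tuple(groups)
    )
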