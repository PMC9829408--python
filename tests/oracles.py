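"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: the classifier
oracle is pure-Python neighborhood counting plus recursive flood fill, and
the hatch-length oracle clips the infinite line against each axis-aligned
cell separately (Liang-Barsky parameter intervals) and sums the pieces —
cells partition the mask, so the sum is the exact clipped length.
"""

from __future__ import annotations

import math


def brute_force_classify(points, bin_size, k, min_cluster_cells, origin=None):
    """Per-point sparse flags by exhaustive enumeration.

    Returns a list of bools aligned with the table rows (True = sparse).
    """
    if origin is None:
        origin = (min(points.x), min(points.y))
    n = len(points)
    cells = [
        (
            math.floor((points.x[i] - origin[0]) / bin_size),
            math.floor((points.y[i] - origin[1]) / bin_size),
        )
        for i in range(n)
    ]
    sparse = [True] * n
    for label in points.groups():
        rows = [i for i in range(n) if points.group[i] == label]
        occupied = {}
        for i in rows:
            occupied[cells[i]] = occupied.get(cells[i], 0) + 1
        # qualifying cells: 3x3 same-group neighborhood count >= k
        qualifying = set()
        for (ci, cj) in occupied:
            total = 0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    total += occupied.get((ci + di, cj + dj), 0)
            if total >= k:
                qualifying.add((ci, cj))
        # flood-fill 8-connected components of qualifying cells
        seen = set()
        kept = set()
        for start in qualifying:
            if start in seen:
                continue
            comp = []
            stack = [start]
            seen.add(start)
            while stack:
                ci, cj = stack.pop()
                comp.append((ci, cj))
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        nb = (ci + di, cj + dj)
                        if nb in qualifying and nb not in seen:
                            seen.add(nb)
                            stack.append(nb)
            if len(comp) >= min_cluster_cells:
                kept.update(comp)
        for i in rows:
            if cells[i] in kept:
                sparse[i] = False
    return sparse


def _clip_line_to_box(px, py, dx, dy, box):
    """Liang-Barsky: parameter interval of line p + t*d inside a box."""
    xmin, ymin, xmax, ymax = box
    t0, t1 = -math.inf, math.inf
    for p, d, lo, hi in ((px, dx, xmin, xmax), (py, dy, ymin, ymax)):
        if abs(d) < 1e-15:
            if not (lo <= p <= hi):
                return None
        else:
            ta, tb = (lo - p) / d, (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            t0, t1 = max(t0, ta), min(t1, tb)
    if t1 <= t0:
        return None
    return t0, t1


def oracle_hatch_length(mask, angle_deg, spacing, phase):
    """Total clipped length of the line family, summed cell by cell."""
    a = math.radians(angle_deg % 180.0)
    d = (math.cos(a), math.sin(a))
    nrm = (-d[1], d[0])
    boxes = [mask.cell_box(c) for c in mask.cells]
    offs = []
    for xmin, ymin, xmax, ymax in boxes:
        for cx in (xmin, xmax):
            for cy in (ymin, ymax):
                offs.append(cx * nrm[0] + cy * nrm[1])
    o_lo, o_hi = min(offs), max(offs)
    n_lo = math.ceil((o_lo - phase) / spacing - 1e-12)
    n_hi = math.floor((o_hi - phase) / spacing + 1e-12)
    total = 0.0
    for n in range(n_lo, n_hi + 1):
        off = phase + n * spacing
        px, py = off * nrm[0], off * nrm[1]
        for box in boxes:
            iv = _clip_line_to_box(px, py, d[0], d[1], box)
            if iv is not None:
                total += iv[1] - iv[0]
    return total


def pixel_hatch_length(mask, angle_deg, spacing, phase, step=1e-3):
    """Dense-sampling fallback oracle: walk each line in tiny steps and sum
    the steps whose sample point falls inside an occupied cell."""
    a = math.radians(angle_deg % 180.0)
    d = (math.cos(a), math.sin(a))
    nrm = (-d[1], d[0])
    boxes = [mask.cell_box(c) for c in mask.cells]
    xs = [b[0] for b in boxes] + [b[2] for b in boxes]
    ys = [b[1] for b in boxes] + [b[3] for b in boxes]
    corners = [(x, y) for x in (min(xs), max(xs)) for y in (min(ys), max(ys))]
    offs = [cx * nrm[0] + cy * nrm[1] for cx, cy in corners]
    ts = [cx * d[0] + cy * d[1] for cx, cy in corners]
    o_lo, o_hi = min(offs), max(offs)
    n_lo = math.ceil((o_lo - phase) / spacing - 1e-12)
    n_hi = math.floor((o_hi - phase) / spacing + 1e-12)
    total = 0.0
    for n in range(n_lo, n_hi + 1):
        off = phase + n * spacing
        t = min(ts)
        while t < max(ts):
            x = off * nrm[0] + (t + step / 2) * d[0]
            y = off * nrm[1] + (t + step / 2) * d[1]
            if mask.contains(x, y):
                total += step
            t += step
    return total
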