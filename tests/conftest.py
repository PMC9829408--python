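import numpy as np
import pytest
from hypothesis import settings

from hatchscatter.io import PointTable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def three_groups() -> PointTable:
    """Tiny mixed table: two tight clusters plus isolated singletons."""
    rng = np.random.default_rng(7)
    xs, ys, groups = [], [], []
    for cx, cy, label in [(0.0, 0.0, "a"), (10.0, 0.0, "b")]:
        xs.extend(rng.normal(cx, 0.3, 40))
        ys.extend(rng.normal(cy, 0.3, 40))
        groups.extend([label] * 40)
    # group c: three isolated points far apart
    xs.extend([0.0, 5.0, 10.0])
    ys.extend([8.0, 8.0, 8.0])
    groups.extend(["c"] * 3)
    return PointTable(
        ids=tuple(range(len(xs))),
        x=np.array(xs),
        y=np.array(ys),
        group=tuple(groups),
    )


def random_point_table(rng, n_groups=2, n_points=60, extent=20.0) -> PointTable:
    """Random clumpy table for oracle comparisons (<= 20x20 unit cells)."""
    xs, ys, groups = [], [], []
    for g in range(n_groups):
        n_clumps = rng.integers(1, 4)
        left = n_points
        for c in range(n_clumps):
            m = left if c == n_clumps - 1 else int(rng.integers(0, left + 1))
            left -= m
            cx, cy = rng.uniform(0, extent, 2)
            sd = rng.uniform(0.3, 3.0)
            xs.extend(np.clip(rng.normal(cx, sd, m), 0, extent))
            ys.extend(np.clip(rng.normal(cy, sd, m), 0, extent))
            groups.extend([f"g{g}"] * m)
    return PointTable(
        ids=tuple(range(len(xs))),
        x=np.array(xs),
        y=np.array(ys),
        group=tuple(groups),
    )
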