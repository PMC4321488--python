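import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from detkit import UnitCell
from detkit.cells import _cell_from_metric, metric_tensor
from detkit.exceptions import InvalidCellError, InvalidG6Error

settings.register_profile(
    "detkit",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("detkit")


def random_cell(rng, lo=3.0, hi=50.0, angle_lo=60.0, angle_hi=120.0):
    """A random valid (positive-volume) triclinic cell."""
    while True:
        lengths = rng.uniform(lo, hi, 3)
        angles = rng.uniform(angle_lo, angle_hi, 3)
        try:
            return UnitCell(*lengths, *angles)
        except InvalidCellError:
            continue


def random_unimodular(rng, lo=-2, hi=2):
    """A random GL(3,Z) matrix (det +/-1) with entries in [lo, hi]."""
    while True:
        m = rng.integers(lo, hi + 1, (3, 3))
        if abs(round(np.linalg.det(m))) == 1:
            return m


def rebase_cell(cell, m):
    """The same lattice described in the basis transformed by m."""
    try:
        return _cell_from_metric(m.T @ metric_tensor(cell) @ m)
    except InvalidG6Error:
        return None  # extreme skew: angle hit 0/180 numerically


@pytest.fixture(scope="session")
def unimodular_pool():
    """All 3x3 integer matrices with entries in {-1,0,1} and det +/-1:
    the brute-force transform set for oracle lattice comparisons."""
    cols = np.array(list(itertools.product((-1, 0, 1), repeat=9)))
    mats = cols.reshape(-1, 3, 3)
    dets = np.rint(np.linalg.det(mats)).astype(int)
    return mats[np.abs(dets) == 1]


def g6_of_metrics(g_stack):
    """G6 vectors of a stack of metric tensors, shape (..., 3, 3) -> (..., 6)."""
    return np.stack(
        [
            g_stack[..., 0, 0],
            g_stack[..., 1, 1],
            g_stack[..., 2, 2],
            2 * g_stack[..., 1, 2],
            2 * g_stack[..., 0, 2],
            2 * g_stack[..., 0, 1],
        ],
        axis=-1,
    )


def brute_force_min_distance(cell_a, cell_b, pool):
    """Oracle lattice distance: minimum reduced-G6 Euclidean distance over
    every brute-force transform applied to either operand."""
    from detkit.cells import g6_from_cell, niggli_reduce

    best = np.inf
    for c1, c2 in ((cell_a, cell_b), (cell_b, cell_a)):
        g = metric_tensor(niggli_reduce(c1).reduced)
        target = g6_from_cell(niggli_reduce(c2).reduced)
        transformed = np.einsum("tji,jk,tkl->til", pool, g, pool)
        d = np.linalg.norm(g6_of_metrics(transformed) - target, axis=1).min()
        best = min(best, float(d))
    return best
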