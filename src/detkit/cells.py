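"""Unit-cell algebra: metric tensors, the G6 embedding, Niggli reduction and
lattice distance metrics.

A unit cell (a, b, c, alpha, beta, gamma) is embedded in the six-dimensional
G6 space

    g = (a^2, b^2, c^2, 2bc cos(alpha), 2ac cos(beta), 2ab cos(gamma)),

with all components in A^2.  Distances between lattices are measured in this
space after Niggli reduction, so they are dimensionally consistent with the
dendrogram-cut threshold used by the clustering stage (also A^2).

Two metrics are provided:

* :func:`g6_distance_euclidean` -- plain Euclidean distance between the
  reduced G6 vectors of the two cells.  Fast, but blind to the fact that a
  single lattice touching the Niggli-cone boundary has several nearly-reduced
  descriptions.
* :func:`ncdist` -- a symmetry-aware distance in the spirit of the
  Andrews-Bernstein NCDist metric: the minimum reduced-G6 Euclidean distance
  over a fixed set of lattice-preserving basis transforms (signed axis
  permutations and the Niggli-cone boundary shears, plus their compositions).
  It never exceeds the plain Euclidean distance and is zero for any two
  parameterizations of the same lattice.  This is a finite-transform
  approximation, not the full manifold-embedding algorithm; tests validate it
  against a brute-force enumeration of small integer basis transforms.

Angles are degrees at the API surface and radians internally.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import gemmi
import numpy as np

from .exceptions import InvalidCellError, InvalidG6Error, ReductionError

__all__ = [
    "UnitCell",
    "ReductionResult",
    "metric_tensor",
    "cell_volume",
    "g6_from_cell",
    "cell_from_g6",
    "niggli_reduce",
    "is_niggli_reduced",
    "g6_distance_euclidean",
    "ncdist",
]


@dataclass(frozen=True)
class UnitCell:
    """Six lattice parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise InvalidCellError(f"cell edge {name} must be positive, got {getattr(self, name)}")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angle {name} must be in (0, 180), got {ang}")
        # positive metric determinant <=> realizable lattice
        if self.volume_squared() <= 0:
            raise InvalidCellError(f"cell {self.parameters} has non-positive volume")

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def volume_squared(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in self.angles)
        return (self.a * self.b * self.c) ** 2 * (
            1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        )

    @property
    def volume(self) -> float:
        """Cell volume in A^3."""
        return math.sqrt(self.volume_squared())

    def is_close(self, other: "UnitCell", rtol: float = 1e-9, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.parameters, other.parameters, rtol=rtol, atol=atol))


def metric_tensor(cell: UnitCell) -> np.ndarray:
    """Real-space metric tensor G (3x3 symmetric, A^2).

    G11=a^2, G22=b^2, G33=c^2, G12=ab cos(gamma), G13=ac cos(beta),
    G23=bc cos(alpha).  det(G) equals the squared cell volume.
    """
    a, b, c = cell.lengths
    ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
    g = np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )
    if np.linalg.det(g) <= 0:
        raise InvalidCellError(f"metric tensor of {cell.parameters} is not positive definite")
    return g


def cell_volume(cell: UnitCell) -> float:
    return cell.volume


def g6_from_cell(cell: UnitCell) -> np.ndarray:
    """Embed a cell in G6: (a^2, b^2, c^2, 2bc cos a, 2ac cos b, 2ab cos g), A^2."""
    a, b, c = cell.lengths
    ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
    return np.array([a * a, b * b, c * c, 2 * b * c * ca, 2 * a * c * cb, 2 * a * b * cg])


def cell_from_g6(g: np.ndarray) -> UnitCell:
    """Invert the G6 embedding.  Raises :class:`InvalidG6Error` if the
    components do not describe a positive-volume lattice."""
    g = np.asarray(g, dtype=float)
    if g.shape != (6,):
        raise InvalidG6Error(f"G6 vector must have 6 components, got shape {g.shape}")
    g1, g2, g3, g4, g5, g6 = g
    if g1 <= 0 or g2 <= 0 or g3 <= 0:
        raise InvalidG6Error(f"g1..g3 must be positive, got {g[:3]}")
    a, b, c = math.sqrt(g1), math.sqrt(g2), math.sqrt(g3)
    cosines = (g4 / (2 * b * c), g5 / (2 * a * c), g6 / (2 * a * b))
    for name, cv in zip(("g4", "g5", "g6"), cosines):
        if abs(cv) >= 1:
            raise InvalidG6Error(f"{name} implies |cos| = {abs(cv):.6g} >= 1")
    alpha, beta, gamma = (math.degrees(math.acos(cv)) for cv in cosines)
    try:
        return UnitCell(a, b, c, alpha, beta, gamma)
    except InvalidCellError as exc:
        raise InvalidG6Error(str(exc)) from exc


def _g6_from_metric(g: np.ndarray) -> np.ndarray:
    return np.array([g[0, 0], g[1, 1], g[2, 2], 2 * g[1, 2], 2 * g[0, 2], 2 * g[0, 1]])


def _cell_from_metric(g: np.ndarray) -> UnitCell:
    return cell_from_g6(_g6_from_metric(g))


@dataclass(frozen=True)
class ReductionResult:
    """Outcome of Niggli reduction.

    ``change_of_basis`` M is an integer matrix with det +/-1 such that
    ``M.T @ metric_tensor(original) @ M == metric_tensor(reduced)``.
    """

    reduced: UnitCell
    change_of_basis: np.ndarray


def niggli_reduce(cell: UnitCell, max_iter: int = 100) -> ReductionResult:
    """Niggli-reduce a cell (Krivy-Gruber steps with epsilon-stabilized
    comparisons), returning the reduced cell and the change of basis.

    Comparisons use a tight stability epsilon of 1e-9 relative to the
    largest squared cell edge.  A looser epsilon would occasionally stop one
    boundary step short of the canonical form, so that two bases of the same
    lattice could reduce to different cells; tolerance for *comparing*
    reduced cells belongs in the distance metrics, not here.
    """
    scale = max(cell.a, cell.b, cell.c) ** 2
    gv = gemmi.GruberVector(
        gemmi.UnitCell(*cell.parameters), "P", True  # track change of basis
    )
    gv.niggli_reduce(epsilon=1e-9 * scale, iteration_limit=max_iter)
    if not gv.is_niggli(epsilon=1e-9 * scale):
        raise ReductionError(
            f"Niggli reduction of {cell.parameters} did not converge in {max_iter} steps"
        )
    mat = np.array(gv.change_of_basis.rot, dtype=float) / gemmi.Op.DEN
    m_int = np.rint(mat).astype(int)
    if not np.allclose(mat, m_int, atol=1e-12) or abs(round(np.linalg.det(m_int))) != 1:
        raise ReductionError(f"non-unimodular change of basis for {cell.parameters}")
    # keep exact arithmetic: rebuild the reduced metric from the integer matrix
    g_red = m_int.T @ metric_tensor(cell) @ m_int
    return ReductionResult(reduced=_cell_from_metric(g_red), change_of_basis=m_int)


def is_niggli_reduced(cell: UnitCell, tol: float = 1e-5) -> bool:
    """Check the standard Niggli conditions (main + special) on a cell.

    Implemented from the textbook inequalities, independently of the
    reduction engine, so it can serve as a verification of reduction output.
    """
    g1, g2, g3, g4, g5, g6 = g6_from_cell(cell)
    eps = tol * max(g1, g2, g3)

    def lt(x, y):
        return x < y - eps

    def eq(x, y):
        return abs(x - y) <= eps

    # main conditions
    if lt(g2, g1) or lt(g3, g2):
        return False
    if lt(g2, abs(g4)) or lt(g1, abs(g5)) or lt(g1, abs(g6)):
        return False
    pos = [x > eps for x in (g4, g5, g6)]
    neg = [x < -eps for x in (g4, g5, g6)]
    if any(pos) and not all(pos):
        return False  # mixed signs (all > 0 or all <= 0 required)
    if any(pos) and any(neg):
        return False
    if lt(g1 + g2 + g4 + g5 + g6, 0):
        return False
    # special (boundary tie) conditions
    if eq(g1, g2) and lt(abs(g5), abs(g4)):
        return False
    if eq(g2, g3) and lt(abs(g6), abs(g5)):
        return False
    if eq(g4, g2) and lt(2 * g5, g6):
        return False
    if eq(g5, g1) and lt(2 * g4, g6):
        return False
    if eq(g6, g1) and lt(2 * g4, g5):
        return False
    if eq(g4, -g2) and not eq(g6, 0):
        return False
    if eq(g5, -g1) and not eq(g6, 0):
        return False
    if eq(g6, -g1) and not eq(g5, 0):
        return False
    if eq(g1 + g2 + g4 + g5 + g6, 0) and lt(0, 2 * (g1 + g5) + g6):
        return False
    return True


# ---------------------------------------------------------------------------
# distance metrics
# ---------------------------------------------------------------------------


def _signed_permutations() -> list[np.ndarray]:
    """All 48 signed 3x3 permutation matrices.  M and -M act identically on a
    metric tensor, so the set is deduplicated to 24 distinct actions."""
    mats = []
    seen = set()
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=int)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            key = tuple((m if m.flat[np.flatnonzero(m)[0]] > 0 else -m).ravel())
            if key not in seen:
                seen.add(key)
                mats.append(m)
    return mats


def _boundary_shears() -> list[np.ndarray]:
    """The shear matrices of the Krivy-Gruber boundary steps (both signs)."""
    mats = []
    for s in (1, -1):
        mats.append(np.array([[1, 0, 0], [0, 1, 0], [0, s, 1]]))  # xi boundary
        mats.append(np.array([[1, 0, 0], [0, 1, 0], [s, 0, 1]]))  # eta boundary
        mats.append(np.array([[1, 0, 0], [s, 1, 0], [0, 0, 1]]))  # zeta boundary
    mats.append(np.array([[1, 0, 0], [0, 1, 0], [1, 1, 1]]))  # face-body boundary
    return mats


@lru_cache(maxsize=1)
def _ncdist_transforms() -> np.ndarray:
    """The fixed transform set used by :func:`ncdist`: signed permutations,
    boundary shears and their two-way compositions (deduplicated)."""
    perms = _signed_permutations()
    shears = _boundary_shears()
    out = {}
    for m in itertools.chain(
        perms,
        shears,
        (p @ s for p in perms for s in shears),
        (s @ p for p in perms for s in shears),
    ):
        canon = m if m.flat[np.flatnonzero(m)[0]] > 0 else -m
        out[tuple(canon.ravel())] = canon
    return np.stack(list(out.values())).astype(float)


def _transformed_g6_variants(cell: UnitCell) -> np.ndarray:
    """Reduced G6 vector of ``cell`` under every ncdist transform (T x 6)."""
    g = metric_tensor(niggli_reduce(cell).reduced)
    mats = _ncdist_transforms()
    gt = np.einsum("tji,jk,tkl->til", mats, g, mats)  # M.T @ G @ M for each M
    return np.stack(
        [
            gt[:, 0, 0],
            gt[:, 1, 1],
            gt[:, 2, 2],
            2 * gt[:, 1, 2],
            2 * gt[:, 0, 2],
            2 * gt[:, 0, 1],
        ],
        axis=1,
    )


def g6_distance_euclidean(c1: UnitCell, c2: UnitCell) -> float:
    """Euclidean distance (A^2) between the Niggli-reduced G6 vectors."""
    g1 = g6_from_cell(niggli_reduce(c1).reduced)
    g2 = g6_from_cell(niggli_reduce(c2).reduced)
    return float(np.linalg.norm(g1 - g2))


def ncdist(c1: UnitCell, c2: UnitCell) -> float:
    """Symmetry-aware lattice distance (A^2): minimum reduced-G6 Euclidean
    distance over the fixed transform set, evaluated in both directions."""
    v1 = _transformed_g6_variants(c1)
    v2 = _transformed_g6_variants(c2)
    g1 = g6_from_cell(niggli_reduce(c1).reduced)
    g2 = g6_from_cell(niggli_reduce(c2).reduced)
    d12 = np.linalg.norm(v1 - g2, axis=1).min()
    d21 = np.linalg.norm(v2 - g1, axis=1).min()
    return float(min(d12, d21))
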