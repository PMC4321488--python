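"""Laboratory-frame crystal-orientation diagnostics.

Each indexed frame carries the reciprocal basis vectors a*, b*, c* in lab
coordinates.  The corresponding real-space axis directions are projected onto
the unit sphere and reported as latitude/longitude so that preferred crystal
orientations (common with loop-mounted goniometer samples) are immediately
visible.

Lab-frame convention (fixed here; remap externally if your geometry differs):
the beam is +z, up is +y and, looking along the beam, right is +x.  Latitude
is asin(v_y), longitude atan2(v_x, v_z), both in degrees, so (0, 0) is along
the beam, North/South are up/down, East/West are right/left.

Crystallographic axes are directions without a sign, so both antipodes of
every axis are emitted.  The density map uses a von Mises-Fisher kernel and
the uniformity test is Bingham's: with the orientation tensor
T = (1/N) sum v v^T, the statistic S = (15N/2) (tr(T^2) - 1/3) is
asymptotically chi-square with 5 degrees of freedom under uniformity; both
are invariant under v -> -v.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .exceptions import DetkitError

logger = logging.getLogger(__name__)

__all__ = [
    "AxisProjection",
    "UniformityResult",
    "real_axes_from_reciprocal",
    "latlong_of_vector",
    "project_axes",
    "spherical_density",
    "bingham_uniformity",
    "axis_vectors_by_label",
    "random_rotations",
]

AXIS_LABELS = ("a", "b", "c")


def real_axes_from_reciprocal(m: np.ndarray, frame_id=None) -> np.ndarray:
    """Unit vectors of the real-space a, b, c axes (rows) from a reciprocal
    orientation matrix whose rows are a*, b*, c* in lab coordinates (A^-1).

    Uses the duality a = (b* x c*)/V*, etc., with V* = a* . (b* x c*);
    before normalization each real axis satisfies a . a* = 1.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise DetkitError(f"orientation matrix must be 3x3, got {m.shape}")
    astar, bstar, cstar = m
    vstar = float(np.dot(astar, np.cross(bstar, cstar)))
    if abs(vstar) < 1e-30 or not np.isfinite(vstar):
        raise DetkitError(
            f"singular orientation matrix"
            + (f" for frame {frame_id}" if frame_id is not None else "")
        )
    axes = np.stack(
        [np.cross(bstar, cstar), np.cross(cstar, astar), np.cross(astar, bstar)]
    ) / vstar
    return axes / np.linalg.norm(axes, axis=1, keepdims=True)


def latlong_of_vector(v: np.ndarray) -> tuple[float, float]:
    """(latitude, longitude) in degrees of a lab-frame unit vector.

    Convention: beam +z, up +y, right +x; lat = asin(v_y),
    lon = atan2(v_x, v_z) in (-180, 180].
    """
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-30:
        raise DetkitError("cannot project a zero vector")
    if abs(norm - 1.0) > 1e-9:
        raise DetkitError(f"vector must be unit length, |v| = {norm!r}")
    lat = float(np.degrees(np.arcsin(np.clip(v[1], -1, 1))))
    lon = float(np.degrees(np.arctan2(v[0], v[2])))
    if lon <= -180.0:
        lon = 180.0
    return lat, lon


@dataclass(frozen=True)
class AxisProjection:
    """Lat/long of one real-space axis direction of one frame."""

    axis: str  # "a", "b" or "c"
    latitude: float
    longitude: float
    frame_id: object = None

    def unit_vector(self) -> np.ndarray:
        lat = np.radians(self.latitude)
        lon = np.radians(self.longitude)
        return np.array(
            [np.cos(lat) * np.sin(lon), np.sin(lat), np.cos(lat) * np.cos(lon)]
        )


def project_axes(frames) -> list[AxisProjection]:
    """Project the real-space axes of every oriented frame; both antipodes
    of each axis are emitted (axes carry no sign).  Frames without an
    orientation matrix are skipped with a logged count."""
    projections = []
    skipped = 0
    for frame in frames:
        if frame.orientation is None:
            skipped += 1
            continue
        axes = real_axes_from_reciprocal(frame.orientation, frame_id=frame.frame_id)
        for label, v in zip(AXIS_LABELS, axes):
            for sign in (1.0, -1.0):
                lat, lon = latlong_of_vector(sign * v)
                projections.append(
                    AxisProjection(axis=label, latitude=lat, longitude=lon, frame_id=frame.frame_id)
                )
    if skipped:
        logger.warning("project_axes: skipped %d frames without orientation", skipped)
    return projections


def spherical_density(
    projections,
    kappa: float = 50.0,
    grid_step: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """von Mises-Fisher kernel density of axis directions on a lat/long grid.

    f(u) = (1/N) sum_i c(kappa) exp(kappa u . v_i) with
    c(kappa) = kappa / (4 pi sinh kappa); the default kappa = 50 gives a
    kernel FWHM of about 20 degrees.  Returns (lat_deg, lon_deg, density)
    with density of shape (n_lat, n_lon); integrating density over the
    sphere (cos(lat) area weights) gives 1.
    """
    if kappa <= 0:
        raise DetkitError(f"kappa must be positive, got {kappa}")
    vecs = _as_unit_vectors(projections)
    if vecs.shape[0] == 0:
        raise DetkitError("spherical_density needs at least one projection")
    lat = np.arange(-90.0 + grid_step / 2, 90.0, grid_step)
    lon = np.arange(-180.0 + grid_step / 2, 180.0, grid_step)
    lat_r = np.radians(lat)[:, None]
    lon_r = np.radians(lon)[None, :]
    grid = np.stack(
        [
            np.cos(lat_r) * np.sin(lon_r) * np.ones_like(lon_r),
            np.sin(lat_r) * np.ones_like(lon_r),
            np.cos(lat_r) * np.cos(lon_r),
        ],
        axis=-1,
    )  # (n_lat, n_lon, 3)
    t = np.tensordot(grid, vecs.T, axes=1)  # (n_lat, n_lon, N)
    # c(k) e^{k t} = k/(2 pi) * e^{k(t-1)} / (1 - e^{-2k}), stable for large k
    dens = (
        kappa
        / (2 * np.pi * (1 - np.exp(-2 * kappa)))
        * np.exp(kappa * (t - 1.0)).mean(axis=-1)
    )
    return lat, lon, dens


def _as_unit_vectors(projections) -> np.ndarray:
    if isinstance(projections, np.ndarray):
        v = np.atleast_2d(np.asarray(projections, dtype=float))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    return np.array([p.unit_vector() for p in projections]).reshape(-1, 3)


@dataclass(frozen=True)
class UniformityResult:
    """Bingham test of uniformity for axial data."""

    eigenvalues: np.ndarray  # tau1 >= tau2 >= tau3, sum 1
    statistic: float  # S, asymptotically chi^2_5 under uniformity
    p_value: float
    n: int


def bingham_uniformity(axes: np.ndarray, min_n: int = 10) -> UniformityResult:
    """Bingham test on axial unit vectors (one per frame per axis;
    antipodes must be deduplicated since v v^T is sign-invariant).

    S = (15 N / 2) (tr(T^2) - 1/3) with T the orientation tensor; the
    p-value is from the chi-square distribution with 5 df.
    """
    v = _as_unit_vectors(axes)
    n = v.shape[0]
    if n < min_n:
        raise DetkitError(f"Bingham test needs at least {min_n} axes, got {n}")
    t = v.T @ v / n
    s = 7.5 * n * (np.trace(t @ t) - 1.0 / 3.0)
    tau = np.sort(np.linalg.eigvalsh(t))[::-1]
    return UniformityResult(
        eigenvalues=tau,
        statistic=float(s),
        p_value=float(chi2.sf(s, df=5)),
        n=n,
    )


def axis_vectors_by_label(frames) -> dict[str, np.ndarray]:
    """One unit vector per oriented frame for each of the a, b, c axes
    (single representative, no antipodes) -- the input to the Bingham test."""
    out: dict[str, list] = {label: [] for label in AXIS_LABELS}
    for frame in frames:
        if frame.orientation is None:
            continue
        axes = real_axes_from_reciprocal(frame.orientation, frame_id=frame.frame_id)
        for label, v in zip(AXIS_LABELS, axes):
            out[label].append(v)
    return {label: np.array(vs).reshape(-1, 3) for label, vs in out.items()}


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform random rotation matrices from normalized Gaussian
    quaternions (Haar measure on SO(3))."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
        ],
        axis=1,
    )
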