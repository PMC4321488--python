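"""Pseudo-Wilson intensity statistics on raw partial intensities.

For each frame an ordinary least-squares line is fitted to
ln(I_partial) versus (sin(theta)/lambda)^2; the gradient is -2B and the
intercept ln(G), so B is a per-frame "pseudo-Wilson" temperature factor and
G a per-frame scale.  "Pseudo" because the intensities are partial and
unnormalized: no multiplicity/epsilon normalization or partiality correction
is applied, so B and G are diagnostics for comparing frames, not absolute
Wilson statistics.

Natural logarithms are used throughout; the intercept is reported both as
ln(G) and as G = exp(intercept).

Frames whose fitted slope or intercept is extreme relative to the rest of
the dataset (robust z-score on median/MAD) are flagged as likely mis-indexed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cells import UnitCell, metric_tensor
from .exceptions import DetkitError, InvalidCellError
from .frames import Frame

logger = logging.getLogger(__name__)

__all__ = [
    "WilsonFit",
    "AggregateStats",
    "s2_of_reflection",
    "s2_of_reflections",
    "frame_wilson_fit",
    "rolling_average",
    "aggregate_intensity_stats",
    "flag_outlier_frames",
]

MIN_REFLECTIONS = 10
ROBUST_Z_DEFAULT = 3.5
_MAD_SCALE = 1.4826  # MAD -> sigma for a normal distribution


def s2_of_reflections(cell: UnitCell, hkl: np.ndarray) -> np.ndarray:
    """(sin(theta)/lambda)^2 in A^-2 for an (n, 3) array of Miller indices.

    1/d^2 = h^T G^-1 h with G the real-space metric tensor; s^2 = 1/(4 d^2).
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    g = metric_tensor(cell)
    try:
        g_inv = np.linalg.inv(g)
    except np.linalg.LinAlgError as exc:
        raise InvalidCellError(f"singular metric tensor for cell {cell.parameters}") from exc
    inv_d2 = np.einsum("ni,ij,nj->n", hkl, g_inv, hkl)
    return inv_d2 / 4.0


def s2_of_reflection(cell: UnitCell, hkl) -> float:
    """Scalar version of :func:`s2_of_reflections`."""
    if tuple(hkl) == (0, 0, 0):
        raise DetkitError("reflection (0,0,0) has no scattering angle")
    return float(s2_of_reflections(cell, np.asarray(hkl)[None, :])[0])


@dataclass(frozen=True)
class WilsonFit:
    """Per-frame pseudo-Wilson regression result.

    slope = -2B (A^2), intercept = ln G; standard errors are the OLS ones.
    """

    frame_id: str
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    n_used: int
    n_dropped_nonpositive: int

    @property
    def b_factor(self) -> float:
        return -self.slope / 2.0

    @property
    def se_b(self) -> float:
        return self.se_slope / 2.0

    @property
    def scale_g(self) -> float:
        return float(np.exp(self.intercept))


def frame_wilson_fit(frame: Frame, min_reflections: int = MIN_REFLECTIONS) -> WilsonFit | None:
    """OLS fit of ln(I_partial) on s^2 for one frame.

    Reflections with I_partial <= 0 are dropped (log undefined) and counted.
    Returns None (fit refused, logged) when fewer than ``min_reflections``
    positive intensities remain or the s^2 values have zero spread.
    """
    if frame.n_reflections == 0:
        logger.info("frame %s: no reflections, fit refused", frame.frame_id)
        return None
    intensities = frame.intensity_array()
    positive = intensities > 0
    n_dropped = int((~positive).sum())
    if positive.sum() < min_reflections:
        logger.info(
            "frame %s: only %d positive intensities (< %d), fit refused",
            frame.frame_id, int(positive.sum()), min_reflections,
        )
        return None
    x = s2_of_reflections(frame.cell, frame.hkl_array()[positive])
    y = np.log(intensities[positive])
    if np.ptp(x) == 0:
        logger.info("frame %s: zero variance in s^2, fit refused", frame.frame_id)
        return None
    res = stats.linregress(x, y)
    return WilsonFit(
        frame_id=frame.frame_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        n_used=int(positive.sum()),
        n_dropped_nonpositive=n_dropped,
    )


def rolling_average(x: np.ndarray, y: np.ndarray, window: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving mean of y over x-sorted points.

    Returns (x_centers, y_means), each of length n - window + 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if window < 1:
        raise DetkitError(f"window must be >= 1, got {window}")
    if window > n:
        raise DetkitError(f"window {window} exceeds number of points {n}")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    kernel = np.ones(window) / window
    return np.convolve(xs, kernel, mode="valid"), np.convolve(ys, kernel, mode="valid")


def fits_to_table(fits: list[WilsonFit]) -> pd.DataFrame:
    rows = [
        {
            "frame_id": f.frame_id,
            "slope": f.slope,
            "intercept": f.intercept,
            "B": f.b_factor,
            "G": f.scale_g,
            "se_slope": f.se_slope,
            "se_intercept": f.se_intercept,
            "n_used": f.n_used,
            "n_dropped_nonpositive": f.n_dropped_nonpositive,
        }
        for f in fits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "frame_id", "slope", "intercept", "B", "G",
            "se_slope", "se_intercept", "n_used", "n_dropped_nonpositive",
        ],
    )


@dataclass
class AggregateStats:
    """Dataset-level pseudo-Wilson summary.

    ``fits`` has one row per successfully fitted frame; ``pooled`` is the
    point cloud of (s^2, ln I) over all frames; ``pooled_slope`` /
    ``pooled_intercept`` are the OLS line through the pooled cloud;
    histograms cover the per-frame gradients and OLS standard errors.
    """

    fits: pd.DataFrame
    pooled: pd.DataFrame
    pooled_slope: float
    pooled_intercept: float
    n_refused: int
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    flags: pd.Series | None = None

    @property
    def trend(self) -> str:
        """Sign of the pooled slope ('decreasing' is the healthy Wilson-like
        behaviour of intensity with scattering angle)."""
        return "decreasing" if self.pooled_slope < 0 else "non-decreasing"


def aggregate_intensity_stats(
    frames: list[Frame],
    min_reflections: int = MIN_REFLECTIONS,
    n_bins: int = 30,
) -> AggregateStats:
    """Per-frame fits, pooled (s^2, ln I) cloud with a pooled OLS line, and
    histograms of gradients and standard errors."""
    fits = []
    pooled_x, pooled_y, pooled_id = [], [], []
    n_refused = 0
    for frame in frames:
        fit = frame_wilson_fit(frame, min_reflections=min_reflections)
        if fit is None:
            n_refused += 1
            continue
        fits.append(fit)
        intensities = frame.intensity_array()
        positive = intensities > 0
        x = s2_of_reflections(frame.cell, frame.hkl_array()[positive])
        pooled_x.append(x)
        pooled_y.append(np.log(intensities[positive]))
        pooled_id.extend([frame.frame_id] * int(positive.sum()))
    if not fits:
        raise DetkitError("no frame had enough positive reflections for a fit")
    x = np.concatenate(pooled_x)
    y = np.concatenate(pooled_y)
    res = stats.linregress(x, y)
    table = fits_to_table(fits)
    histograms = {
        key: np.histogram(table[col], bins=n_bins)
        for key, col in [
            ("gradient", "slope"),
            ("se_slope", "se_slope"),
            ("se_intercept", "se_intercept"),
        ]
    }
    pooled = pd.DataFrame({"frame_id": pooled_id, "s2": x, "log_i": y})
    return AggregateStats(
        fits=table,
        pooled=pooled,
        pooled_slope=float(res.slope),
        pooled_intercept=float(res.intercept),
        n_refused=n_refused,
        histograms=histograms,
    )


def flag_outlier_frames(
    fits: pd.DataFrame | list[WilsonFit], robust_z: float = ROBUST_Z_DEFAULT
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag frames whose gradient or intercept is a robust outlier.

    A frame is flagged iff |x - median| / (1.4826 MAD) > robust_z for
    x = slope or x = intercept.  When the MAD of a column is zero but the
    values are not all identical, flagging falls back to exact mismatch with
    the median (logged).  Returns (flags aligned with the input rows, the
    surviving subset).
    """
    table = fits if isinstance(fits, pd.DataFrame) else fits_to_table(fits)
    if len(table) < 5:
        raise DetkitError(f"outlier filter needs >= 5 fits, got {len(table)}")
    flagged = np.zeros(len(table), dtype=bool)
    for col in ("slope", "intercept"):
        values = table[col].to_numpy()
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        if mad == 0:
            if np.any(values != med):
                logger.warning(
                    "flag_outlier_frames: zero MAD for %s, falling back to "
                    "exact-match filtering", col,
                )
                flagged |= values != med
            continue
        flagged |= np.abs(values - med) / (_MAD_SCALE * mad) > robust_z
    flags = pd.Series(flagged, index=table.index, name="flagged")
    return flags, table[~flagged]
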