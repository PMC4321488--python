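"""Synthetic serial-diffraction datasets with known ground truth.

The generator emulates the statistical structure the toolkit is meant to
diagnose in real serial data:

* a mixture of unit-cell populations (defaults: two orthorhombic forms with
  median edges (69, 169, 288) A and (69, 146, 170) A, weighted 249:69),
  with Gaussian jitter on the reduced-cell parameters;
* crystal orientations either uniform on SO(3) or with a preferred-axis
  bias: the real-space a axis is drawn from a von Mises-Fisher distribution
  about a mean lab direction, with a uniform spin about it;
* Wilson-model partial intensities
  I = G exp(-2 B s^2) * partiality * lognormal-noise, with per-frame B and
  G drawn from across-frame distributions;
* a mis-indexed contaminant fraction: those frames keep intensities
  generated under their true lattice but record a *scrambled* cell (drawn
  from a different population, axes randomly permuted), and the recorded
  Miller indices are paired with unrelated reflections of the true lattice
  -- a wrong indexing solution assigns indices that bear no relation to the
  spots actually integrated.  The s^2 values a downstream fit computes from
  the recorded cell are therefore uncorrelated with the intensities and the
  fitted slope/intercept is aberrant.

Everything is driven by one integer seed; regenerating with the same config
is bit-identical.  What this generator does NOT emulate: spot shapes,
detector noise models, absorption, resolution-dependent completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import UnitCell
from .exceptions import DetkitError
from .frames import Frame, Reflection
from .orientation import random_rotations

__all__ = [
    "Population",
    "OrientationModel",
    "IntensityModel",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate",
    "default_two_form_config",
]

LONG_CELL = UnitCell(69.0, 169.0, 288.0, 90.0, 90.0, 90.0)
SHORT_CELL = UnitCell(69.0, 146.0, 170.0, 90.0, 90.0, 90.0)


@dataclass(frozen=True)
class Population:
    """One unit-cell population: a median cell plus per-parameter jitter."""

    cell: UnitCell
    jitter_lengths: float = 0.5  # A, per edge
    jitter_angles: float = 0.1  # degrees, per angle
    weight: float = 1.0


@dataclass(frozen=True)
class OrientationModel:
    """'uniform' rotations, or 'vmf': a-axis ~ vMF(mean_direction, kappa_bias)."""

    kind: str = "uniform"
    mean_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    kappa_bias: float = 5.0


@dataclass(frozen=True)
class IntensityModel:
    """Wilson-model partial intensities.

    Per frame: B ~ Normal(b_mean, b_sigma^2) (A^2), ln G ~ Normal(log_g_mean,
    log_g_sigma^2).  Per reflection: s^2 uniform on [s2_min, s2_max] (A^-2),
    partiality uniform on [partiality_min, partiality_max], multiplicative
    lognormal noise with log-sd noise_sigma.
    """

    b_mean: float = 15.0
    b_sigma: float = 2.0
    log_g_mean: float = math.log(100.0)
    log_g_sigma: float = 0.3
    n_reflections: int = 150
    s2_min: float = 0.001
    s2_max: float = 0.0625
    noise_sigma: float = 0.3
    partiality_min: float = 0.1
    partiality_max: float = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    populations: tuple[Population, ...]
    n_frames: int
    orientation: OrientationModel = field(default_factory=OrientationModel)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    misindex_fraction: float = 0.0
    wavelength: float = 1.3  # A
    seed: int = 0

    def validate(self) -> None:
        if not self.populations:
            raise DetkitError("config needs at least one population")
        weights = np.array([p.weight for p in self.populations], dtype=float)
        if np.any(weights <= 0):
            raise DetkitError("population weights must be positive")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise DetkitError(f"population weights must sum to 1, got {weights.sum()!r}")
        for p in self.populations:
            if p.jitter_lengths < 0 or p.jitter_angles < 0:
                raise DetkitError("jitter sigmas must be non-negative")
        if self.n_frames < 0:
            raise DetkitError("n_frames must be non-negative")
        if not 0 <= self.misindex_fraction < 1:
            raise DetkitError("misindex_fraction must be in [0, 1)")
        if self.orientation.kind not in ("uniform", "vmf"):
            raise DetkitError(f"unknown orientation model {self.orientation.kind!r}")
        im = self.intensity
        if im.n_reflections < 1:
            raise DetkitError("n_reflections must be >= 1")
        if not 0 < im.s2_min < im.s2_max:
            raise DetkitError("need 0 < s2_min < s2_max")
        if not 0 < im.partiality_min <= im.partiality_max <= 1:
            raise DetkitError("need 0 < partiality_min <= partiality_max <= 1")
        if im.noise_sigma < 0 or im.b_sigma < 0 or im.log_g_sigma < 0:
            raise DetkitError("model sigmas must be non-negative")


@dataclass
class SyntheticDataset:
    """Generated frames plus per-frame ground truth.

    ``truth`` columns: frame_id, population (of the *recorded* cell -- what
    unit-cell clustering can recover), population_true (the lattice that
    generated the intensities; differs only for mis-indexed frames),
    misindexed, b_true, g_true, a_axis_{x,y,z} (true lab direction of the
    real-space a axis).
    """

    frames: list[Frame]
    truth: pd.DataFrame
    config: SyntheticConfig


def default_two_form_config(
    n_frames: int = 318, seed: int = 0, misindex_fraction: float = 0.1
) -> SyntheticConfig:
    """Two-form goniometer-style dataset: long cell (69, 169, 288) A and
    short cell (69, 146, 170) A, weighted 249:69, with a-axis orientation
    bias and 10% mis-indexed contaminants by default."""
    return SyntheticConfig(
        populations=(
            Population(LONG_CELL, weight=249.0 / 318.0),
            Population(SHORT_CELL, weight=69.0 / 318.0),
        ),
        n_frames=n_frames,
        orientation=OrientationModel(kind="vmf", mean_direction=(0.0, 1.0, 0.0), kappa_bias=5.0),
        misindex_fraction=misindex_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def real_basis_matrix(cell: UnitCell) -> np.ndarray:
    """Real-space basis vectors as rows (standard orientation: a along x,
    b in the xy plane)."""
    a, b, c = cell.lengths
    ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
    sg = math.sin(math.radians(cell.gamma))
    v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
    return np.array(
        [
            [a, 0.0, 0.0],
            [b * cg, b * sg, 0.0],
            [c * cb, c * (ca - cb * cg) / sg, c * v / sg],
        ]
    )


def reciprocal_basis_matrix(cell: UnitCell) -> np.ndarray:
    """Reciprocal basis vectors as rows (A^-1), dual to real_basis_matrix."""
    return np.linalg.inv(real_basis_matrix(cell)).T


def _sample_vmf(mean: np.ndarray, kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n unit vectors from the von Mises-Fisher distribution on S^2."""
    mean = np.asarray(mean, dtype=float)
    mean = mean / np.linalg.norm(mean)
    u = rng.random(n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    theta = rng.random(n) * 2.0 * np.pi
    helper = np.array([1.0, 0.0, 0.0])
    if abs(mean @ helper) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(mean, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mean, e1)
    sin_part = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    return (
        w[:, None] * mean
        + (sin_part * np.cos(theta))[:, None] * e1
        + (sin_part * np.sin(theta))[:, None] * e2
    )


def _rotation_taking_x_to(d: np.ndarray, spin: float) -> np.ndarray:
    """Rotation R with R x_hat = d, after a spin about x_hat by ``spin``."""
    d = d / np.linalg.norm(d)
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    r0 = np.column_stack([d, e1, e2])
    cs, sn = math.cos(spin), math.sin(spin)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cs, -sn], [0.0, sn, cs]])
    return r0 @ rx


_PERMUTATIONS = [(0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]  # non-identity


def _permute_cell(cell: UnitCell, perm: tuple[int, int, int]) -> UnitCell:
    """Permute the cell axes (angles follow their opposite edges)."""
    lengths = [cell.lengths[i] for i in perm]
    angles = [cell.angles[i] for i in perm]
    return UnitCell(*lengths, *angles)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _jittered_cell(pop: Population, rng: np.random.Generator) -> UnitCell:
    lengths = np.array(pop.cell.lengths) + rng.normal(0.0, 1.0, 3) * pop.jitter_lengths
    angles = np.array(pop.cell.angles) + rng.normal(0.0, 1.0, 3) * pop.jitter_angles
    return UnitCell(*lengths, *angles)


def _sample_hkl(cell: UnitCell, s2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Miller indices whose resolution is close to the requested s^2 values:
    a random point on the |q| = 2 sqrt(s^2) sphere is snapped to the nearest
    lattice point of ``cell``."""
    n = s2.size
    real = real_basis_matrix(cell)
    out = np.zeros((n, 3), dtype=int)
    todo = np.arange(n)
    while todo.size:
        u = rng.standard_normal((todo.size, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        q = 2.0 * np.sqrt(s2[todo])[:, None] * u
        hkl = np.rint(q @ real.T).astype(int)
        good = np.any(hkl != 0, axis=1)
        out[todo[good]] = hkl[good]
        todo = todo[~good]
    return out


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a dataset (frames + ground truth) from a config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    pops = config.populations
    weights = np.array([p.weight for p in pops], dtype=float)
    weights /= weights.sum()
    im = config.intensity

    pop_idx = rng.choice(len(pops), size=n, p=weights)
    misindexed = rng.random(n) < config.misindex_fraction

    if config.orientation.kind == "uniform":
        rotations = random_rotations(n, rng)
    else:
        directions = _sample_vmf(
            np.asarray(config.orientation.mean_direction, dtype=float),
            config.orientation.kappa_bias,
            n,
            rng,
        )
        spins = rng.random(n) * 2.0 * np.pi
        rotations = np.stack(
            [_rotation_taking_x_to(d, s) for d, s in zip(directions, spins)]
        ) if n else np.zeros((0, 3, 3))

    frames: list[Frame] = []
    truth_rows = []
    for i in range(n):
        true_pop = int(pop_idx[i])
        true_cell = _jittered_cell(pops[true_pop], rng)
        if misindexed[i]:
            others = [j for j in range(len(pops)) if j != true_pop] or [true_pop]
            rec_pop = int(others[rng.integers(len(others))])
            perm = _PERMUTATIONS[rng.integers(len(_PERMUTATIONS))]
            recorded_cell = _permute_cell(_jittered_cell(pops[rec_pop], rng), perm)
        else:
            rec_pop = true_pop
            recorded_cell = true_cell

        b_true = rng.normal(im.b_mean, im.b_sigma)
        g_true = math.exp(rng.normal(im.log_g_mean, im.log_g_sigma))

        s2_req = rng.uniform(im.s2_min, im.s2_max, im.n_reflections)
        hkl = _sample_hkl(recorded_cell, s2_req, rng)
        # intensities follow the *true* lattice; for mis-indexed frames the
        # recorded cell (hence any downstream s^2) disagrees with it
        g_true_metric = np.linalg.inv(
            real_basis_matrix(true_cell) @ real_basis_matrix(true_cell).T
        )
        s2_true = np.einsum("ni,ij,nj->n", hkl.astype(float), g_true_metric, hkl.astype(float)) / 4.0
        if misindexed[i]:
            # a wrong-lattice indexing solution pairs each recorded index
            # with the intensity of an unrelated reflection of the true
            # lattice: break the pairing entirely
            s2_true = rng.permutation(s2_true)
        partiality = rng.uniform(im.partiality_min, im.partiality_max, im.n_reflections)
        noise = (
            np.exp(rng.normal(0.0, im.noise_sigma, im.n_reflections))
            if im.noise_sigma > 0
            else np.ones(im.n_reflections)
        )
        intensities = g_true * np.exp(-2.0 * b_true * s2_true) * partiality * noise
        sigma_i = intensities * max(im.noise_sigma, 0.01)

        reflections = [
            Reflection(int(h), int(k), int(l), float(ii), float(si))
            for (h, k, l), ii, si in zip(hkl, intensities, sigma_i)
        ]
        rot = rotations[i]
        orientation = reciprocal_basis_matrix(recorded_cell) @ rot.T
        frame_id = f"synth-{i:05d}"
        frames.append(
            Frame(
                frame_id=frame_id,
                cell=recorded_cell,
                orientation=orientation,
                reflections=reflections,
                wavelength=config.wavelength,
                source_file="synthetic",
            )
        )
        a_axis = rot @ np.array([1.0, 0.0, 0.0])
        truth_rows.append(
            {
                "frame_id": frame_id,
                "population": rec_pop,
                "population_true": true_pop,
                "misindexed": bool(misindexed[i]),
                "b_true": b_true,
                "g_true": g_true,
                "a_axis_x": a_axis[0],
                "a_axis_y": a_axis[1],
                "a_axis_z": a_axis[2],
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "frame_id", "population", "population_true", "misindexed",
            "b_true", "g_true", "a_axis_x", "a_axis_y", "a_axis_z",
        ],
    )
    return SyntheticDataset(frames=frames, truth=truth, config=config)
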