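"""Core per-image containers: Reflection and Frame.

A Frame is one diffraction image's integration result: unit cell, optional
lab-frame orientation (reciprocal basis rows a*, b*, c* in A^-1), optional
list of partially recorded reflections, and provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cells import UnitCell
from .exceptions import DetkitError

__all__ = ["Reflection", "Frame"]


@dataclass(frozen=True)
class Reflection:
    """One partially recorded integrated reflection.

    ``i_partial`` is the raw partial intensity in arbitrary detector units;
    no partiality or multiplicity correction is implied.  ``sigma_i`` is its
    standard deviation in the same units (optional).
    """

    h: int
    k: int
    l: int
    i_partial: float
    sigma_i: float | None = None

    def __post_init__(self):
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise DetkitError("reflection (0,0,0) is not allowed")
        for name in ("h", "k", "l"):
            v = getattr(self, name)
            if int(v) != v:
                raise DetkitError(f"Miller index {name} must be an integer, got {v!r}")

    @property
    def hkl(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


@dataclass
class Frame:
    """One image's integration result."""

    frame_id: str
    cell: UnitCell
    orientation: np.ndarray | None = None  # rows a*, b*, c* in lab coords, A^-1
    reflections: list[Reflection] = field(default_factory=list)
    wavelength: float | None = None  # A
    source_file: str | None = None
    extra: dict = field(default_factory=dict)  # unknown fields, preserved on round trip

    def __post_init__(self):
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=float)
            if self.orientation.shape != (3, 3):
                raise DetkitError(
                    f"frame {self.frame_id}: orientation must be 3x3, "
                    f"got {self.orientation.shape}"
                )

    @property
    def n_reflections(self) -> int:
        return len(self.reflections)

    def hkl_array(self) -> np.ndarray:
        return np.array([r.hkl for r in self.reflections], dtype=int).reshape(-1, 3)

    def intensity_array(self) -> np.ndarray:
        return np.array([r.i_partial for r in self.reflections], dtype=float)
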