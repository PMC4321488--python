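"""Readers and writers for per-frame serial diffraction data.

Three formats are supported:

* native JSON ("det-frames-v1") -- the canonical, lossless interchange
  format of this package.  Schema (one object)::

      {
        "format": "det-frames-v1",
        "frames": [
          {
            "frame_id": str,
            "cell": [a, b, c, alpha, beta, gamma],      # A / degrees
            "orientation": [[...3],[...3],[...3]]|null, # rows a*,b*,c*, A^-1
            "wavelength": float|null,                   # A
            "source_file": str|null,
            "reflections": [[h, k, l, i_partial, sigma_i|null], ...],
            ... any unknown keys are preserved on round trip ...
          }, ...
        ]
      }

* a read-only subset of the CrystFEL text stream format: per-chunk cell
  parameters (nm/deg -> A/deg, lengths x10), reciprocal axes astar/bstar/
  cstar (nm^-1 -> A^-1, x0.1) and the h k l I sigma(I) reflection columns.
  Chunks without a crystal yield no Frame; malformed chunks are skipped with
  a logged line number.

* CSV reflection tables (columns h, k, l, i_partial, sigma_i), lossless to
  12 significant digits.
"""

from __future__ import annotations

import glob as _glob
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import UnitCell
from .exceptions import DetkitError, SchemaError, StreamParseError
from .frames import Frame, Reflection

logger = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "Reflection",
    "FORMAT_TAG",
    "read_frames_json",
    "write_frames_json",
    "read_crystfel_stream",
    "read_reflections_csv",
    "write_reflections_csv",
    "load_frames",
]

FORMAT_TAG = "det-frames-v1"
_KNOWN_KEYS = {"frame_id", "cell", "orientation", "wavelength", "source_file", "reflections"}


# ---------------------------------------------------------------------------
# native JSON
# ---------------------------------------------------------------------------


def _frame_to_dict(frame: Frame) -> dict:
    d = {
        "frame_id": frame.frame_id,
        "cell": list(frame.cell.parameters),
        "orientation": None
        if frame.orientation is None
        else [[float(x) for x in row] for row in frame.orientation],
        "wavelength": frame.wavelength,
        "source_file": frame.source_file,
        "reflections": [
            [r.h, r.k, r.l, r.i_partial, r.sigma_i] for r in frame.reflections
        ],
    }
    d.update(frame.extra)
    return d


def _frame_from_dict(d: dict, index: int) -> Frame:
    if not isinstance(d, dict):
        raise SchemaError("frame entry is not an object", frame_index=index)
    for key in ("frame_id", "cell"):
        if key not in d:
            raise SchemaError("missing required field", field=key, frame_index=index)
    cell = d["cell"]
    if not (isinstance(cell, (list, tuple)) and len(cell) == 6):
        raise SchemaError("cell must be a list of 6 numbers", field="cell", frame_index=index)
    try:
        unit_cell = UnitCell(*[float(x) for x in cell])
    except (TypeError, ValueError, DetkitError) as exc:
        raise SchemaError(f"invalid cell: {exc}", field="cell", frame_index=index) from exc
    orientation = d.get("orientation")
    if orientation is not None:
        arr = np.asarray(orientation, dtype=float)
        if arr.shape != (3, 3):
            raise SchemaError(
                "orientation must be a 3x3 matrix", field="orientation", frame_index=index
            )
        orientation = arr
    reflections = []
    for j, row in enumerate(d.get("reflections") or []):
        if not (isinstance(row, (list, tuple)) and len(row) == 5):
            raise SchemaError(
                f"reflection {j} must be [h, k, l, i_partial, sigma_i]",
                field="reflections", frame_index=index,
            )
        h, k, l, i_partial, sigma = row
        try:
            reflections.append(
                Reflection(
                    int(h), int(k), int(l), float(i_partial),
                    None if sigma is None else float(sigma),
                )
            )
        except (TypeError, ValueError, DetkitError) as exc:
            raise SchemaError(
                f"invalid reflection {j}: {exc}", field="reflections", frame_index=index
            ) from exc
    extra = {k: v for k, v in d.items() if k not in _KNOWN_KEYS}
    return Frame(
        frame_id=str(d["frame_id"]),
        cell=unit_cell,
        orientation=orientation,
        reflections=reflections,
        wavelength=None if d.get("wavelength") is None else float(d["wavelength"]),
        source_file=d.get("source_file"),
        extra=extra,
    )


def read_frames_json(path) -> list[Frame]:
    """Read a det-frames-v1 JSON file into a list of Frames."""
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_TAG:
        raise SchemaError(f"not a {FORMAT_TAG} file: {path}", field="format")
    frames = [_frame_from_dict(d, i) for i, d in enumerate(doc.get("frames", []))]
    seen = set()
    for i, f in enumerate(frames):
        if f.frame_id in seen:
            raise SchemaError(f"duplicate frame_id {f.frame_id!r}", field="frame_id", frame_index=i)
        seen.add(f.frame_id)
    return frames


def write_frames_json(frames: list[Frame], path) -> None:
    """Write frames as det-frames-v1 JSON (lossless, deterministic)."""
    doc = {"format": FORMAT_TAG, "frames": [_frame_to_dict(f) for f in frames]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# CrystFEL stream subset
# ---------------------------------------------------------------------------

_CHUNK_BEGIN = "----- Begin chunk -----"
_CHUNK_END = "----- End chunk -----"
_CRYSTAL_BEGIN = "--- Begin crystal"
_CRYSTAL_END = "--- End crystal"
_REFL_BEGIN = "Reflections measured after indexing"
_REFL_END = "End of reflections"


def _parse_chunk(lines: list[str], first_line_no: int, source: str, index: int) -> Frame | None:
    cell = None
    recip = {}
    reflections = []
    frame_id = None
    wavelength = None
    in_crystal = False
    in_refl = False
    for line in lines:
        s = line.strip()
        if s.startswith("Image filename:"):
            frame_id = s.split(":", 1)[1].strip()
        elif s.startswith("Event:") and frame_id is not None:
            frame_id += s.split(":", 1)[1].strip()
        elif s.startswith(_CRYSTAL_BEGIN):
            in_crystal = True
        elif s.startswith(_CRYSTAL_END):
            in_crystal = False
        elif s.startswith("wavelength =") or s.startswith("incident_wavelength ="):
            try:
                wavelength = float(s.split("=")[1].split()[0])
            except (ValueError, IndexError):
                pass
        elif in_crystal and s.startswith("Cell parameters"):
            # "Cell parameters 6.9 16.9 28.8 nm, 90 90 90 deg"
            body = s[len("Cell parameters"):].replace(",", " ")
            toks = [t for t in body.split() if t not in ("nm", "deg")]
            vals = [float(t) for t in toks[:6]]
            if len(vals) != 6:
                raise ValueError(f"bad cell parameters line: {s!r}")
            cell = UnitCell(
                vals[0] * 10.0, vals[1] * 10.0, vals[2] * 10.0, vals[3], vals[4], vals[5]
            )
        elif in_crystal and s[:5] in ("astar", "bstar", "cstar"):
            # "astar = +0.1448 -0.0366 +0.0306 nm^-1"
            toks = s.split("=")[1].split()
            recip[s[:5]] = [float(t) * 0.1 for t in toks[:3]]
        elif in_crystal and s.startswith(_REFL_BEGIN):
            in_refl = True
        elif in_crystal and s.startswith(_REFL_END):
            in_refl = False
        elif in_refl:
            toks = s.split()
            if len(toks) < 5 or toks[0] in ("h", "#"):
                continue
            h, k, l = int(toks[0]), int(toks[1]), int(toks[2])
            if (h, k, l) == (0, 0, 0):
                continue
            reflections.append(Reflection(h, k, l, float(toks[3]), float(toks[4])))
    if cell is None:
        return None  # chunk without an indexed crystal
    orientation = None
    if set(recip) == {"astar", "bstar", "cstar"}:
        orientation = np.array([recip["astar"], recip["bstar"], recip["cstar"]])
    return Frame(
        frame_id=frame_id or f"{source}#chunk{index}",
        cell=cell,
        orientation=orientation,
        reflections=reflections,
        wavelength=wavelength,
        source_file=source,
    )


def read_crystfel_stream(path) -> list[Frame]:
    """Parse the supported subset of a CrystFEL stream.

    Lengths are converted nm -> A (x10) and reciprocal axes nm^-1 -> A^-1
    (x0.1).  Returns one Frame per indexed chunk; raises
    :class:`StreamParseError` if no chunk could be parsed.
    """
    path = Path(path)
    frames: list[Frame] = []
    chunk_lines: list[str] = []
    chunk_start = 0
    n_chunks = n_skipped = 0
    in_chunk = False
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            s = line.strip()
            if s == _CHUNK_BEGIN:
                in_chunk = True
                chunk_lines = []
                chunk_start = line_no
            elif s == _CHUNK_END:
                if in_chunk:
                    n_chunks += 1
                    try:
                        frame = _parse_chunk(chunk_lines, chunk_start, str(path), n_chunks)
                    except (ValueError, DetkitError) as exc:
                        n_skipped += 1
                        logger.warning(
                            "%s: skipping malformed chunk starting at line %d: %s",
                            path, chunk_start, exc,
                        )
                    else:
                        if frame is not None:
                            frames.append(frame)
                in_chunk = False
            elif in_chunk:
                chunk_lines.append(line)
    if not frames:
        raise StreamParseError(
            f"{path}: no indexed chunks parsed ({n_chunks} chunks seen, {n_skipped} skipped)"
        )
    logger.info(
        "%s: parsed %d frames from %d chunks (%d skipped)", path, len(frames), n_chunks, n_skipped
    )
    # ensure unique ids (streams may repeat filenames across events)
    seen: dict[str, int] = {}
    for f in frames:
        if f.frame_id in seen:
            seen[f.frame_id] += 1
            f.frame_id = f"{f.frame_id}#{seen[f.frame_id]}"
        else:
            seen[f.frame_id] = 0
    return frames


# ---------------------------------------------------------------------------
# CSV reflection tables
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["h", "k", "l", "i_partial", "sigma_i"]


def write_reflections_csv(frame: Frame, path) -> None:
    """Write a frame's reflections as CSV (12 significant digits)."""
    df = pd.DataFrame(
        [[r.h, r.k, r.l, r.i_partial, r.sigma_i] for r in frame.reflections],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_reflections_csv(path) -> list[Reflection]:
    """Read a reflections CSV back into Reflection objects."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise SchemaError(f"reflections CSV {path} missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        for name in ("h", "k", "l"):
            v = getattr(row, name)
            if float(v) != int(v):
                raise SchemaError(f"non-integer Miller index {name}={v!r} in {path}")
        sigma = getattr(row, "sigma_i", None)
        if sigma is not None and (isinstance(sigma, float) and math.isnan(sigma)):
            sigma = None
        out.append(
            Reflection(int(row.h), int(row.k), int(row.l), float(row.i_partial), sigma)
        )
    return out


# ---------------------------------------------------------------------------
# generic loading
# ---------------------------------------------------------------------------


def load_frames(inputs, fmt: str = "json") -> list[Frame]:
    """Load frames from one or more paths/globs in the given format."""
    if isinstance(inputs, (str, Path)):
        inputs = [inputs]
    paths: list[Path] = []
    for item in inputs:
        expanded = sorted(_glob.glob(str(item)))
        if expanded:
            paths.extend(Path(p) for p in expanded)
        elif Path(item).exists():
            paths.append(Path(item))
        else:
            raise DetkitError(f"input not found: {item}")
    if not paths:
        raise DetkitError(f"no input files matched {list(map(str, inputs))}")
    frames: list[Frame] = []
    for p in paths:
        if fmt == "json":
            frames.extend(read_frames_json(p))
        elif fmt == "stream":
            frames.extend(read_crystfel_stream(p))
        else:
            raise DetkitError(f"unknown input format {fmt!r}")
    return frames
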