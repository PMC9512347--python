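"""Domain types for structure sets and their portable on-disk formats.

A *structure set* is one patient's collection of named regions of interest
(ROIs), each ROI a set of closed planar polygons indexed by axial slice on a
fixed pixel grid with uniform slice spacing.

Conventions (fixed here and relied on by the rest of the package):

* Pixel ``(row r, col c)`` has its **center** at continuous coordinates
  ``(x=c, y=r)``.  Polygon vertices live in this continuous pixel frame.
* Slice indices are 0-based and increase toward the patient's superior
  (cranial) direction.
* In-plane axes follow the DICOM-style patient convention: ``+x`` is patient
  left, ``+y`` is posterior.

The portable format is a JSON document (schema below) plus an optional
loss-lessly compressed mask archive (``.npz``) keyed by structure and slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np


class StructureSetError(Exception):
    """Base class for structure-set parse/validation failures."""


class ParseError(StructureSetError):
    pass


class ValidationError(StructureSetError):
    pass


@dataclass(frozen=True)
class ContourPolygon:
    """A closed planar polygon in continuous pixel units.

    ``vertices`` is an (n, 2) float array of (x, y) pairs; the polygon is
    closed implicitly (last vertex connects back to the first).  Fewer than
    3 vertices is degenerate: allowed to exist, but rasterizes to nothing.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError(f"polygon vertices must be (n, 2), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("polygon vertices must be finite")
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def degenerate(self) -> bool:
        return self.n_vertices < 3

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContourPolygon):
            return NotImplemented
        return self.vertices.shape == other.vertices.shape and np.array_equal(
            self.vertices, other.vertices
        )

    def __hash__(self) -> int:  # frozen dataclass wants it; cheap content hash
        return hash(self.vertices.tobytes())


@dataclass
class Structure:
    """One named ROI: a label plus per-slice polygon lists."""

    label: str
    slices: dict[int, list[ContourPolygon]] = field(default_factory=dict)

    def slice_indices(self) -> list[int]:
        """Sorted indices of slices carrying at least one polygon."""
        return sorted(k for k, v in self.slices.items() if v)

    def nonempty_slice_indices(self) -> list[int]:
        """Sorted indices of slices carrying >=1 non-degenerate polygon."""
        return sorted(
            k
            for k, polys in self.slices.items()
            if any(not p.degenerate for p in polys)
        )

    @property
    def slice_count(self) -> int:
        """Number of slices with at least one non-degenerate polygon."""
        return len(self.nonempty_slice_indices())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return self.label == other.label and self.slices == other.slices


@dataclass
class StructureSet:
    """One patient's structures on a fixed grid.

    grid: (n_rows, n_cols); slice_thickness in mm; n_slices total axial
    slices; every structure's slice indices must lie in [0, n_slices).
    """

    patient_id: str
    grid: tuple[int, int]
    slice_thickness: float
    n_slices: int
    structures: list[Structure] = field(default_factory=list)

    def validate(self) -> "StructureSet":
        rows, cols = self.grid
        if rows <= 0 or cols <= 0:
            raise ValidationError(f"grid dims must be positive, got {self.grid}")
        if self.slice_thickness <= 0:
            raise ValidationError(
                f"slice_thickness must be > 0, got {self.slice_thickness}"
            )
        if self.n_slices <= 0:
            raise ValidationError(f"n_slices must be positive, got {self.n_slices}")
        for s in self.structures:
            for idx in s.slices:
                if not (0 <= idx < self.n_slices):
                    raise ValidationError(
                        f"structure {s.label!r} references slice {idx} "
                        f"outside [0, {self.n_slices})"
                    )
        return self

    def find(self, label: str) -> Structure:
        for s in self.structures:
            if s.label == label:
                return s
        raise KeyError(f"no structure labelled {label!r} in patient {self.patient_id}")

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.structures)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureSet):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and tuple(self.grid) == tuple(other.grid)
            and self.slice_thickness == other.slice_thickness
            and self.n_slices == other.n_slices
            and self.structures == other.structures
        )


# ---------------------------------------------------------------------------
# JSON structure-set format
#
# {patient_id, grid:[rows,cols], slice_thickness_mm, n_slices,
#  structures:[{label, slices:{"<index>":[[[x,y],...],...]}}]}
# ---------------------------------------------------------------------------


def _set_to_dict(s: StructureSet) -> dict:
    return {
        "patient_id": s.patient_id,
        "grid": [int(s.grid[0]), int(s.grid[1])],
        "slice_thickness_mm": float(s.slice_thickness),
        "n_slices": int(s.n_slices),
        "structures": [
            {
                "label": st.label,
                "slices": {
                    str(idx): [p.vertices.tolist() for p in polys]
                    for idx, polys in sorted(st.slices.items())
                },
            }
            for st in s.structures
        ],
    }


def write_structure_set(s: StructureSet, path: str | Path) -> Path:
    """Write ``s`` as canonical JSON; identical input gives identical bytes."""
    s.validate()
    path = Path(path)
    text = json.dumps(_set_to_dict(s), sort_keys=True, separators=(",", ":"))
    path.write_text(text + "\n")
    return path


def read_structure_set(path: str | Path) -> StructureSet:
    """Read and validate a JSON structure-set file.

    Unknown (non-TG-263) ROI labels are preserved verbatim; a malformed
    document raises :class:`ParseError` naming the offending field, and an
    invariant violation raises :class:`ValidationError`.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: not valid JSON: {e}") from e

    def req(d: dict, key: str):
        if key not in d:
            raise ParseError(f"{path}: missing required field {key!r}")
        return d[key]

    try:
        grid = req(doc, "grid")
        sset = StructureSet(
            patient_id=str(req(doc, "patient_id")),
            grid=(int(grid[0]), int(grid[1])),
            slice_thickness=float(req(doc, "slice_thickness_mm")),
            n_slices=int(req(doc, "n_slices")),
            structures=[],
        )
        for st in req(doc, "structures"):
            slices: dict[int, list[ContourPolygon]] = {}
            for key, polys in req(st, "slices").items():
                slices[int(key)] = [ContourPolygon(np.asarray(p)) for p in polys]
            sset.structures.append(Structure(label=str(req(st, "label")), slices=slices))
    except (TypeError, ValueError, IndexError) as e:
        raise ParseError(f"{path}: malformed structure-set document: {e}") from e
    return sset.validate()


# ---------------------------------------------------------------------------
# Mask archive: one 2-D uint8 array per (structure, slice), loss-lessly
# compressed, keyed "<structure_index>/<slice_index>".
# ---------------------------------------------------------------------------


def write_mask_archive(
    masks: dict[tuple[int, int], np.ndarray], path: str | Path
) -> Path:
    path = Path(path)
    arrays = {f"{si}/{zi}": np.asarray(m, dtype=np.uint8) for (si, zi), m in masks.items()}
    with open(path, "wb") as f:
        np.savez_compressed(f, **arrays)
    return path


def read_mask_archive(path: str | Path) -> dict[tuple[int, int], np.ndarray]:
    out: dict[tuple[int, int], np.ndarray] = {}
    with np.load(Path(path)) as z:
        for key in z.files:
            si, zi = key.split("/")
            out[(int(si), int(zi))] = z[key]
    return out
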