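"""Coordinate-normalization frames for center-of-mass features.

Four schemes are supported:

* ``UNNORM`` — raw pixel/slice coordinates, unchanged.
* ``NONANAT`` — nonanatomical linear scaling: the in-plane pixel range
  ``[0, n-1]`` maps to ``[-1, 1]`` on both axes; the axial (z) coordinate is
  anchored to the patient's brain, the inferior-most brain slice mapping to
  0 and the superior-most to 1.
* ``ANAT_BRAIN`` — anatomical scaling: the lateral, anterior-posterior and
  cranial-caudal extremes of the rasterized brain map to ``[-1, 1]`` on each
  axis.
* ``ANAT_EYES_BSTEM`` — anatomical scaling anchored on the eyes and
  brainstem: lateral extremes from the union of the two eyes, cranial-caudal
  extremes from the union of eyes and brainstem.  (The anterior-posterior
  reference is likewise taken from the union of the three ROIs, oriented as
  in ``ANAT_BRAIN``; this axis is not pinned down by any single obvious
  choice, so it is kept configurable via the frame fields.)

All maps are affine per axis and never clamp: anatomy outside the reference
extent (esophagus, spinal cord below the brain) legitimately maps outside
the nominal output interval.  Axis orientation: the minimum pixel/slice
coordinate of the reference maps to the lower end of the output range, so
normalized x/y/z increase with column/row/slice index.  No correction is
made for head orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .model import Structure, StructureSet
from .rasterize import rasterize_structure


class Scheme(str, Enum):
    UNNORM = "UNNORM"
    NONANAT = "NONANAT"
    ANAT_BRAIN = "ANAT_BRAIN"
    ANAT_EYES_BSTEM = "ANAT_EYES_BSTEM"


class MissingReferenceError(ValueError):
    """A frame's required reference ROI is absent or empty."""


@dataclass(frozen=True)
class NormalizedPosition:
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class Frame:
    """A coordinate-normalization specification.

    Each ``*_ref`` pair (lo, hi) maps affinely onto the output interval:
    x and y onto (-1, 1); z onto ``z_out_range``.
    """

    scheme: Scheme
    x_ref: tuple[float, float]
    y_ref: tuple[float, float]
    z_ref: tuple[float, float]
    z_out_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.scheme is Scheme.UNNORM:
            return
        for name, (lo, hi) in (
            ("x_ref", self.x_ref),
            ("y_ref", self.y_ref),
            ("z_ref", self.z_ref),
        ):
            if not lo < hi:
                raise MissingReferenceError(
                    f"{name} must satisfy lo < hi, got ({lo}, {hi}); "
                    "the reference anatomy is degenerate along this axis"
                )

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.value,
            "x_ref": list(self.x_ref),
            "y_ref": list(self.y_ref),
            "z_ref": list(self.z_ref),
            "z_out_range": list(self.z_out_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Frame":
        return cls(
            scheme=Scheme(d["scheme"]),
            x_ref=tuple(d["x_ref"]),
            y_ref=tuple(d["y_ref"]),
            z_ref=tuple(d["z_ref"]),
            z_out_range=tuple(d["z_out_range"]),
        )


def _affine(v: float, lo: float, hi: float, out_lo: float, out_hi: float) -> float:
    return out_lo + (out_hi - out_lo) * (v - lo) / (hi - lo)


def apply(frame: Frame, com: tuple[float, float], z: float) -> NormalizedPosition:
    """Map a center of mass ``(x, y)`` and slice index ``z`` through ``frame``.

    Out-of-range inputs extrapolate linearly; nothing is clamped.
    """
    x, y = com
    if frame.scheme is Scheme.UNNORM:
        return NormalizedPosition(float(x), float(y), float(z))
    a, b = frame.z_out_range
    return NormalizedPosition(
        _affine(x, *frame.x_ref, -1.0, 1.0),
        _affine(y, *frame.y_ref, -1.0, 1.0),
        _affine(z, *frame.z_ref, a, b),
    )


def frame_unnormalized() -> Frame:
    return Frame(Scheme.UNNORM, (0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 1.0))


def _brain_z_anchors(brain: Structure) -> tuple[int, int]:
    idx = brain.nonempty_slice_indices()
    if not idx:
        raise MissingReferenceError(
            "nonanatomical/anatomical frames require a nonempty 'Brain' structure"
        )
    return idx[0], idx[-1]


def frame_nonanatomical(grid: tuple[int, int], brain: Structure) -> Frame:
    """Grid-anchored x/y in [-1,1]; z anchored to the brain's slice span in [0,1]."""
    rows, cols = grid
    z_lo, z_hi = _brain_z_anchors(brain)
    return Frame(
        Scheme.NONANAT,
        x_ref=(0.0, float(cols - 1)),
        y_ref=(0.0, float(rows - 1)),
        z_ref=(float(z_lo), float(z_hi)),
        z_out_range=(0.0, 1.0),
    )


def _mask_extremes(masks: dict[int, np.ndarray]) -> tuple[float, float, float, float]:
    """(x_min, x_max, y_min, y_max) over the union of per-slice masks."""
    x_min = y_min = np.inf
    x_max = y_max = -np.inf
    for m in masks.values():
        rr, cc = np.nonzero(m)
        if rr.size == 0:
            continue
        x_min = min(x_min, cc.min())
        x_max = max(x_max, cc.max())
        y_min = min(y_min, rr.min())
        y_max = max(y_max, rr.max())
    if not np.isfinite(x_min):
        raise MissingReferenceError("reference structure rasterizes to an empty mask")
    return float(x_min), float(x_max), float(y_min), float(y_max)


def _require(s: StructureSet, label: str) -> Structure:
    try:
        return s.find(label)
    except KeyError:
        raise MissingReferenceError(
            f"frame requires ROI {label!r}, absent from patient {s.patient_id!r}"
        ) from None


def frame_anatomical_brain(s: StructureSet) -> Frame:
    """Anatomical frame: all three axes anchored to the rasterized brain."""
    brain = _require(s, "Brain")
    masks = rasterize_structure(brain, s.grid)
    if not masks:
        raise MissingReferenceError("'Brain' structure rasterizes to nothing")
    x_min, x_max, y_min, y_max = _mask_extremes(masks)
    z_lo, z_hi = min(masks), max(masks)
    return Frame(
        Scheme.ANAT_BRAIN,
        x_ref=(x_min, x_max),
        y_ref=(y_min, y_max),
        z_ref=(float(z_lo), float(z_hi)),
        z_out_range=(-1.0, 1.0),
    )


def frame_anatomical_eyes_brainstem(s: StructureSet) -> Frame:
    """Anatomical frame anchored on the eyes (lateral) and eyes+brainstem
    (cranial-caudal, anterior-posterior)."""
    eye_l = _require(s, "Eye_L")
    eye_r = _require(s, "Eye_R")
    bstem = _require(s, "Brainstem")
    eye_masks = {("L", k): v for k, v in rasterize_structure(eye_l, s.grid).items()}
    eye_masks.update(
        {("R", k): v for k, v in rasterize_structure(eye_r, s.grid).items()}
    )
    bstem_masks = rasterize_structure(bstem, s.grid)
    if not eye_masks or not bstem_masks:
        raise MissingReferenceError("eyes/brainstem rasterize to nothing")

    x_min, x_max, _, _ = _mask_extremes(eye_masks)
    all_masks = dict(enumerate(eye_masks.values()))
    all_masks.update(
        {len(all_masks) + i: m for i, m in enumerate(bstem_masks.values())}
    )
    _, _, y_min, y_max = _mask_extremes(all_masks)

    z_indices = (
        eye_l.nonempty_slice_indices()
        + eye_r.nonempty_slice_indices()
        + bstem.nonempty_slice_indices()
    )
    z_lo, z_hi = min(z_indices), max(z_indices)
    return Frame(
        Scheme.ANAT_EYES_BSTEM,
        x_ref=(x_min, x_max),
        y_ref=(y_min, y_max),
        z_ref=(float(z_lo), float(z_hi)),
        z_out_range=(-1.0, 1.0),
    )


def build_frame(scheme: Scheme | str, s: StructureSet) -> Frame:
    """Build the frame of the given scheme from one patient's structure set."""
    scheme = Scheme(scheme)
    if scheme is Scheme.UNNORM:
        return frame_unnormalized()
    if scheme is Scheme.NONANAT:
        return frame_nonanatomical(s.grid, _require(s, "Brain"))
    if scheme is Scheme.ANAT_BRAIN:
        return frame_anatomical_brain(s)
    return frame_anatomical_eyes_brainstem(s)
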