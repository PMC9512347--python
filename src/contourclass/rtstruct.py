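"""Optional DICOM RTSTRUCT import adapter.

Converts the standard Structure Set ROI / ROI Contour modules into the
package's native :class:`~contourclass.model.StructureSet`, mapping contour
points from patient-space millimetres to continuous pixel/slice indices.
Only axial ``CLOSED_PLANAR`` contours are supported — every point of a
contour must lie on one axial plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import ContourPolygon, ParseError, Structure, StructureSet


@dataclass(frozen=True)
class GridGeometry:
    """Patient-space to pixel/slice mapping for an axial image stack.

    ``origin`` is the patient-space position (mm) of the center of pixel
    (row 0, col 0) of slice 0; ``spacing`` is (col, row) pixel spacing in
    mm; slices are ``slice_thickness`` mm apart along +z.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float]
    slice_thickness: float
    grid: tuple[int, int]
    n_slices: int

    def to_pixels(self, xyz_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(n,3) patient mm -> ((n,2) pixel xy, (n,) continuous slice index)."""
        x0, y0, z0 = self.origin
        dx, dy = self.spacing
        xy = np.column_stack(
            [(xyz_mm[:, 0] - x0) / dx, (xyz_mm[:, 1] - y0) / dy]
        )
        z = (xyz_mm[:, 2] - z0) / self.slice_thickness
        return xy, z


def import_rtstruct(
    path: str | Path, geometry: GridGeometry, patient_id: str | None = None
) -> StructureSet:
    """Read a DICOM RTSTRUCT file into a validated StructureSet.

    ROI labels are preserved verbatim.  Non-axial or non-CLOSED_PLANAR
    contours raise :class:`ParseError`.
    """
    import pydicom

    if geometry is None:
        raise ValueError("RTSTRUCT import requires a GridGeometry")
    ds = pydicom.dcmread(str(path), force=True)

    names: dict[int, str] = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        names[int(roi.ROINumber)] = str(roi.ROIName)

    structures: list[Structure] = []
    for rc in getattr(ds, "ROIContourSequence", []):
        number = int(rc.ReferencedROINumber)
        label = names.get(number, f"ROI_{number}")
        slices: dict[int, list[ContourPolygon]] = {}
        for c in getattr(rc, "ContourSequence", []):
            gtype = str(getattr(c, "ContourGeometricType", "CLOSED_PLANAR"))
            if gtype != "CLOSED_PLANAR":
                raise ParseError(
                    f"{path}: ROI {label!r} has a {gtype} contour; only "
                    "axial CLOSED_PLANAR contours are supported"
                )
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            if not np.allclose(pts[:, 2], pts[0, 2], atol=1e-6):
                raise ParseError(
                    f"{path}: ROI {label!r} has a non-axial contour "
                    "(z varies within one contour)"
                )
            xy, z = geometry.to_pixels(pts)
            idx = int(round(float(z[0])))
            slices.setdefault(idx, []).append(ContourPolygon(xy))
        structures.append(Structure(label=label, slices=slices))

    sset = StructureSet(
        patient_id=patient_id or str(getattr(ds, "PatientID", "UNKNOWN")),
        grid=geometry.grid,
        slice_thickness=geometry.slice_thickness,
        n_slices=geometry.n_slices,
        structures=structures,
    )
    return sset.validate()
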