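"""Polygon-to-mask conversion and per-slice geometric features.

A contour polygon is converted to a binary mask by testing, for every pixel,
whether the pixel *center* lies inside the contour — no subsampling or
supersampling.  The inside test is the even-odd (ray-crossing) rule; a pixel
center lying exactly on a polygon edge counts as inside.  Multiple polygons
of one ROI on one slice are unioned into a single mask (and hence a single
center of mass); within a single self-overlapping polygon, overlap flips
parity under the even-odd rule.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .model import ContourPolygon, Structure

log = logging.getLogger(__name__)

#: Tolerance for the "pixel center exactly on an edge" test, in pixel units.
_EDGE_TOL = 1e-9


class EmptyMaskError(ValueError):
    """Raised when a geometric feature is requested of an all-zero mask."""


def _single_polygon_mask(vertices: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Even-odd rasterization of one polygon; boundary-inclusive."""
    rows, cols = grid
    mask = np.zeros((rows, cols), dtype=np.uint8)

    xs_min, ys_min = vertices.min(axis=0)
    xs_max, ys_max = vertices.max(axis=0)
    c_lo = max(0, math.ceil(xs_min - _EDGE_TOL))
    c_hi = min(cols - 1, math.floor(xs_max + _EDGE_TOL))
    r_lo = max(0, math.ceil(ys_min - _EDGE_TOL))
    r_hi = min(rows - 1, math.floor(ys_max + _EDGE_TOL))
    if c_lo > c_hi or r_lo > r_hi:
        return mask

    px = np.arange(c_lo, c_hi + 1, dtype=float)  # pixel-center x (cols)
    py = np.arange(r_lo, r_hi + 1, dtype=float)  # pixel-center y (rows)

    inside = np.zeros((py.size, px.size), dtype=bool)
    on_edge = np.zeros_like(inside)

    v1 = vertices
    v2 = np.roll(vertices, -1, axis=0)
    for (x1, y1), (x2, y2) in zip(v1, v2):
        # Parity toggle: edge straddles the horizontal line through py and
        # the rightward ray from the pixel center crosses it.
        straddle = (y1 > py) != (y2 > py)
        if np.any(straddle):
            x_int = x1 + (py[straddle] - y1) * (x2 - x1) / (y2 - y1)
            inside[straddle] ^= px[None, :] < x_int[:, None]

        # Boundary inclusion: pixel center within _EDGE_TOL of the segment.
        ex, ey = x2 - x1, y2 - y1
        seg2 = ex * ex + ey * ey
        dx = px[None, :] - x1
        dy = py[:, None] - y1
        if seg2 == 0.0:
            on_edge |= dx * dx + dy * dy <= _EDGE_TOL**2
            continue
        t = np.clip((dx * ex + dy * ey) / seg2, 0.0, 1.0)
        qx = dx - t * ex
        qy = dy - t * ey
        on_edge |= qx * qx + qy * qy <= _EDGE_TOL**2

    mask[r_lo : r_hi + 1, c_lo : c_hi + 1] = inside | on_edge
    return mask


def polygon_to_mask(
    polys: list[ContourPolygon] | ContourPolygon, grid: tuple[int, int]
) -> np.ndarray:
    """Union the even-odd masks of ``polys`` on a ``grid``-shaped raster.

    Degenerate polygons (< 3 vertices) contribute nothing; a warning is
    logged rather than raising, because clinical exports do contain stray
    single-point contours.
    """
    if isinstance(polys, ContourPolygon):
        polys = [polys]
    rows, cols = grid
    if rows <= 0 or cols <= 0:
        raise ValueError(f"grid dims must be positive, got {grid}")
    out = np.zeros((rows, cols), dtype=np.uint8)
    for p in polys:
        if p.degenerate:
            log.warning("skipping degenerate polygon with %d vertices", p.n_vertices)
            continue
        out |= _single_polygon_mask(p.vertices, grid)
    return out


def center_of_mass(mask: np.ndarray) -> tuple[float, float]:
    """Geometric center ``(x, y)`` of the one-pixels of a binary mask.

    x is the mean column index and y the mean row index of pixels equal to 1.
    Raises :class:`EmptyMaskError` for an all-zero mask — callers must skip
    empty slices.
    """
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise EmptyMaskError("center of mass of an empty mask is undefined")
    return float(cc.mean()), float(rr.mean())


def slice_count(s: Structure) -> int:
    """Number of slices of ``s`` carrying at least one non-degenerate polygon."""
    return s.slice_count


def rasterize_structure(
    s: Structure, grid: tuple[int, int]
) -> dict[int, np.ndarray]:
    """Rasterize every nonempty slice of a structure; returns slice -> mask.

    Slices whose polygons all rasterize to zero pixels are dropped from the
    result (they carry no classifiable segment).
    """
    out: dict[int, np.ndarray] = {}
    for idx in s.nonempty_slice_indices():
        m = polygon_to_mask(s.slices[idx], grid)
        if m.any():
            out[idx] = m
    return out
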