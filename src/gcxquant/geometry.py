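"""Polyline geometry for curved epithelial surfaces.

The ependymal surface is represented as an ordered polyline in image
coordinates (µm).  The orientation convention used throughout the package is
that the brain parenchyma lies on the LEFT of the direction of travel, i.e.
the left-hand normal ``n = (-ty, tx)`` of the local tangent ``t`` points from
the ventricular lumen into the tissue.  Signed distances to the surface are
therefore negative on the luminal (CSF) side and positive on the parenchymal
side.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString

__all__ = [
    "arc_length",
    "resample_polyline",
    "polyline_point_and_normal",
    "signed_distance_field",
    "check_simple",
]


def check_simple(polyline: np.ndarray) -> None:
    """Reject degenerate or self-intersecting surface polylines."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("surface polyline needs at least two 2-D points")
    seg = np.diff(pts, axis=0)
    if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
        raise ValueError("surface polyline contains zero-length segments")
    if not LineString(pts).is_simple:
        raise ValueError("surface polyline is self-intersecting")


def arc_length(polyline: np.ndarray) -> np.ndarray:
    """Cumulative arc length (µm) at each vertex, starting at 0."""
    pts = np.asarray(polyline, dtype=float)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(polyline: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arc-length spacing ``step``.

    Returns (points (M,2), arc positions (M,)). The final vertex is always
    included so the full arc length is covered.
    """
    pts = np.asarray(polyline, dtype=float)
    s = arc_length(pts)
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polyline (zero length)")
    u = np.arange(0.0, total, step)
    if total - (u[-1] if len(u) else 0.0) > 1e-9:
        u = np.append(u, total)
    x = np.interp(u, s, pts[:, 0])
    y = np.interp(u, s, pts[:, 1])
    return np.column_stack([x, y]), u


def polyline_point_and_normal(polyline: np.ndarray, u: np.ndarray):
    """Point and unit left-hand normal at arc position(s) ``u`` (µm).

    The left normal points toward the parenchyma under the package's
    orientation convention.
    """
    pts = np.asarray(polyline, dtype=float)
    s = arc_length(pts)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    px = np.interp(u, s, pts[:, 0])
    py = np.interp(u, s, pts[:, 1])
    # tangent from the segment containing each u
    idx = np.clip(np.searchsorted(s, u, side="right") - 1, 0, len(pts) - 2)
    seg = pts[idx + 1] - pts[idx]
    norm = np.hypot(seg[:, 0], seg[:, 1])
    t = seg / norm[:, None]
    n = np.column_stack([-t[:, 1], t[:, 0]])
    return np.column_stack([px, py]), n


def signed_distance_field(
    polyline: np.ndarray,
    shape: tuple[int, int],
    pixel_size: float,
    sample_step: float | None = None,
):
    """Signed distance (µm) and arc coordinate (µm) of every pixel.

    Pixel (row, col) maps to physical (x, y) = (col·px, row·px).  Distances
    are signed by the left-normal convention (parenchyma positive).  The
    polyline is densely resampled and queried through a KD-tree; the
    discretization error is O(step²/curvature), far below a pixel for the
    default ``sample_step = pixel_size / 4``.
    """
    if sample_step is None:
        sample_step = pixel_size / 4.0
    dense, u_dense = resample_polyline(polyline, sample_step)
    # per-sample tangents (forward differences, last repeats)
    d = np.diff(dense, axis=0)
    d = np.vstack([d, d[-1]])
    norm = np.hypot(d[:, 0], d[:, 1])
    tangents = d / norm[:, None]

    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    coords = np.column_stack([xx.ravel() * pixel_size, yy.ravel() * pixel_size])
    tree = cKDTree(dense)
    dist, idx = tree.query(coords, workers=-1)
    rel = coords - dense[idx]
    t = tangents[idx]
    cross = t[:, 0] * rel[:, 1] - t[:, 1] * rel[:, 0]
    signed = dist * np.sign(cross)
    # pixels exactly on the line get +0
    u = u_dense[idx]
    return signed.reshape(shape), u.reshape(shape)
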