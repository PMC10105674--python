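"""Deterministic raster geometry shared by the quantification modules.

Pixel membership is defined once, here: a pixel belongs to a region when its
*center* lies inside the polygon under the even-odd (ray-crossing) rule.
Coordinates are 0-based with x = column and y = row, so the pixel at
``(row r, col c)`` covers the unit square ``[c, c+1] x [r, r+1]`` and has its
center at ``(c + 0.5, r + 0.5)``.  This convention is deliberately simple
enough to check against exhaustive per-pixel enumeration.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, Polygon


class GeometryError(ValueError):
    """Invalid polygon, polyline, or axis geometry."""


def as_vertex_array(vertices) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise GeometryError(f"expected an (n, 2) vertex list, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise GeometryError("vertex coordinates must be finite")
    return arr


def validate_polygon(vertices) -> np.ndarray:
    """Return the vertex array of a simple (non-self-intersecting) polygon.

    Raises GeometryError for polygons with fewer than 3 vertices, zero area
    (e.g. collinear vertices) or self-intersections.
    """
    arr = as_vertex_array(vertices)
    # drop an explicit closing vertex
    if len(arr) > 1 and np.array_equal(arr[0], arr[-1]):
        arr = arr[:-1]
    if len(arr) < 3:
        raise GeometryError("polygon needs at least 3 distinct vertices")
    poly = Polygon(arr)
    if poly.area == 0:
        raise GeometryError("degenerate polygon (zero area / collinear vertices)")
    if not poly.is_valid:
        raise GeometryError("self-intersecting polygon")
    return arr


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd rule point-in-polygon test, vectorized over points.

    A point is inside when a horizontal ray towards +x crosses the boundary an
    odd number of times.  Edges are treated half-open in y, which makes the
    test deterministic for points aligned with vertices.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = as_vertex_array(polygon)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at_y = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < x_at_y)
    return inside


def polygon_mask(polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside ``polygon``.

    ``shape`` is the image (rows, cols).  Restricted to the polygon's bounding
    box for speed; semantics are identical to testing every pixel center.
    """
    poly = validate_polygon(polygon)
    h, w = shape
    c0 = max(int(np.floor(poly[:, 0].min() - 1)), 0)
    c1 = min(int(np.ceil(poly[:, 0].max() + 1)), w)
    r0 = max(int(np.floor(poly[:, 1].min() - 1)), 0)
    r1 = min(int(np.ceil(poly[:, 1].max() + 1)), h)
    mask = np.zeros(shape, dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    centers = np.column_stack([cols.ravel() + 0.5, rows.ravel() + 0.5])
    inside = points_in_polygon(centers, poly).reshape(rows.shape)
    mask[r0:r1, c0:c1] = inside
    return mask


def region_area(polygon, shape: tuple[int, int]) -> int:
    """Pixel count of a polygonal region (centers-inside, even-odd rule)."""
    return int(polygon_mask(polygon, shape).sum())


def polyline_length(vertices) -> float:
    """Total Euclidean length of a polyline, in the units of its coordinates."""
    arr = as_vertex_array(vertices)
    if len(arr) < 2 or np.allclose(arr, arr[0]):
        raise GeometryError("polyline needs at least 2 distinct vertices")
    seg = np.diff(arr, axis=0)
    length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if length == 0:
        raise GeometryError("polyline has zero length")
    return length


def axis_projection(points: np.ndarray, axis_start, axis_end) -> np.ndarray:
    """Normalized projection of points onto a directed axis.

    Returns t in (-inf, inf) with t = 0 at ``axis_start`` (apical end) and
    t = 1 at ``axis_end`` (basolateral end).
    """
    a = np.asarray(axis_start, dtype=float)
    b = np.asarray(axis_end, dtype=float)
    d = b - a
    norm2 = float(d @ d)
    if norm2 == 0:
        raise GeometryError("degenerate axis (zero length)")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (pts - a) @ d / norm2


def min_distance_to_polyline(points: np.ndarray, polyline) -> np.ndarray:
    """Minimum Euclidean distance from each point to a polyline (shapely)."""
    line = LineString(as_vertex_array(polyline))
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    from shapely import distance, points as shp_points

    return distance(shp_points(pts), line)
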