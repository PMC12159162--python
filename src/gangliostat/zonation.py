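"""Tissue-edge zonation: convex-hull boundaries and distance-to-edge summaries.

The tissue outline of a ganglion section is approximated by the convex hull
of all cell centroids in that section.  Each cell then gets the shortest
Euclidean distance from its centroid to the hull boundary, and distances are
aggregated per cell type (mean, median, quartiles) to rank types from the
tissue periphery inward.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.geometry.polygon import orient

__all__ = [
    "build_boundary",
    "distance_to_edge",
    "edge_distances",
    "edge_summary",
]


def build_boundary(cells: pd.DataFrame | np.ndarray) -> Polygon:
    """Smallest convex polygon enclosing all cell centroids.

    Accepts a cell table (with ``x_um``/``y_um`` columns) or an (n, 2) array.
    The hull vertices are a subset of the input points, returned as a
    counterclockwise shapely Polygon with collinear vertices dropped.
    Raises for < 3 points or an all-collinear configuration.
    """
    if isinstance(cells, pd.DataFrame):
        xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(cells, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of centroids")
    if len(xy) < 3:
        raise ValueError("degenerate geometry: need >= 3 centroids to build a hull")
    hull = MultiPoint(xy).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("degenerate geometry: centroids are collinear, hull is not a polygon")
    return orient(Polygon(hull.exterior.coords), sign=1.0)


def validate_polygon(poly: Polygon) -> Polygon:
    """Check boundary-polygon invariants: >= 3 vertices, simple, convex."""
    if not isinstance(poly, Polygon) or poly.is_empty:
        raise ValueError("boundary must be a non-empty polygon")
    n_vertices = len(poly.exterior.coords) - 1
    if n_vertices < 3:
        raise ValueError("boundary polygon needs >= 3 vertices")
    if not poly.is_valid:
        raise ValueError("boundary polygon is self-intersecting or otherwise invalid")
    if not poly.equals(poly.convex_hull):
        raise ValueError("boundary polygon must be convex")
    return orient(poly, sign=1.0)


def distance_to_edge(points: np.ndarray, polygon: Polygon) -> np.ndarray:
    """Shortest Euclidean distance (um) from each point to the polygon ring.

    Defined for interior and exterior points alike (exterior points, possible
    with a user-supplied boundary, get their positive distance to the ring
    with a warning); exactly 0 for points on the ring.
    """
    polygon = validate_polygon(polygon)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ring = polygon.exterior
    d = shapely.distance(shapely.points(pts[:, 0], pts[:, 1]), ring)
    inside = shapely.covers(polygon, shapely.points(pts[:, 0], pts[:, 1]))
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} point(s) lie outside the boundary polygon; "
            "their distance to the ring is reported"
        )
    return np.asarray(d, dtype=float)


def edge_distances(cells: pd.DataFrame, boundary: Polygon | None = None) -> pd.DataFrame:
    """Per-cell distance to the tissue edge, per section.

    If *boundary* is None a convex hull is built per section from all cells in
    that section (neuronal and non-neuronal together); a user-supplied polygon
    is applied to every section.
    Returns the cell table plus an ``edge_distance_um`` column.
    """
    out = []
    for _, sec in cells.groupby("section_id"):
        poly = boundary if boundary is not None else build_boundary(sec)
        d = distance_to_edge(sec[["x_um", "y_um"]].to_numpy(dtype=float), poly)
        sec = sec.copy()
        sec["edge_distance_um"] = d
        out.append(sec)
    return pd.concat(out, ignore_index=True)


def edge_summary(distances: pd.DataFrame) -> pd.DataFrame:
    """Per-type zonation summary, most peripheral type first.

    Expects the output of :func:`edge_distances`.  Returns one row per cell
    type with n, mean, median and quartiles of the edge distance, sorted by
    ascending mean (rank 1 = closest to the edge).
    """
    if "edge_distance_um" not in distances.columns:
        raise ValueError("expected an 'edge_distance_um' column; run edge_distances first")
    grp = distances.groupby("cell_type")["edge_distance_um"]
    summary = grp.agg(
        n="count",
        mean="mean",
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
    ).reset_index()
    empty = summary["n"] == 0
    if empty.any():
        warnings.warn(f"cell type(s) with no cells after filtering: "
                      f"{summary.loc[empty, 'cell_type'].tolist()}")
    summary = summary.sort_values("mean", kind="mergesort").reset_index(drop=True)
    summary["rank_peripheral"] = np.arange(1, len(summary) + 1)
    return summary
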