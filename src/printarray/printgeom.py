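"""Print isolation, registration and neighbour statistics.

Detected microcolony positions are first used to isolate the print from
stray debris: the print centre is the mean colony position, the mean
radial distance r̄ gives the side length of an (assumed square) print as

    L = 6 r̄ / (sqrt(2) + ln(1 + sqrt(2)))

(the expected distance of a uniform point in a unit square from its
centre is (sqrt(2) + ln(1 + sqrt(2)))/6 ≈ 0.3826), and colonies beyond a
radial threshold are discarded, after which the centre is recalculated.

The print is then registered to the x-y axes: the convex hull's radial
deviation profile d(φ) is resampled onto N regular polar angles, and the
print rotation θ follows from the phase of the discrete Fourier
transform of d(φ) at wavenumber k = 4 (a square's corners give d(φ) a
4-fold harmonic).  Finally, Delaunay triangulation of colony positions
defines the neighbour graph; colonies on the outer boundary are
excluded from neighbour-distance summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

__all__ = [
    "PrintGeometry", "NeighbourGraph", "SQUARE_RADIUS_CONSTANT",
    "estimate_centre", "estimate_side_length", "isolate_print",
    "register_print", "neighbour_distances",
]

#: E(r)/L for a point uniform in a square of side L measured from the
#: centre: (sqrt 2 + ln(1 + sqrt 2)) / 6.
SQUARE_RADIUS_CONSTANT = (np.sqrt(2.0) + np.log(1.0 + np.sqrt(2.0))) / 6.0

DEFAULT_MARGIN_FACTOR = 1.15
DEFAULT_N_ANGLES = 360


@dataclass
class PrintGeometry:
    """Summary geometry of one isolated, registered print."""

    centre: tuple[float, float]
    mean_radius: float
    side_length: float
    rotation_deg: float
    registered_extent: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "centre_x_um": self.centre[0],
            "centre_y_um": self.centre[1],
            "mean_radius_um": self.mean_radius,
            "side_length_um": self.side_length,
            "rotation_deg": self.rotation_deg,
            "extent_x_um": self.registered_extent[0],
            "extent_y_um": self.registered_extent[1],
        }


@dataclass
class NeighbourGraph:
    """Delaunay neighbour edges with distances; hull colonies flagged."""

    edges: np.ndarray          # (n_edges, 2) colony indices
    distances: np.ndarray      # µm per edge
    boundary: np.ndarray       # indices of convex-hull colonies
    interior_distances: np.ndarray  # distances of edges avoiding the hull


def _positions(table: pd.DataFrame) -> np.ndarray:
    return table[["x_um", "y_um"]].to_numpy(dtype=float)


def estimate_centre(table: pd.DataFrame) -> tuple[float, float]:
    """Approximate print centre: mean of all microcolony positions."""
    if len(table) == 0:
        raise ValueError("empty microcolony table")
    pos = _positions(table)
    return float(pos[:, 0].mean()), float(pos[:, 1].mean())


def estimate_side_length(
    table: pd.DataFrame, centre: tuple[float, float] | None = None
) -> float:
    """Side length of the (assumed square) print from the mean radius."""
    if len(table) == 0:
        raise ValueError("empty microcolony table")
    if centre is None:
        centre = estimate_centre(table)
    pos = _positions(table)
    r_bar = float(np.hypot(pos[:, 0] - centre[0], pos[:, 1] - centre[1]).mean())
    return r_bar / SQUARE_RADIUS_CONSTANT


def isolate_print(
    table: pd.DataFrame,
    margin_factor: float = DEFAULT_MARGIN_FACTOR,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Drop debris colonies outside the print's radial footprint.

    Colonies farther than ``margin_factor x L*sqrt(2)/2`` (the print's
    half-diagonal with slack) from the centre are removed; the centre is
    recomputed on the survivors and the threshold re-applied once with
    the refined centre.  Returns the filtered table and refined centre.
    """
    if margin_factor <= 0:
        raise ValueError("margin_factor must be positive")
    current = table
    centre = estimate_centre(current)
    for _ in range(2):  # initial pass + one refinement
        L = estimate_side_length(current, centre)
        cutoff = margin_factor * L * np.sqrt(2.0) / 2.0
        pos = _positions(current)
        dist = np.hypot(pos[:, 0] - centre[0], pos[:, 1] - centre[1])
        keep = dist <= cutoff
        if not keep.any():
            raise ValueError(
                "radial threshold removed every colony; margin_factor is "
                "misconfigured for this print"
            )
        current = current.loc[keep].reset_index(drop=True)
        centre = estimate_centre(current)
    return current, centre


def _radial_deviation_profile(
    pos: np.ndarray, centre: tuple[float, float], n_angles: int
) -> np.ndarray:
    """Mean-subtracted hull-boundary distance on regular polar angles.

    For each regular angle the distance is measured along the ray from
    the centre to its intersection with the convex-hull polygon, which
    resamples the hull boundary exactly (hull vertices cluster at the
    print's corners, so interpolating vertex distances alone would
    distort the profile).
    """
    try:
        hull = ConvexHull(pos)
    except QhullError as exc:
        raise ValueError("degenerate hull: colony positions are collinear") from exc
    verts = pos[hull.vertices] - np.asarray(centre)   # CCW order
    p1 = verts
    p2 = np.roll(verts, -1, axis=0)
    grid = np.arange(n_angles) * 2 * np.pi / n_angles
    u = np.column_stack([np.cos(grid), np.sin(grid)])
    # ray s*u intersects edge p1 + t*(p2-p1): solve the 2x2 system
    e = p2 - p1                                        # (E, 2)
    det = u[:, None, 0] * (-e[None, :, 1]) - u[:, None, 1] * (-e[None, :, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (p1[None, :, 0] * (-e[None, :, 1])
             - p1[None, :, 1] * (-e[None, :, 0])) / det
        t = (u[:, None, 0] * p1[None, :, 1]
             - u[:, None, 1] * p1[None, :, 0]) / det
    valid = (s > 0) & (t >= -1e-9) & (t <= 1 + 1e-9)
    s = np.where(valid, s, np.inf)
    d = s.min(axis=1)
    if not np.isfinite(d).all():
        raise ValueError("print centre lies outside the convex hull")
    return d - d.mean()


def register_print(
    table: pd.DataFrame,
    centre: tuple[float, float] | None = None,
    n_angles: int = DEFAULT_N_ANGLES,
) -> tuple[float, pd.DataFrame, tuple[float, float]]:
    """Rotate a print into alignment with the x-y axes.

    The rotation θ (degrees, in [-45, 45)) is the print's detected
    orientation from the phase of the k = 4 Fourier component of the
    hull's radial deviation profile; the registered table has all
    centroids rotated by -θ about the centre.  Returns
    ``(theta_deg, registered_table, extent)`` where extent is the
    (max - min) of the registered x and y coordinates.
    """
    if len(table) < 4:
        raise ValueError("registration needs at least 4 colonies")
    if n_angles < 8:
        raise ValueError("n_angles must be at least 8")
    if centre is None:
        centre = estimate_centre(table)
    pos = _positions(table)
    d = _radial_deviation_profile(pos, centre, n_angles)
    n = np.arange(n_angles)
    coeff = np.sum(d * np.exp(-1j * 8 * np.pi * n / n_angles))
    theta = 0.25 * (np.pi - np.angle(coeff))
    # fold into [-45, 45) degrees (the descriptor has period 90)
    theta_deg = (np.rad2deg(theta) + 45.0) % 90.0 - 45.0

    th = np.deg2rad(-theta_deg)
    dx, dy = pos[:, 0] - centre[0], pos[:, 1] - centre[1]
    rx = centre[0] + dx * np.cos(th) - dy * np.sin(th)
    ry = centre[1] + dx * np.sin(th) + dy * np.cos(th)
    registered = table.copy()
    registered["x_um"] = rx
    registered["y_um"] = ry
    extent = (float(rx.max() - rx.min()), float(ry.max() - ry.min()))
    return float(theta_deg), registered, extent


def _near_hull_boundary(
    pos: np.ndarray, hull_vertices: np.ndarray, tol_frac: float
) -> np.ndarray:
    """Boolean flag for points on or near the convex-hull polygon."""
    on_hull = np.zeros(len(pos), dtype=bool)
    on_hull[hull_vertices] = True
    hull = ConvexHull(pos)
    verts = pos[hull.vertices]
    centroid = verts.mean(axis=0)
    tol = tol_frac * float(
        np.hypot(*(verts - centroid).T).mean()
    )
    if tol <= 0:
        return on_hull
    a = verts
    b = np.roll(verts, -1, axis=0)
    ab = b - a                                       # (E, 2)
    denom = (ab ** 2).sum(axis=1)
    ap = pos[:, None, :] - a[None, :, :]             # (N, E, 2)
    t = np.clip((ap * ab[None]).sum(-1) / denom[None], 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d = np.hypot(*(pos[:, None, :] - proj).transpose(2, 0, 1)).min(axis=1)
    return on_hull | (d < tol)


def neighbour_distances(
    table: pd.DataFrame, *, boundary_tol_frac: float = 0.01
) -> NeighbourGraph:
    """Delaunay neighbour graph of colony positions.

    Colonies directly connected in the triangulation are neighbours.
    Colonies forming the print's outer boundary - hull vertices plus any
    colony within ``boundary_tol_frac`` of the mean hull radius of the
    hull polygon (near-collinear boundary colonies are not hull
    vertices) - are excluded from the reported interior distance
    distribution, since their edges carry triangulation boundary
    artefacts.
    """
    pos = _positions(table)
    if len(pos) < 3:
        raise ValueError("triangulation needs at least 3 colonies")
    try:
        tri = Delaunay(pos)
    except QhullError as exc:
        raise ValueError("degenerate input: colony positions are collinear") from exc
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            edges.add((min(i, j), max(i, j)))
    edges = np.array(sorted(edges), dtype=int)
    dist = np.hypot(*(pos[edges[:, 0]] - pos[edges[:, 1]]).T)
    on_hull = _near_hull_boundary(pos, np.unique(tri.convex_hull.ravel()),
                                  boundary_tol_frac)
    boundary = np.flatnonzero(on_hull)
    interior = ~(on_hull[edges[:, 0]] | on_hull[edges[:, 1]])
    if not interior.any():
        warnings.warn("all colonies lie on the hull; no interior edges",
                      stacklevel=2)
    return NeighbourGraph(
        edges=edges,
        distances=dist,
        boundary=boundary,
        interior_distances=dist[interior],
    )
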