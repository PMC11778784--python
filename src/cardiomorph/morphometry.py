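"""Chamber ellipsoid geometry and surface scalar fields.

Three morphometric readouts live here:

* a bounding-ellipsoid fit per chamber — semi-axes are half the mesh
  extents along the scene orientation triad (width = left-right,
  length = pole-apex, depth = dorso-ventral), and asphericity is the
  coefficient of variation of the semi-axes (0 for a sphere);
* ballooning — per-vertex distance from a surface mesh to the lumen
  centreline, a readout of regional chamber expansion;
* wall thickness — per-vertex distance from a carrier mesh to the nearest
  point (point-to-triangle) of the opposing nested mesh. Applied to the
  inner/outer faces of one tissue it measures wall thickness; applied to
  the outer inner-layer and inner outer-layer meshes it measures the
  thickness of the inter-layer (ECM) compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cardiomorph._geom import TriangleDistanceQuery, polyline_nearest
from cardiomorph.centreline import Centreline
from cardiomorph.meshing import SurfaceMesh


@dataclass
class EllipsoidFit:
    """Bounding ellipsoid of a chamber along the scene triad, in um.

    ``semi_axes`` are tagged (width, length, depth) following the triad
    axes. ``asphericity = sqrt(sum_i (s_i - s_mean)^2) / s_mean`` — zero
    iff all semi-axes are equal.
    """

    centre: np.ndarray
    semi_axes: tuple[float, float, float]
    asphericity: float

    def volume(self) -> float:
        """Ellipsoid volume (4/3) pi a b c, a convex-size proxy in um^3."""
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


def fit_ellipsoid(chamber: SurfaceMesh, triad: np.ndarray | None = None) -> EllipsoidFit:
    """Fit the extent-based bounding ellipsoid of a chamber mesh.

    ``triad`` is a 3x3 matrix whose rows are the scene axes (unit vectors,
    (z, y, x) components); defaults to the image axes. The mesh is
    projected onto each axis and the semi-axis is half the projected
    extent; the centre is the extent midpoint (in scene coordinates,
    mapped back to physical coordinates).
    """
    if len(chamber.vertices) == 0:
        raise ValueError("empty mesh")
    if triad is None:
        triad = np.eye(3)
    triad = np.asarray(triad, dtype=float)
    norms = np.linalg.norm(triad, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("triad axes must be nonzero")
    triad = triad / norms
    proj = chamber.vertices @ triad.T  # (N, 3) coordinates in the triad frame
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    semi = (hi - lo) / 2.0
    if np.any(semi <= 0):
        raise ValueError(f"flat mesh: zero extent along a triad axis (semi-axes {semi})")
    centre_triad = (hi + lo) / 2.0
    centre = centre_triad @ triad  # back to physical coordinates
    mean = semi.mean()
    asphericity = float(np.sqrt(np.sum((semi - mean) ** 2)) / mean)
    return EllipsoidFit(centre=centre, semi_axes=tuple(semi), asphericity=asphericity)


def ballooning_map(mesh: SurfaceMesh, cl: Centreline) -> SurfaceMesh:
    """Per-vertex distance (um) from the mesh to the centreline polyline.

    Distances are to the polyline segments (not only its sample points).
    The result carries the scalar ``"ballooning"``.
    """
    if len(mesh.vertices) == 0:
        raise ValueError("empty mesh")
    if len(cl.points) < 2:
        raise ValueError("degenerate centreline")
    dist, _, _, _ = polyline_nearest(mesh.vertices, cl.points)
    return mesh.with_scalar(dist, "ballooning")


def thickness_map(
    inner: SurfaceMesh, outer: SurfaceMesh, carrier: str = "outer"
) -> SurfaceMesh:
    """Per-vertex distance (um) between two nested surfaces.

    The scalar at each vertex of the carrier mesh is the exact distance to
    the closest point on the other mesh's triangles (point-to-triangle,
    not point-to-vertex). The result carries the scalar ``"thickness"``.
    """
    if len(inner.vertices) == 0 or len(outer.vertices) == 0:
        raise ValueError("empty mesh")
    if carrier == "outer":
        src, target = outer, inner
    elif carrier == "inner":
        src, target = inner, outer
    else:
        raise ValueError(f"carrier must be 'inner' or 'outer', got {carrier!r}")
    query = TriangleDistanceQuery(target.vertices, target.faces)
    dist = query.distance(src.vertices)
    return src.with_scalar(dist, "thickness")
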