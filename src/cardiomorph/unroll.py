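"""Unrolling of tubular 3D heatmaps into standardized 2D matrices.

A mesh carrying a per-vertex scalar (thickness or ballooning) is cut by a
series of planes transverse to the extended lumen centreline. Each plane's
intersection loop is parameterized by the signed circumferential angle
about the station point — the ventral direction is 0 degrees, dorsal is
+/-180 — and the scalar is binned by angle. Rows follow arclength from the
venous to the arterial end, so every specimen maps onto one universal
(arclength, angle) coordinate system: heatmaps from multiple specimens can
be averaged cell-wise, with per-cell contributor counts and standard
deviations. Cells never intersected stay missing — gaps (typically at the
inner curvature of looped chambers) are preserved, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from cardiomorph._geom import normalize, polyline_nearest
from cardiomorph.centreline import Centreline
from cardiomorph.meshing import SurfaceMesh


@dataclass
class Heatmap2D:
    """Matrix over (arclength bin, circumferential-angle bin).

    ``values[p, q]`` holds the scalar at arclength bin ``p`` (um along the
    extended centreline, venous to arterial) and angle bin ``q`` (degrees,
    bin centres uniformly covering [-180, 180), ventral = 0, dorsal =
    +/-180). Missing cells are NaN and are never interpolated.
    """

    values: np.ndarray  # (P, Q) float, NaN = missing
    arc_centres: np.ndarray  # (P,) um
    angle_centres: np.ndarray  # (Q,) degrees
    count: np.ndarray | None = None  # contributors per cell (averaged maps)
    sd: np.ndarray | None = None  # sample SD per cell (averaged maps)
    scalar_name: str = ""
    region_labels: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.arc_centres = np.asarray(self.arc_centres, dtype=float)
        self.angle_centres = np.asarray(self.angle_centres, dtype=float)
        if self.values.shape != (len(self.arc_centres), len(self.angle_centres)):
            raise ValueError("values shape must match axis lengths")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def present(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def band_means(self, bands: dict[str, tuple[float, float]] | None = None) -> dict[str, float]:
        """Mean of present cells within named arclength bands (um ranges)."""
        bands = bands if bands is not None else self.region_labels
        out = {}
        for name, (lo, hi) in bands.items():
            rows = (self.arc_centres >= lo) & (self.arc_centres <= hi)
            vals = self.values[rows]
            out[name] = float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else np.nan
        return out


def unroll_heatmap(
    mesh: SurfaceMesh,
    cl: Centreline,
    dorsal_ref,
    n_planes: int = 100,
    n_angle_bins: int = 72,
) -> Heatmap2D:
    """Unroll a scalar-carrying tubular mesh along its (extended) centreline.

    At each of ``n_planes`` stations along the centreline the mesh is
    intersected with the plane normal to the local tangent. Intersection
    segments are kept only when their nearest point on the centreline falls
    in this station's arclength bin (this both assigns geometry to stations
    and discards loops belonging to other parts of a looped organ; the
    number of discarded segments is not an error). Each kept segment
    contributes its face's mean scalar, weighted by segment length, to the
    angle bin of its midpoint. The angle is measured from the ventral
    direction (the projection of ``-dorsal_ref`` into the cutting plane),
    signed, with dorsal at +/-180 degrees.

    Stations whose plane misses the mesh leave their row missing.
    """
    if mesh.scalar is None:
        raise ValueError("mesh carries no scalar field to unroll")
    d = normalize(dorsal_ref)
    total = cl.length
    bin_w = total / n_planes
    arc_centres = (np.arange(n_planes) + 0.5) * bin_w
    angle_edges = np.linspace(-180.0, 180.0, n_angle_bins + 1)
    angle_centres = (angle_edges[:-1] + angle_edges[1:]) / 2.0

    station_pts = np.column_stack(
        [np.interp(arc_centres, cl.arclength, cl.points[:, k]) for k in range(3)]
    )
    tangents_line = cl.points[1:] - cl.points[:-1]
    tangents_line = tangents_line / np.linalg.norm(tangents_line, axis=1, keepdims=True)
    seg_idx = np.clip(np.searchsorted(cl.arclength, arc_centres) - 1, 0, len(tangents_line) - 1)

    tm = mesh.to_trimesh()
    face_scalar = mesh.scalar[mesh.faces].mean(axis=1)
    acc = np.zeros((n_planes, n_angle_bins))
    wsum = np.zeros((n_planes, n_angle_bins))

    for p in range(n_planes):
        t = tangents_line[seg_idx[p]]
        if np.linalg.norm(t) < 1e-12:
            raise ValueError(f"degenerate tangent at station {p}")
        origin = station_pts[p]
        segments, faces = trimesh.intersections.mesh_plane(
            tm, plane_normal=t, plane_origin=origin, return_faces=True
        )
        if len(segments) == 0:
            continue
        mid = segments.mean(axis=1)
        _, arc_m, _, _ = polyline_nearest(mid, cl.points)
        keep = np.abs(arc_m - arc_centres[p]) <= bin_w / 2.0 + 1e-9
        if not keep.any():
            continue
        segments, faces, mid = segments[keep], faces[keep], mid[keep]
        # in-plane frame: e1 = ventral, e2 completes it; angle in (-180, 180]
        v = -d - np.dot(-d, t) * t
        if np.linalg.norm(v) < 1e-9:
            raise ValueError("dorsal_ref parallel to the centreline tangent")
        e1 = v / np.linalg.norm(v)
        e2 = np.cross(e1, t)  # positive angles on the left side (t x dorsal half-space)
        u = mid - origin
        ang = np.degrees(np.arctan2(u @ e2, u @ e1))
        q = np.clip(((ang + 180.0) / 360.0 * n_angle_bins).astype(int), 0, n_angle_bins - 1)
        w = np.linalg.norm(segments[:, 1] - segments[:, 0], axis=1)
        np.add.at(acc, (p, q), w * face_scalar[faces])
        np.add.at(wsum, (p, q), w)

    with np.errstate(invalid="ignore"):
        values = np.where(wsum > 0, acc / np.where(wsum == 0, 1.0, wsum), np.nan)
    return Heatmap2D(
        values=values,
        arc_centres=arc_centres,
        angle_centres=angle_centres,
        scalar_name=mesh.scalar_name,
    )


def average_heatmaps(maps: list[Heatmap2D]) -> Heatmap2D:
    """Cell-wise mean of same-shape heatmaps, with count and sample SD.

    Cells missing in a specimen simply do not contribute; cells missing in
    all specimens stay missing. SD is the sample (n-1) standard deviation,
    NaN where fewer than two specimens contribute.
    """
    if not maps:
        raise ValueError("empty heatmap list")
    first = maps[0]
    for m in maps[1:]:
        if m.shape != first.shape:
            raise ValueError("heatmaps must share one shape")
        if not (np.allclose(m.arc_centres, first.arc_centres) and np.allclose(m.angle_centres, first.angle_centres)):
            raise ValueError("heatmaps must share axes")
    stack = np.stack([m.values for m in maps])
    count = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, np.nansum(np.nan_to_num(stack), axis=0) / np.where(count == 0, 1, count), np.nan)
        dev2 = np.nansum((stack - mean) ** 2 * ~np.isnan(stack), axis=0)
        sd = np.where(count > 1, np.sqrt(dev2 / np.maximum(count - 1, 1)), np.nan)
    return Heatmap2D(
        values=mean,
        arc_centres=first.arc_centres.copy(),
        angle_centres=first.angle_centres.copy(),
        count=count,
        sd=sd,
        scalar_name=first.scalar_name,
        region_labels=dict(first.region_labels),
    )


def export_heatmap_csv(hmap: Heatmap2D, path: str | Path) -> Path:
    """Write a heatmap as CSV: angle-bin header, arclength index, '.' decimal.

    Missing cells serialize as empty fields (never zeros); present cells
    round-trip bit-exactly through :func:`read_heatmap_csv`.
    """
    df = pd.DataFrame(hmap.values, index=hmap.arc_centres, columns=hmap.angle_centres)
    df.index.name = "arclength_um"
    df.to_csv(path, float_format=None)
    return Path(path)


def read_heatmap_csv(path: str | Path) -> Heatmap2D:
    """Re-import a heatmap written by :func:`export_heatmap_csv`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return Heatmap2D(
        values=df.to_numpy(dtype=float),
        arc_centres=df.index.to_numpy(dtype=float),
        angle_centres=np.array([float(c) for c in df.columns]),
    )


def render_heatmap_png(hmap: Heatmap2D, path: str | Path, title: str = "") -> Path:
    """Thin matplotlib rendering of a heatmap (missing cells transparent)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.pcolormesh(hmap.angle_centres, hmap.arc_centres, hmap.values, shading="nearest")
    ax.set_xlabel("circumferential angle (deg, ventral = 0)")
    ax.set_ylabel("arclength along centreline (um)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label=hmap.scalar_name or "value")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
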