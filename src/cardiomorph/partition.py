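"""Chamber partitioning and orientation.

A user-defined cutting disc placed at the constriction between chambers
(the atrioventricular canal in the heart) splits a mask or mesh into an
atrium and a ventricle by the sign of the signed distance to the disc
plane. The centreline further splits each chamber into left and right
halves, and chamber orientation is quantified as the signed angle between
each chamber's pole-to-apex axis and a reference vector, projected into a
ventral or lateral view plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cardiomorph._geom import normalize, polyline_nearest, signed_angle_in_plane
from cardiomorph.centreline import Centreline
from cardiomorph.compartments import VoxelMask
from cardiomorph.meshing import SurfaceMesh

ATRIUM = "atrium"
VENTRICLE = "ventricle"


@dataclass
class CutDisc:
    """Finite cutting disc: centre and unit normal in um, radius in um."""

    centre: np.ndarray
    normal: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float)
        self.normal = normalize(self.normal)
        self.radius = float(self.radius)
        if self.radius <= 0:
            raise ValueError("disc radius must be positive")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.centre) @ self.normal


@dataclass
class ChamberPartition:
    """Per-voxel (or per-face) chamber labels plus the disc that produced them."""

    labels: np.ndarray  # str array, ATRIUM / VENTRICLE / "" outside foreground
    disc: CutDisc
    kind: str  # "voxel" or "face"
    grid: VoxelMask | None = None  # source mask for voxel partitions
    mesh: SurfaceMesh | None = None
    cut_area_um2: float = 0.0

    def chamber_mask(self, chamber: str) -> VoxelMask:
        if self.kind != "voxel" or self.grid is None:
            raise ValueError("chamber_mask is only defined for voxel partitions")
        return VoxelMask(
            self.labels == chamber, self.grid.spacing, self.grid.origin, label=chamber
        )

    def chamber_volume(self, chamber: str) -> float:
        if self.kind == "voxel":
            return self.chamber_mask(chamber).volume()
        raise ValueError("volume only defined for voxel partitions")


def split_by_disc(
    target: VoxelMask | SurfaceMesh,
    disc: CutDisc,
    label_rule: str = "negative_is_atrium",
) -> ChamberPartition:
    """Split a mask or mesh into two chambers at a cutting disc.

    Voxels (or mesh faces, by centroid) are classified by the sign of
    ``(p - centre) . normal``; points exactly on the plane go to the
    ventricle side (deterministic tie-break). ``label_rule`` states which
    sign is the atrium (``negative_is_atrium`` or ``positive_is_atrium``).

    The disc must actually sever the target: each side must be nonempty,
    and the target's cross-section in the cut plane must lie within the
    disc radius (otherwise the error reports the measured overhang).
    """
    if label_rule not in ("negative_is_atrium", "positive_is_atrium"):
        raise ValueError(f"unknown label_rule {label_rule!r}")

    if isinstance(target, VoxelMask):
        vox = target.voxels
        if not vox.any():
            raise ValueError("empty target")
        spacing = np.asarray(target.spacing)
        idx = np.argwhere(vox)
        pts = idx * spacing + np.asarray(target.origin)
        s = disc.signed_distance(pts)
        slab = np.abs(s) <= max(target.spacing)  # voxels straddling the plane
        if not slab.any():
            raise ValueError("disc plane does not intersect the target")
        inplane = pts[slab] - disc.centre
        inplane -= np.outer(inplane @ disc.normal, disc.normal)
        r = np.linalg.norm(inplane, axis=1)
        if r.max() > disc.radius:
            raise ValueError(
                f"disc radius {disc.radius} um too small: cross-section overhangs by "
                f"{r.max() - disc.radius:.2f} um"
            )
        neg = s < 0  # plane points (s == 0) fall on the positive/ventricle side
        atrium_side = neg if label_rule == "negative_is_atrium" else ~neg
        labels = np.full(vox.shape, "", dtype=object)
        labels[tuple(idx[atrium_side].T)] = ATRIUM
        labels[tuple(idx[~atrium_side].T)] = VENTRICLE
        for chamber in (ATRIUM, VENTRICLE):
            m = labels == chamber
            if not m.any():
                raise ValueError(f"{chamber} side of the disc is empty")
            _, n_comp = ndimage.label(m)
            if n_comp > 1:
                raise ValueError(f"{chamber} side is disconnected ({n_comp} components)")
        # cross-section area: volume of the one-spacing slab / its thickness
        slab_thickness = 2.0 * max(target.spacing)
        cut_area = slab.sum() * float(np.prod(spacing)) / slab_thickness
        return ChamberPartition(
            labels=labels, disc=disc, kind="voxel", grid=target, cut_area_um2=cut_area
        )

    # mesh: classify faces by centroid
    centroids = target.vertices[target.faces].mean(axis=1)
    s = disc.signed_distance(centroids)
    neg = s < 0
    atrium_side = neg if label_rule == "negative_is_atrium" else ~neg
    if atrium_side.all() or (~atrium_side).all():
        raise ValueError("disc plane does not intersect the mesh")
    labels = np.where(atrium_side, ATRIUM, VENTRICLE)
    return ChamberPartition(labels=labels, disc=disc, kind="face", mesh=target)


def split_left_right(
    chamber: VoxelMask, cl: Centreline, dorsal_ref
) -> np.ndarray:
    """Label each chamber voxel left or right of the centreline.

    For every voxel the nearest centreline point defines the local tangent
    ``t``; the voxel is left when the triple product
    ``(voxel - point) . (t x dorsal_ref)`` is positive, right otherwise
    (voxels exactly on the tangent-dorsal plane go right — deterministic
    tie-break). Negating ``dorsal_ref`` swaps the labels.
    """
    d = normalize(dorsal_ref)
    vox = chamber.voxels
    if not vox.any():
        raise ValueError("empty chamber mask")
    idx = np.argwhere(vox)
    pts = idx * np.asarray(chamber.spacing) + np.asarray(chamber.origin)
    dist, _, foot, seg = polyline_nearest(pts, cl.points)
    tang = cl.points[1:] - cl.points[:-1]
    tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    t = tang[seg]
    side = np.einsum("ij,ij->i", pts - foot, np.cross(t, d))
    labels = np.full(vox.shape, "", dtype=object)
    labels[tuple(idx[side > 0].T)] = "left"
    labels[tuple(idx[side <= 0].T)] = "right"
    if not (side > 0).any() or not (side <= 0).any():
        raise ValueError("one side of the centreline is empty; does the centreline traverse the chamber?")
    return labels


def chamber_angles(
    partition: ChamberPartition,
    cl: Centreline,
    ref_vector,
    view: str = "ventral",
) -> dict[str, float]:
    """Orientation of each chamber axis relative to a reference vector.

    Each chamber's axis runs from its pole (the disc centre) to its apex
    (the chamber point farthest from the disc centre). Axis and reference
    vector are projected into the view plane — ``ventral``: the plane
    orthogonal to the imaging z axis; ``lateral``: orthogonal to the
    left-right x axis — and the signed angle between the projections is
    reported in (-180, 180] degrees, together with the inter-chamber angle
    folded to [0, 180].
    """
    if view == "ventral":
        plane_normal = np.array([1.0, 0.0, 0.0])  # imaging z axis, (z,y,x) order
    elif view == "lateral":
        plane_normal = np.array([0.0, 0.0, 1.0])  # left-right x axis
    else:
        raise ValueError(f"unknown view {view!r}")
    if partition.kind != "voxel" or partition.grid is None:
        raise ValueError("chamber_angles requires a voxel partition")
    out: dict[str, float] = {}
    for chamber in (ATRIUM, VENTRICLE):
        mask = partition.chamber_mask(chamber)
        idx = np.argwhere(mask.voxels)
        pts = idx * np.asarray(mask.spacing) + np.asarray(mask.origin)
        d = np.linalg.norm(pts - partition.disc.centre, axis=1)
        apex = pts[np.argmax(d)]
        axis = apex - partition.disc.centre
        if np.linalg.norm(axis) < 1e-9:
            raise ValueError(f"{chamber}: apex coincides with pole")
        out[f"{chamber}_angle_deg"] = signed_angle_in_plane(axis, ref_vector, plane_normal)
    inter = abs(out[f"{ATRIUM}_angle_deg"] - out[f"{VENTRICLE}_angle_deg"])
    if inter > 180.0:
        inter = 360.0 - inter
    out["inter_chamber_angle_deg"] = inter
    return out
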