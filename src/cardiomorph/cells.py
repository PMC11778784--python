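"""Cell-scale analysis from nuclei centroid coordinates.

Nuclei coordinates (as exported from a spot-detection tool) are assigned
to chambers by the same cutting disc used for tissue partitioning, and to
circumferential regions (ventral / dorsal / left / right quadrants about
the centreline). Every nucleus acts as the seed of a cluster formed by its
k nearest neighbours within the same chamber; the mean seed-to-neighbour
distance is the internuclear distance (IND), a proxy for cell size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from cardiomorph._geom import normalize, polyline_nearest
from cardiomorph.centreline import Centreline
from cardiomorph.partition import ATRIUM, VENTRICLE, CutDisc

UNASSIGNED = "unassigned"
REGIONS = ("ventral", "dorsal", "left", "right")


@dataclass
class NucleiSet:
    """Nuclei centroids (um) with chamber and region labels."""

    points: np.ndarray  # (N, 3) um, (z, y, x)
    chamber: np.ndarray = field(default=None)  # type: ignore[assignment]
    region: np.ndarray = field(default=None)  # type: ignore[assignment]
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if not np.all(np.isfinite(self.points)):
            raise ValueError("nuclei coordinates must be finite")
        n = len(self.points)
        if self.chamber is None:
            self.chamber = np.full(n, UNASSIGNED, dtype=object)
        if self.region is None:
            self.region = np.full(n, UNASSIGNED, dtype=object)
        if self.ids is None:
            self.ids = np.arange(n)

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path: str | Path, ind: np.ndarray | None = None) -> Path:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "x_um": self.points[:, 2],
                "y_um": self.points[:, 1],
                "z_um": self.points[:, 0],
                "chamber": self.chamber,
                "region": self.region,
            }
        )
        if ind is not None:
            df["ind_um"] = ind
        df.to_csv(path, index=False)
        return Path(path)


def load_nuclei(path: str | Path, dedup_tol: float = 0.1) -> NucleiSet:
    """Read nuclei coordinates from a CSV with x, y, z columns (um).

    Column names are matched case-insensitively (``x``/``x_um`` etc.; an
    optional ``id`` column is preserved). Duplicate points closer than
    ``dedup_tol`` um are merged with a warning; malformed (non-numeric)
    rows raise an error naming the row.
    """
    df = pd.read_csv(path)
    cols = {c.lower().split("_")[0].strip(): c for c in df.columns}
    missing = [ax for ax in ("x", "y", "z") if ax not in cols]
    if missing:
        raise ValueError(f"nuclei CSV lacks columns {missing}; found {list(df.columns)}")
    if len(df) < 1:
        raise ValueError("nuclei CSV has no rows")
    xyz = df[[cols["x"], cols["y"], cols["z"]]]
    numeric = xyz.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) & ~xyz.isna().any(axis=1) | xyz.isna().any(axis=1)
    if bad.any():
        raise ValueError(f"non-numeric coordinate in row(s) {list(df.index[bad])}")
    pts = numeric.to_numpy()[:, ::-1]  # (x,y,z) columns -> (z,y,x) convention
    ids = df[cols["id"]].to_numpy() if "id" in cols else np.arange(len(pts))
    # merge duplicates within tolerance
    tree = cKDTree(pts)
    pairs = tree.query_pairs(dedup_tol)
    if pairs:
        drop = {max(i, j) for i, j in pairs}
        warnings.warn(f"merged {len(drop)} duplicate nuclei within {dedup_tol} um")
        keep = np.array([i for i in range(len(pts)) if i not in drop])
        pts, ids = pts[keep], ids[keep]
    return NucleiSet(points=pts, ids=ids)


def assign_chambers(nuclei: NucleiSet, disc: CutDisc, label_rule: str = "negative_is_atrium") -> NucleiSet:
    """Label each nucleus atrial or ventricular by the cutting disc plane.

    Same sign rule and tie-break as the tissue partition: nuclei exactly
    on the plane fall on the ventricle side.
    """
    s = disc.signed_distance(nuclei.points)
    neg = s < 0
    atr = neg if label_rule == "negative_is_atrium" else ~neg
    chamber = np.where(atr, ATRIUM, VENTRICLE).astype(object)
    return NucleiSet(points=nuclei.points.copy(), chamber=chamber, region=nuclei.region.copy(), ids=nuclei.ids.copy())


def assign_regions(nuclei: NucleiSet, cl: Centreline, dorsal_ref) -> NucleiSet:
    """Bucket nuclei into dorsal/ventral/left/right quadrants about the centreline.

    For each nucleus the nearest centreline point defines the local tangent
    ``t``; with ``d = dorsal_ref`` and ``l = t x d``, the angle of the
    radial offset in the (d, l) frame selects one of four 90-degree sectors
    centred on +d (dorsal), -d (ventral), +l (left), -l (right). Points on
    a 45-degree sector boundary join the counter-clockwise-next sector.
    """
    if np.all(nuclei.chamber == UNASSIGNED):
        raise ValueError("assign chambers before regions")
    d = normalize(dorsal_ref)
    _, _, foot, seg = polyline_nearest(nuclei.points, cl.points)
    tang = cl.points[1:] - cl.points[:-1]
    tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    t = tang[seg]
    l_axis = np.cross(t, np.broadcast_to(d, t.shape))
    l_axis = l_axis / np.linalg.norm(l_axis, axis=1, keepdims=True)
    u = nuclei.points - foot
    ang = np.degrees(np.arctan2(np.einsum("ij,ij->i", u, l_axis), np.einsum("ij,ij->i", u, np.broadcast_to(d, u.shape))))
    # sectors centred on d (0), l (90), -d (180), -l (-90); boundaries at
    # odd multiples of 45 go to the counter-clockwise-next (larger-angle) sector
    region = np.empty(len(ang), dtype=object)
    ang = np.mod(ang, 360.0)
    region[(ang >= 315.0) | (ang < 45.0)] = "dorsal"
    region[(ang >= 45.0) & (ang < 135.0)] = "left"
    region[(ang >= 135.0) & (ang < 225.0)] = "ventral"
    region[(ang >= 225.0) & (ang < 315.0)] = "right"
    return NucleiSet(points=nuclei.points.copy(), chamber=nuclei.chamber.copy(), region=region, ids=nuclei.ids.copy())


def internuclear_distance(
    nuclei: NucleiSet, k_neighbours: int = 4
) -> tuple[np.ndarray, pd.DataFrame]:
    """Mean distance from every seed nucleus to its k nearest neighbours.

    Every nucleus serves as a seed; neighbours are restricted to the same
    chamber. Chambers with too few nuclei (<= k) are skipped with a
    warning, leaving NaN INDs. Returns the per-nucleus IND array and a
    summary table of mean IND per chamber and per (chamber, region), with
    counts — the per-chamber mean equals the count-weighted mean of its
    region means by construction.
    """
    if k_neighbours < 1:
        raise ValueError("k_neighbours must be >= 1")
    ind = np.full(len(nuclei), np.nan)
    chambers = [c for c in pd.unique(nuclei.chamber)]
    for ch in chambers:
        sel = np.nonzero(nuclei.chamber == ch)[0]
        if len(sel) <= k_neighbours:
            warnings.warn(f"chamber {ch!r} has {len(sel)} nuclei <= k={k_neighbours}; skipped")
            continue
        pts = nuclei.points[sel]
        tree = cKDTree(pts)
        dist, _ = tree.query(pts, k=k_neighbours + 1)  # first hit is the seed itself
        ind[sel] = dist[:, 1:].mean(axis=1)
    rows = []
    for ch in chambers:
        sel = (nuclei.chamber == ch) & ~np.isnan(ind)
        if sel.any():
            rows.append({"chamber": ch, "region": "all", "n": int(sel.sum()), "mean_ind_um": float(ind[sel].mean())})
        for reg in REGIONS:
            rsel = sel & (nuclei.region == reg)
            if rsel.any():
                rows.append({"chamber": ch, "region": reg, "n": int(rsel.sum()), "mean_ind_um": float(ind[rsel].mean())})
    return ind, pd.DataFrame(rows)
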