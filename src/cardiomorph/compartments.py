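"""Negative-space extraction of the inter-layer compartment (cardiac ECM).

The acellular matrix between two nested tissue layers carries no fluorescent
label of its own; its mask is derived from the two labelled layers by
boolean algebra: the space enclosed by the outer layer's lumen (its filled
internal contour) that is not occupied by the inner layer (its filled
external contour).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class VoxelMask:
    """A 3D boolean mask on a physical grid.

    ``volume()`` is the true-voxel count times the voxel volume, in um^3.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def volume(self) -> float:
        """Mask volume in um^3."""
        return float(self.voxels.sum()) * self.voxel_volume()

    def same_grid(self, other: "VoxelMask") -> bool:
        return (
            self.voxels.shape == other.voxels.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def save(self, path: str | Path) -> Path:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.voxels.astype(np.uint8), photometric="minisblack")
        meta = {"spacing": list(self.spacing), "origin": list(self.origin), "label": self.label}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "VoxelMask":
        import tifffile

        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            voxels=tifffile.imread(path) > 0,
            spacing=tuple(meta["spacing"]),
            origin=tuple(meta.get("origin", (0, 0, 0))),
            label=meta.get("label", ""),
        )


def ecm_mask(inner_bound: VoxelMask, outer_bound: VoxelMask) -> tuple[VoxelMask, int]:
    """Extract the inter-layer compartment by AND/XOR mask algebra.

    Parameters
    ----------
    inner_bound : VoxelMask
        The filled internal contour of the outer layer (e.g. the space
        enclosed by the myocardial wall).
    outer_bound : VoxelMask
        The filled external contour of the inner layer (e.g. the whole
        endocardium including its lumen).

    Returns
    -------
    (mask, leak_count)
        ``mask = inner_bound XOR (inner_bound AND outer_bound)`` — i.e.
        inner_bound minus outer_bound. ``leak_count`` is the number of
        ``outer_bound`` voxels protruding outside ``inner_bound``
        (segmentation noise violating strict nesting); they are clipped out
        of every compartment rather than producing negative volumes.
    """
    if not inner_bound.same_grid(outer_bound):
        raise ValueError("masks must share shape, spacing and origin")
    overlap = inner_bound.voxels & outer_bound.voxels
    result = inner_bound.voxels ^ overlap
    leak = int((outer_bound.voxels & ~inner_bound.voxels).sum())
    return (
        VoxelMask(result, inner_bound.spacing, inner_bound.origin, label="ecm"),
        leak,
    )


def compartment_volumes(
    library,
    outer_channel: str,
    inner_channel: str,
) -> pd.DataFrame:
    """Tabulate per-compartment volumes and their percentage shares.

    Compartments of the organ, from outside in: the outer-layer wall
    (myocardium analogue), the inter-layer ECM, the inner-layer wall
    (endocardium analogue), and the lumen (the inner layer's filled internal
    contour). Shares are percentages of the outer layer's filled external
    volume; voxels of the inner layer leaking outside the outer layer's
    lumen are reported in a separate ``leak`` row and excluded from shares.
    """
    spacing, origin = library.spacing, library.origin
    myo_tissue = VoxelMask(library.mask3d(outer_channel, "tissue"), spacing, origin)
    myo_internal = VoxelMask(library.mask3d(outer_channel, "filled_internal"), spacing, origin)
    myo_external = VoxelMask(library.mask3d(outer_channel, "filled_external"), spacing, origin)
    endo_external = VoxelMask(library.mask3d(inner_channel, "filled_external"), spacing, origin)
    endo_internal = VoxelMask(library.mask3d(inner_channel, "filled_internal"), spacing, origin)
    endo_tissue = VoxelMask(library.mask3d(inner_channel, "tissue"), spacing, origin)

    ecm, leak_vox = ecm_mask(myo_internal, endo_external)
    vv = myo_tissue.voxel_volume()
    # clip the inner layer to the outer layer's lumen so compartments partition it
    endo_tissue_in = int((endo_tissue.voxels & myo_internal.voxels).sum()) * vv
    lumen_in = int((endo_internal.voxels & myo_internal.voxels).sum()) * vv
    rows = {
        f"{outer_channel}_tissue": myo_tissue.volume(),
        "ecm": ecm.volume(),
        f"{inner_channel}_tissue": endo_tissue_in,
        "lumen": lumen_in,
    }
    total = myo_external.volume()
    df = pd.DataFrame(
        {
            "compartment": list(rows.keys()),
            "volume_um3": list(rows.values()),
            "share_pct": [100.0 * v / total if total else np.nan for v in rows.values()],
        }
    )
    leak_volume = leak_vox * vv
    df.loc[len(df)] = ["leak", leak_volume, np.nan]
    df.loc[len(df)] = ["total_filled_external", total, 100.0]
    return df
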