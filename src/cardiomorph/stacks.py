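"""Reading, cropping, filtering and writing of multi-channel z-stacks.

A stack carries its anisotropic voxel spacing ``(dz, dy, dx)`` in micrometres
and the physical coordinate of voxel ``(0, 0, 0)``. Downstream modules work
exclusively in physical coordinates; this module is the only place voxel
indices are authoritative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage


@dataclass
class IntensityStack:
    """Multi-channel 3D intensity image with physical voxel spacing.

    Parameters
    ----------
    channels : dict of str -> ndarray
        One ``(nz, ny, nx)`` array of non-negative intensities per channel,
        all of identical shape. Keys are layer labels (e.g. ``"myocardium"``).
    spacing : tuple of float
        ``(dz, dy, dx)`` voxel spacing in micrometres; all components > 0.
    origin : tuple of float
        Physical coordinate (z, y, x, in um) of voxel ``(0, 0, 0)``.

    The physical coordinate of voxel ``(k, j, i)`` is
    ``origin + (k*dz, j*dy, i*dx)``.
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel arrays must share one shape, got {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} must be 3D, got ndim={arr.ndim}")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels.keys())

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        dz, dy, dx = self.spacing
        return dz * dy * dx


def read_stack(
    path: str | Path,
    spacing: tuple[float, float, float],
    channel_names: list[str],
    layout: str = "interleaved",
) -> IntensityStack:
    """Read a multi-page TIFF into an :class:`IntensityStack`.

    Parameters
    ----------
    path : path
        TIFF file whose page count is divisible by ``len(channel_names)``.
    spacing : (dz, dy, dx) in um.
    channel_names : labels in acquisition order.
    layout : {"interleaved", "stacked"}
        ``interleaved`` — channel index varies fastest across pages
        (c0z0, c1z0, c0z1, ...); ``stacked`` — all pages of channel 0,
        then all of channel 1, etc. Both dialects occur in practice.

    If ``path`` has a sidecar JSON (written by :func:`write_stack`), spacing,
    origin and channel names recorded there take precedence when the caller
    passes ``spacing=None`` / ``channel_names=None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    origin = (0.0, 0.0, 0.0)
    meta_layout = layout
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if spacing is None:
            spacing = tuple(meta["spacing"])
        if channel_names is None:
            channel_names = list(meta["channel_names"])
        origin = tuple(meta.get("origin", origin))
        meta_layout = meta.get("layout", layout)
    if spacing is None or channel_names is None:
        raise ValueError("spacing and channel_names required when no sidecar JSON exists")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive components, got {spacing}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_ch = len(channel_names)
    if pages.shape[0] % n_ch != 0:
        raise ValueError(
            f"{pages.shape[0]} pages not divisible by {n_ch} channels"
        )
    nz = pages.shape[0] // n_ch
    channels: dict[str, np.ndarray] = {}
    for c, name in enumerate(channel_names):
        if meta_layout == "interleaved":
            channels[name] = np.ascontiguousarray(pages[c::n_ch])
        elif meta_layout == "stacked":
            channels[name] = np.ascontiguousarray(pages[c * nz : (c + 1) * nz])
        else:
            raise ValueError(f"unknown layout {meta_layout!r}")
    return IntensityStack(channels=channels, spacing=tuple(spacing), origin=origin)


def write_stack(stack: IntensityStack, path: str | Path, layout: str = "interleaved") -> Path:
    """Write a stack as multi-page TIFF plus a sidecar JSON with metadata.

    Round-trip through :func:`read_stack` preserves voxels bit-exactly and
    spacing/origin to full float precision (JSON decimal).
    """
    path = Path(path)
    arrays = list(stack.channels.values())
    nz = arrays[0].shape[0]
    if layout == "interleaved":
        pages = np.stack(arrays, axis=1).reshape((-1,) + arrays[0].shape[1:])
    elif layout == "stacked":
        pages = np.concatenate(arrays, axis=0)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "spacing": list(stack.spacing),
        "origin": list(stack.origin),
        "channel_names": stack.channel_names,
        "layout": layout,
        "pages": int(nz * len(arrays)),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def crop_stack(stack: IntensityStack, roi: tuple[tuple[int, int], ...]) -> IntensityStack:
    """Restrict a stack to an axis-aligned voxel-index box.

    ``roi`` is ``((z0, z1), (y0, y1), (x0, x1))`` with half-open bounds.
    The origin shifts by the roi offset times the spacing, so physical
    coordinates of retained voxels are unchanged.
    """
    if len(roi) != 3:
        raise ValueError("roi must have 3 (start, stop) pairs")
    shape = stack.shape
    for ax, ((a, b), n) in enumerate(zip(roi, shape)):
        if not (0 <= a < b <= n):
            raise ValueError(f"roi axis {ax}: ({a}, {b}) invalid for extent {n}")
    sl = tuple(slice(a, b) for a, b in roi)
    channels = {name: arr[sl].copy() for name, arr in stack.channels.items()}
    origin = tuple(o + a * s for o, (a, _), s in zip(stack.origin, roi, stack.spacing))
    return IntensityStack(channels=channels, spacing=stack.spacing, origin=origin)


def despeckle(stack: IntensityStack, radius: int = 1) -> IntensityStack:
    """Per-slice median filter removing isolated bright/dark voxels.

    ``radius`` is in pixels; the kernel is a ``(2r+1) x (2r+1)`` square
    applied independently to each z-slice of each channel. Intensities stay
    in the input dtype; shape, spacing and origin are unchanged.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    size = 2 * radius + 1
    channels = {}
    for name, arr in stack.channels.items():
        channels[name] = ndimage.median_filter(arr, size=(1, size, size))
    return IntensityStack(channels=channels, spacing=stack.spacing, origin=stack.origin)
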