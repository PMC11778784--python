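"""Synthetic two-layer phantoms with closed-form ground truth.

Phantoms emulate a two-layer tubular tissue — an outer muscular wall
(myocardium analogue) and a thinner inner lining (endocardium analogue)
separated by an acellular gap — as two-channel intensity stacks, plus
nuclei lattices for the cell module. Every geometric truth (volumes,
lengths, ratios, thicknesses) is stored in closed form alongside the
voxel data.

Voxelization rule: a voxel is foreground iff its centre lies inside the
analytic solid (centre sampling), so recovered voxel-count volumes differ
from the analytic value by at most about one surface layer of voxels.
Noise injection (salt-and-pepper or Gaussian) perturbs intensities only;
the truth record never changes. Generation is deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from cardiomorph.compartments import VoxelMask
from cardiomorph.stacks import IntensityStack

OUTER = "outer_wall"
INNER = "inner_wall"

KINDS = (
    "straight_tube",
    "bent_tube",
    "nested_tubes",
    "concentric_shells",
    "bulged_tube",
    "two_chamber",
    "nuclei_lattice",
)


@dataclass
class PhantomSpec:
    """Recipe for one phantom: geometry (um), voxel spacing, noise, seed."""

    kind: str
    params: dict[str, float] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (0.5, 0.25, 0.25)
    noise: dict[str, float] | None = None  # {"salt_pepper": frac} and/or {"gaussian": sigma}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {KINDS}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class PhantomResult:
    """Generated phantom: intensity stack (or nuclei) plus the truth record."""

    stack: IntensityStack | None
    truth: dict[str, Any]
    nuclei: np.ndarray | None = None  # (N, 3) um for nuclei_lattice

    def mask(self, channel: str) -> VoxelMask:
        """Binary foreground of one channel as a VoxelMask."""
        arr = self.stack.channels[channel]
        return VoxelMask(arr >= 128, self.stack.spacing, self.stack.origin, label=channel)


def _grid(shape, spacing, origin):
    """Voxel-centre physical coordinates per axis (broadcastable)."""
    z = origin[0] + np.arange(shape[0]) * spacing[0]
    y = origin[1] + np.arange(shape[1]) * spacing[1]
    x = origin[2] + np.arange(shape[2]) * spacing[2]
    return z[:, None, None], y[None, :, None], x[None, None, :]


def _to_stack(masks: dict[str, np.ndarray], spacing, seed, noise) -> IntensityStack:
    rng = np.random.default_rng(seed)
    channels = {}
    for name, m in masks.items():
        img = np.where(m, 255, 0).astype(np.uint8)
        if noise:
            frac = noise.get("salt_pepper", 0.0)
            if frac > 0:
                flips = rng.random(img.shape) < frac
                img[flips] = np.where(img[flips] > 0, 0, 255)
            sigma = noise.get("gaussian", 0.0)
            if sigma > 0:
                img = np.clip(
                    img.astype(float) + rng.normal(0.0, sigma, img.shape), 0, 255
                ).astype(np.uint8)
        channels[name] = img
    return IntensityStack(channels=channels, spacing=spacing)


def _check_feature(sizes_um: list[float], spacing) -> None:
    min_sp = min(spacing)
    for s in sizes_um:
        if s < 2 * min_sp:
            raise ValueError(f"feature of {s} um thinner than 2 voxels at spacing {spacing}")


def generate(spec: PhantomSpec) -> PhantomResult:
    """Generate a phantom stack (or nuclei set) and its analytic truth record."""
    fn = {
        "straight_tube": _straight_tube,
        "bent_tube": _bent_tube,
        "nested_tubes": _nested_tubes,
        "concentric_shells": _concentric_shells,
        "bulged_tube": _bulged_tube,
        "two_chamber": _two_chamber,
        "nuclei_lattice": _nuclei_lattice,
    }[spec.kind]
    return fn(spec)


def _margin(spacing) -> float:
    return 4.0 * max(spacing)


def _straight_tube(spec: PhantomSpec) -> PhantomResult:
    p = {"r_lumen": 20.0, "wall": 5.0, "height": 100.0, **spec.params}
    r, w, h = p["r_lumen"], p["wall"], p["height"]
    _check_feature([w, r], spec.spacing)
    m = _margin(spec.spacing)
    half = r + w + m
    shape = tuple(
        int(np.ceil(ext / s)) for ext, s in zip((h + 2 * m, 2 * half, 2 * half), spec.spacing)
    )
    z, y, x = _grid(shape, spec.spacing, (0.0, 0.0, 0.0))
    cy = cx = half
    z0, z1 = m, m + h
    rad = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
    inz = (z >= z0) & (z <= z1)
    outer = inz & (rad <= r + w)
    lumen_analytic = inz & (rad <= r)
    wall = outer & ~lumen_analytic
    truth = {
        "r_lumen": r,
        "wall": w,
        "height": h,
        "axis_yx": (cy, cx),
        "pole_a": (z0, cy, cx),
        "pole_b": (z1, cy, cx),
        "centreline_length": h,
        "looping_ratio": 1.0,
        "lumen_volume": np.pi * r**2 * h,
        "wall_volume": np.pi * ((r + w) ** 2 - r**2) * h,
        "filled_external_volume": np.pi * (r + w) ** 2 * h,
    }
    stack = _to_stack({OUTER: wall}, spec.spacing, spec.seed, spec.noise)
    return PhantomResult(stack=stack, truth=truth)


def _bent_tube(spec: PhantomSpec) -> PhantomResult:
    p = {"bend_radius": 50.0, "tube_radius": 12.0, "angle_deg": 180.0, "wall": 4.0, **spec.params}
    R, r, theta, w = p["bend_radius"], p["tube_radius"], np.radians(p["angle_deg"]), p["wall"]
    _check_feature([w, r], spec.spacing)
    m = _margin(spec.spacing)
    # arc in the (y, x) plane at constant z, centre at c, angles 0..theta
    pad = r + w + m
    ys = [R * np.sin(t) for t in np.linspace(0, theta, 181)]
    xs = [R * np.cos(t) for t in np.linspace(0, theta, 181)]
    y_lo, y_hi = min(ys) - pad, max(ys) + pad
    x_lo, x_hi = min(xs) - pad, max(xs) + pad
    z_half = pad
    shape = tuple(
        int(np.ceil(ext / s))
        for ext, s in zip((2 * z_half, y_hi - y_lo, x_hi - x_lo), spec.spacing)
    )
    origin = (0.0, 0.0, 0.0)
    z, y, x = _grid(shape, spec.spacing, origin)
    cz, cy, cx = z_half, -y_lo, -x_lo  # arc centre in grid coordinates
    phi = np.mod(np.arctan2(y - cy, x - cx), 2 * np.pi)
    phi_c = np.clip(phi, 0.0, theta)
    near_y = cy + R * np.sin(phi_c)
    near_x = cx + R * np.cos(phi_c)
    d_arc = np.sqrt((z - cz) ** 2 + (y - near_y) ** 2 + (x - near_x) ** 2)
    # beyond the angular range the nearest arc point is an endpoint
    endA = np.sqrt((z - cz) ** 2 + (y - cy) ** 2 + (x - (cx + R)) ** 2)
    endB = np.sqrt(
        (z - cz) ** 2 + (y - (cy + R * np.sin(theta))) ** 2 + (x - (cx + R * np.cos(theta))) ** 2
    )
    d = np.minimum(d_arc, np.minimum(endA, endB))
    outer = d <= r + w
    lumen = d <= r
    wall = outer & ~lumen
    chord = 2 * R * np.sin(theta / 2)
    truth = {
        "bend_radius": R,
        "tube_radius": r,
        "angle_deg": p["angle_deg"],
        "wall": w,
        "pole_a": (cz, cy, cx + R),
        "pole_b": (cz, cy + R * np.sin(theta), cx + R * np.cos(theta)),
        "apex": (cz, cy + R * np.sin(theta / 2), cx + R * np.cos(theta / 2)),
        "arc_centre": (cz, cy, cx),
        "centreline_length": R * theta,
        "chord": chord,
        "looping_ratio": R * theta / chord,
    }
    stack = _to_stack({OUTER: wall}, spec.spacing, spec.seed, spec.noise)
    return PhantomResult(stack=stack, truth=truth)


def _nested_tubes(spec: PhantomSpec) -> PhantomResult:
    p = {
        "r_myo_out": 30.0,
        "r_myo_in": 25.0,
        "r_endo_out": 20.0,
        "r_endo_in": 17.0,
        "height": 100.0,
        **spec.params,
    }
    rmo, rmi, reo, rei, h = (
        p["r_myo_out"],
        p["r_myo_in"],
        p["r_endo_out"],
        p["r_endo_in"],
        p["height"],
    )
    if not (rmo > rmi > reo > rei > 0):
        raise ValueError("nested_tubes radii must satisfy r_myo_out > r_myo_in > r_endo_out > r_endo_in")
    _check_feature([rmo - rmi, reo - rei, rmi - reo], spec.spacing)
    m = _margin(spec.spacing)
    half = rmo + m
    shape = tuple(
        int(np.ceil(ext / s)) for ext, s in zip((h + 2 * m, 2 * half, 2 * half), spec.spacing)
    )
    z, y, x = _grid(shape, spec.spacing, (0.0, 0.0, 0.0))
    cy = cx = half
    rad = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
    inz = (z >= m) & (z <= m + h)
    myo_wall = inz & (rad <= rmo) & (rad > rmi)
    endo_wall = inz & (rad <= reo) & (rad > rei)
    truth = {
        **{k: p[k] for k in ("r_myo_out", "r_myo_in", "r_endo_out", "r_endo_in", "height")},
        "axis_yx": (cy, cx),
        "pole_a": (m, cy, cx),
        "pole_b": (m + h, cy, cx),
        "myo_wall_volume": np.pi * (rmo**2 - rmi**2) * h,
        "endo_wall_volume": np.pi * (reo**2 - rei**2) * h,
        "ecm_volume": np.pi * (rmi**2 - reo**2) * h,
        "lumen_volume": np.pi * rei**2 * h,
        "filled_external_volume": np.pi * rmo**2 * h,
        "ecm_gap": rmi - reo,
    }
    stack = _to_stack({OUTER: myo_wall, INNER: endo_wall}, spec.spacing, spec.seed, spec.noise)
    return PhantomResult(stack=stack, truth=truth)


def _concentric_shells(spec: PhantomSpec) -> PhantomResult:
    p = {"r_outer": 30.0, "r_inner": 20.0, **spec.params}
    ro, ri = p["r_outer"], p["r_inner"]
    if not ro > ri > 0:
        raise ValueError("r_outer must exceed r_inner")
    _check_feature([ro - ri, ri], spec.spacing)
    m = _margin(spec.spacing)
    half = ro + m
    shape = tuple(int(np.ceil(2 * half / s)) for s in spec.spacing)
    z, y, x = _grid(shape, spec.spacing, (0.0, 0.0, 0.0))
    c = np.array([half, half, half])
    rad = np.sqrt((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
    truth = {
        "r_outer": ro,
        "r_inner": ri,
        "centre": tuple(c),
        "shell_thickness": ro - ri,
        "outer_volume": 4 / 3 * np.pi * ro**3,
        "inner_volume": 4 / 3 * np.pi * ri**3,
        "shell_volume": 4 / 3 * np.pi * (ro**3 - ri**3),
    }
    stack = _to_stack({OUTER: rad <= ro, INNER: rad <= ri}, spec.spacing, spec.seed, spec.noise)
    return PhantomResult(stack=stack, truth=truth)


def _bulged_tube(spec: PhantomSpec) -> PhantomResult:
    p = {
        "r_lumen": 20.0,
        "bump_amplitude": 10.0,
        "bump_sigma": 10.0,
        "wall": 4.0,
        "height": 100.0,
        **spec.params,
    }
    r0, amp, sig, w, h = p["r_lumen"], p["bump_amplitude"], p["bump_sigma"], p["wall"], p["height"]
    _check_feature([w, r0], spec.spacing)
    m = _margin(spec.spacing)
    half = r0 + amp + w + m
    shape = tuple(
        int(np.ceil(ext / s)) for ext, s in zip((h + 2 * m, 2 * half, 2 * half), spec.spacing)
    )
    z, y, x = _grid(shape, spec.spacing, (0.0, 0.0, 0.0))
    cy = cx = half
    zc = m + h / 2
    r_of_z = r0 + amp * np.exp(-((z - zc) ** 2) / (2 * sig**2))
    rad = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
    inz = (z >= m) & (z <= m + h)
    lumen = inz & (rad <= r_of_z)
    outer = inz & (rad <= r_of_z + w)
    truth = {
        "r_lumen": r0,
        "bump_amplitude": amp,
        "bump_sigma": sig,
        "wall": w,
        "height": h,
        "axis_yx": (cy, cx),
        "pole_a": (m, cy, cx),
        "pole_b": (m + h, cy, cx),
        "bump_centre_z": zc,
        "r_max": r0 + amp,
    }
    stack = _to_stack({OUTER: outer & ~lumen}, spec.spacing, spec.seed, spec.noise)
    return PhantomResult(stack=stack, truth=truth)


def _two_chamber(spec: PhantomSpec) -> PhantomResult:
    p = {"r_atrium": 25.0, "r_ventricle": 30.0, "neck_radius": 10.0, "separation": 60.0, **spec.params}
    ra, rv, rn, sep = p["r_atrium"], p["r_ventricle"], p["neck_radius"], p["separation"]
    if sep <= 0 or rn > min(ra, rv):
        raise ValueError("need positive separation and neck_radius <= both sphere radii")
    _check_feature([rn, ra, rv], spec.spacing)
    m = _margin(spec.spacing)
    half_y = (sep + ra + rv) / 2 + m
    half = max(ra, rv) + m
    shape = tuple(
        int(np.ceil(ext / s)) for ext, s in zip((2 * half, 2 * half_y, 2 * half), spec.spacing)
    )
    z, y, x = _grid(shape, spec.spacing, (0.0, 0.0, 0.0))
    cz = cx = half
    ca = np.array([cz, half_y - sep / 2, cx])  # atrium centre
    cv = np.array([cz, half_y + sep / 2, cx])  # ventricle centre
    da = np.sqrt((z - ca[0]) ** 2 + (y - ca[1]) ** 2 + (x - ca[2]) ** 2)
    dv = np.sqrt((z - cv[0]) ** 2 + (y - cv[1]) ** 2 + (x - cv[2]) ** 2)
    neck = (np.sqrt((z - cz) ** 2 + (x - cx) ** 2) <= rn) & (y >= ca[1]) & (y <= cv[1])
    solid = (da <= ra) | (dv <= rv) | neck
    truth = {
        "r_atrium": ra,
        "r_ventricle": rv,
        "neck_radius": rn,
        "separation": sep,
        "atrium_centre": tuple(ca),
        "ventricle_centre": tuple(cv),
        "disc_centre": tuple((ca + cv) / 2),
        "disc_normal": (0.0, 1.0, 0.0),
    }
    stack = _to_stack({OUTER: solid}, spec.spacing, spec.seed, spec.noise)
    return PhantomResult(stack=stack, truth=truth)


def _nuclei_lattice(spec: PhantomSpec) -> PhantomResult:
    p = {"spacing_um": 8.0, "n_per_axis": 7, "jitter": 0.0, **spec.params}
    a, n, jitter = p["spacing_um"], int(p["n_per_axis"]), p["jitter"]
    if a <= 0 or n < 2:
        raise ValueError("lattice needs positive spacing and >= 2 points per axis")
    ax = np.arange(n) * a
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3).astype(float)
    if jitter > 0:
        rng = np.random.default_rng(spec.seed)
        pts = pts + rng.normal(0.0, jitter, pts.shape)
    interior = np.all((pts > 0) & (pts < (n - 1) * a), axis=1) if jitter == 0 else None
    truth = {
        "spacing_um": a,
        "n_per_axis": n,
        "n_points": n**3,
        "interior_ind_k_le_6": a,
        "interior_mask": interior,
    }
    return PhantomResult(stack=None, truth=truth, nuclei=pts)
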