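"""Shared phantom fixtures.

Phantoms are generated at 1 um-scale voxel spacing — coarse enough that a
whole-suite run stays fast, fine enough that every feature spans >= 5
voxels. Expensive artefacts (contour libraries, centrelines, meshes) are
session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiomorph import (
    build_contour_library,
    extract_centreline,
    mask_to_mesh,
)
from cardiomorph.compartments import VoxelMask
from cardiomorph.phantoms import INNER, OUTER, PhantomSpec, generate


def lib_mask(lib, channel, kind):
    return VoxelMask(lib.mask3d(channel, kind), lib.spacing, lib.origin, label=f"{channel}_{kind}")


@pytest.fixture(scope="session")
def nested():
    """Nested two-layer tube (myocardium/endocardium analogue) + library."""
    res = generate(PhantomSpec("nested_tubes", spacing=(1.0, 0.25, 0.25)))
    lib = build_contour_library(res.stack)
    return res, lib


@pytest.fixture(scope="session")
def straight():
    """Straight one-layer tube with lumen centreline and meshes."""
    res = generate(PhantomSpec("straight_tube", spacing=(1.0, 0.5, 0.5)))
    lib = build_contour_library(res.stack)
    lumen = lib_mask(lib, OUTER, "filled_internal")
    cl = extract_centreline(lumen, res.truth["pole_a"], res.truth["pole_b"])
    ext_mesh = mask_to_mesh(lib_mask(lib, OUTER, "filled_external"))
    int_mesh = mask_to_mesh(lumen)
    return {
        "res": res,
        "truth": res.truth,
        "lib": lib,
        "lumen": lumen,
        "cl": cl,
        "ext_mesh": ext_mesh,
        "int_mesh": int_mesh,
    }


@pytest.fixture(scope="session")
def bent(request):
    """Factory for bent-tube assets keyed by bend angle (degrees)."""
    cache: dict[float, dict] = {}

    def make(angle_deg: float) -> dict:
        if angle_deg not in cache:
            res = generate(
                PhantomSpec("bent_tube", params={"angle_deg": angle_deg}, spacing=(1.0, 1.0, 1.0))
            )
            lib = build_contour_library(res.stack)
            lumen = lib_mask(lib, OUTER, "filled_internal")
            cl = extract_centreline(lumen, res.truth["pole_a"], res.truth["pole_b"])
            cache[angle_deg] = {"res": res, "truth": res.truth, "lib": lib, "lumen": lumen, "cl": cl}
        return cache[angle_deg]

    return make


@pytest.fixture(scope="session")
def shells():
    """Concentric spheres (radii 30/20 um) and their surface meshes."""
    res = generate(PhantomSpec("concentric_shells", spacing=(1.0, 1.0, 1.0)))
    outer_mesh = mask_to_mesh(res.mask(OUTER))
    inner_mesh = mask_to_mesh(res.mask(INNER))
    return {"res": res, "truth": res.truth, "outer_mesh": outer_mesh, "inner_mesh": inner_mesh}


@pytest.fixture(scope="session")
def lattice():
    """Cubic nuclei lattice, spacing 8 um, 7 points per axis."""
    return generate(PhantomSpec("nuclei_lattice"))
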