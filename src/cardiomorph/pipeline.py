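"""Batch pipeline: configuration, stage orchestration, manifest.

One JSON config describes one specimen: the stack and its spacing, which
channel is the outer and which the inner tissue layer, threshold policies,
pole anchors, the chamber-cutting disc, orientation vectors, unrolling
parameters. ``run_pipeline`` executes the requested stages in dependency
order, writes each stage's artifacts (masks as TIFF, meshes as PLY,
tables and heatmaps as CSV) into the output directory, and records a
machine-readable manifest of inputs, parameters and output hashes.
Deterministic stages reproduce identical outputs for identical configs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cardiomorph import __version__
from cardiomorph._geom import normalize
from cardiomorph.cells import assign_chambers, assign_regions, internuclear_distance, load_nuclei
from cardiomorph.centreline import extend_centreline, extract_centreline, looping_metrics, Centreline
from cardiomorph.compartments import VoxelMask, compartment_volumes, ecm_mask
from cardiomorph.contours import build_contour_library
from cardiomorph.meshing import mask_to_mesh, mesh_volume, save_mesh
from cardiomorph.morphometry import ballooning_map, fit_ellipsoid, thickness_map
from cardiomorph.partition import ChamberPartition, CutDisc, chamber_angles, split_by_disc
from cardiomorph.stacks import read_stack
from cardiomorph.unroll import export_heatmap_csv, unroll_heatmap

log = logging.getLogger("cardiomorph")

STAGES = ("segment", "ecm", "mesh", "centreline", "partition", "morphometry", "unroll", "cells")
_DEPS = {
    "segment": (),
    "ecm": ("segment",),
    "mesh": ("segment",),
    "centreline": ("segment",),
    "partition": ("segment",),
    "morphometry": ("mesh", "centreline"),
    "unroll": ("morphometry", "centreline"),
    "cells": (),
}


@dataclass
class RunConfig:
    """Validated per-specimen run configuration."""

    stack_path: str
    spacing: tuple[float, float, float]
    outer_channel: str
    inner_channel: str | None = None
    channel_layout: str = "interleaved"
    threshold: dict = field(default_factory=dict)  # per channel: {"threshold":..., "min_area":...}
    pole_a: tuple[float, float, float] | None = None
    pole_b: tuple[float, float, float] | None = None
    disc: dict | None = None  # {"centre": [...], "normal": [...], "radius": r}
    dorsal_ref: tuple[float, float, float] = (0.0, 1.0, 0.0)
    triad: list | None = None
    n_planes: int = 100
    n_angle_bins: int = 72
    extension_frac: float = 0.05
    k_neighbours: int = 4
    nuclei_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("invalid config field 'spacing': components must be positive")
        self.dorsal_ref = tuple(normalize(self.dorsal_ref))
        if self.disc is not None:
            self.disc = {
                "centre": [float(v) for v in self.disc["centre"]],
                "normal": list(normalize(self.disc["normal"])),
                "radius": float(self.disc["radius"]),
            }

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        cfg = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"invalid config field(s): {sorted(unknown)}")
        return cls(**cfg)

    def to_json(self, path: str | Path) -> Path:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(json.dumps(payload, indent=2, default=list))
        return Path(path)

    def cut_disc(self) -> CutDisc:
        if self.disc is None:
            raise ValueError("config defines no cutting disc")
        return CutDisc(self.disc["centre"], self.disc["normal"], self.disc["radius"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path, stages=None) -> dict:
    """Execute the requested stages and return the manifest dict.

    Stage dependencies must be included in ``stages`` (or already have
    their artifacts from this call); a missing dependency raises.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    ordered = [s for s in STAGES if s in stages]
    done: set[str] = set()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    manifest: dict = {
        "version": __version__,
        "config": json.loads(json.dumps({k: getattr(config, k) for k in config.__dataclass_fields__}, default=list)),
        "stages": {},
    }

    for stage in ordered:
        missing = [d for d in _DEPS[stage] if d not in done and d not in stages]
        if missing:
            raise ValueError(f"stage {stage!r} requires stage(s) {missing}")
        log.info("stage %s", stage)
        outputs = _run_stage(stage, config, out_dir, state)
        manifest["stages"][stage] = {
            "outputs": {name: _sha256(Path(p)) for name, p in outputs.items()},
            "files": {name: str(p) for name, p in outputs.items()},
        }
        done.add(stage)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _channels(config: RunConfig) -> list[str]:
    return [c for c in (config.outer_channel, config.inner_channel) if c]


def _run_stage(stage: str, config: RunConfig, out: Path, state: dict) -> dict[str, Path]:
    outputs: dict[str, Path] = {}

    if stage == "segment":
        stack = read_stack(config.stack_path, config.spacing, _channels(config), layout=config.channel_layout)
        log.info("threshold policies: %s (default: per-slice Otsu, min_area 25 px)", config.threshold or "{}")
        library = build_contour_library(stack, per_channel_policy=config.threshold)
        state["stack"], state["library"] = stack, library
        outputs["library"] = library.save(out / "library") / "library.json"

    elif stage == "ecm":
        lib = state["library"]
        if config.inner_channel is None:
            raise ValueError("ecm stage requires an inner_channel")
        inner_bound = VoxelMask(lib.mask3d(config.outer_channel, "filled_internal"), lib.spacing, lib.origin)
        outer_bound = VoxelMask(lib.mask3d(config.inner_channel, "filled_external"), lib.spacing, lib.origin)
        ecm, leak = ecm_mask(inner_bound, outer_bound)
        log.info("ecm leak voxels: %d", leak)
        state["ecm"] = ecm
        outputs["ecm_mask"] = ecm.save(out / "ecm.tif")
        vols = compartment_volumes(lib, config.outer_channel, config.inner_channel)
        vols.to_csv(out / "compartment_volumes.csv", index=False)
        outputs["compartment_volumes"] = out / "compartment_volumes.csv"

    elif stage == "mesh":
        lib = state["library"]
        meshes = {}
        rows = []
        for ch in _channels(config):
            for kind in ("tissue", "filled_external", "filled_internal"):
                m = VoxelMask(lib.mask3d(ch, kind), lib.spacing, lib.origin, label=f"{ch}_{kind}")
                if not m.voxels.any():
                    continue
                mesh = mask_to_mesh(m)
                meshes[f"{ch}_{kind}"] = mesh
                p = out / f"mesh_{ch}_{kind}.ply"
                save_mesh(mesh, p)
                outputs[f"mesh_{ch}_{kind}"] = p
                rows.append({"mesh": f"{ch}_{kind}", "volume_um3": mesh_volume(mesh), "mask_volume_um3": m.volume()})
        state["meshes"] = meshes
        pd.DataFrame(rows).to_csv(out / "mesh_volumes.csv", index=False)
        outputs["mesh_volumes"] = out / "mesh_volumes.csv"

    elif stage == "centreline":
        lib = state["library"]
        if config.pole_a is None or config.pole_b is None:
            raise ValueError("centreline stage requires pole_a and pole_b")
        lumen = VoxelMask(lib.mask3d(config.outer_channel, "filled_internal"), lib.spacing, lib.origin, label="lumen")
        cl = extract_centreline(lumen, config.pole_a, config.pole_b)
        state["centreline"] = cl
        outputs["centreline"] = cl.to_csv(out / "centreline.csv")
        metrics = looping_metrics(cl)
        pd.DataFrame([metrics]).to_csv(out / "looping.csv", index=False)
        outputs["looping"] = out / "looping.csv"

    elif stage == "partition":
        lib = state["library"]
        disc = config.cut_disc()
        target = VoxelMask(lib.mask3d(config.outer_channel, "filled_external"), lib.spacing, lib.origin)
        part = split_by_disc(target, disc)
        state["partition"] = part
        rows = [
            {"chamber": ch, "volume_um3": part.chamber_volume(ch)}
            for ch in ("atrium", "ventricle")
        ]
        pd.DataFrame(rows).to_csv(out / "chamber_volumes.csv", index=False)
        outputs["chamber_volumes"] = out / "chamber_volumes.csv"
        if "centreline" in state:
            angles = {}
            for view in ("ventral", "lateral"):
                angles.update(
                    {f"{view}_{k}": v for k, v in chamber_angles(part, state["centreline"], config.dorsal_ref, view=view).items()}
                )
            pd.DataFrame([angles]).to_csv(out / "chamber_angles.csv", index=False)
            outputs["chamber_angles"] = out / "chamber_angles.csv"

    elif stage == "morphometry":
        meshes, cl = state["meshes"], state["centreline"]
        triad = np.asarray(config.triad, dtype=float) if config.triad else None
        rows = []
        ext = meshes.get(f"{config.outer_channel}_filled_external")
        if ext is not None:
            fit = fit_ellipsoid(ext, triad)
            rows.append({"mesh": "outer_filled_external", "semi_a": fit.semi_axes[0], "semi_b": fit.semi_axes[1], "semi_c": fit.semi_axes[2], "asphericity": fit.asphericity})
            bal = ballooning_map(ext, cl)
            state["ballooning_mesh"] = bal
            p = out / "ballooning.ply"
            save_mesh(bal, p)
            outputs["ballooning_mesh"] = p
        inner = meshes.get(f"{config.outer_channel}_filled_internal")
        if ext is not None and inner is not None:
            thick = thickness_map(inner, ext, carrier="outer")
            state["thickness_mesh"] = thick
            p = out / "thickness.ply"
            save_mesh(thick, p)
            outputs["thickness_mesh"] = p
        pd.DataFrame(rows).to_csv(out / "ellipsoid.csv", index=False)
        outputs["ellipsoid"] = out / "ellipsoid.csv"

    elif stage == "unroll":
        cl = state["centreline"]
        extended = extend_centreline(cl, config.extension_frac * cl.length)
        for name in ("ballooning_mesh", "thickness_mesh"):
            mesh = state.get(name)
            if mesh is None:
                continue
            hmap = unroll_heatmap(mesh, extended, config.dorsal_ref, config.n_planes, config.n_angle_bins)
            p = out / f"heatmap_{name.removesuffix('_mesh')}.csv"
            export_heatmap_csv(hmap, p)
            outputs[name.removesuffix("_mesh") + "_heatmap"] = p

    elif stage == "cells":
        if config.nuclei_path is None:
            raise ValueError("cells stage requires nuclei_path")
        nuclei = load_nuclei(config.nuclei_path)
        if config.disc is not None:
            nuclei = assign_chambers(nuclei, config.cut_disc())
        if "centreline" in state:
            nuclei = assign_regions(nuclei, state["centreline"], config.dorsal_ref)
        ind, summary = internuclear_distance(nuclei, config.k_neighbours)
        outputs["nuclei"] = nuclei.to_csv(out / "nuclei.csv", ind=ind)
        summary.to_csv(out / "ind_summary.csv", index=False)
        outputs["ind_summary"] = out / "ind_summary.csv"

    return outputs
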