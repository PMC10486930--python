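"""TIFF / CSV / JSON input-output helpers.

Stacks are written as paired single-channel multi-page TIFFs
(``<name>_green.tif`` / ``<name>_red.tif``, one page per z-slice) with a
JSON sidecar recording the voxel size; planted ground truth goes into a
``<name>_truth.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .mitoquant import VoxelStack
from .synth import MitoRecord, StackTruth


def write_stack(stack: VoxelStack, directory, name: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{name}_green.tif", stack.green)
    tifffile.imwrite(directory / f"{name}_red.tif", stack.red)
    (directory / f"{name}_meta.json").write_text(
        json.dumps({"voxel_size_um": stack.voxel_size_um})
    )


def read_stack(directory, name: str) -> VoxelStack:
    directory = Path(directory)
    green = tifffile.imread(directory / f"{name}_green.tif")
    red = tifffile.imread(directory / f"{name}_red.tif")
    meta_path = directory / f"{name}_meta.json"
    voxel = 0.4
    if meta_path.exists():
        voxel = json.loads(meta_path.read_text()).get("voxel_size_um", 0.4)
    return VoxelStack(green=green, red=red, voxel_size_um=voxel)


def list_stacks(directory) -> list[str]:
    """Stack base names found in a directory (paired *_green/*_red files)."""
    directory = Path(directory)
    names = sorted(p.name[: -len("_green.tif")] for p in directory.glob("*_green.tif"))
    return [n for n in names if (directory / f"{n}_red.tif").exists()]


def write_truth(truth: StackTruth, directory, name: str) -> None:
    directory = Path(directory)
    payload = {
        "voxel_size_um": truth.voxel_size_um,
        "mito_records": [
            {
                "id": r.id,
                "planted_enclosed": bool(r.planted_enclosed),
                "voxels": r.voxels.tolist(),
            }
            for r in truth.mito_records
        ],
        "n_astrocytes": len(truth.astro_masks),
    }
    (directory / f"{name}_truth.json").write_text(json.dumps(payload))


def read_truth_records(directory, name: str) -> list[MitoRecord]:
    payload = json.loads((Path(directory) / f"{name}_truth.json").read_text())
    return [
        MitoRecord(
            id=r["id"],
            voxels=np.asarray(r["voxels"], dtype=int),
            planted_enclosed=r["planted_enclosed"],
        )
        for r in payload["mito_records"]
    ]
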