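"""NIfTI-1 I/O for scalar maps, masks and structure sets.

Maps and masks are exchanged as .nii/.nii.gz volumes with diagonal
(axis-aligned) affines; a structure set is a directory of mask files plus a
YAML/JSON manifest mapping each role name (TV1, TV2, GTV, muscle, ...) to a
file. Masks are written as unsigned bytes; any nonzero voxel on read counts
as inside, which tolerates the common 0/1, 0/255 and float dialects.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import Not3DVolumeError, NonPositiveSpacingError, NonAxisAlignedError
from .grid import ImageGrid, Quantity, ScalarMap, StructureSet


def _grid_from_affine(shape, affine) -> ImageGrid:
    lin = np.asarray(affine)[:3, :3]
    off = np.abs(lin - np.diag(np.diag(lin)))
    if np.any(off > 1e-6 * max(1.0, np.abs(lin).max())):
        raise NonAxisAlignedError(
            "affine has rotation/shear terms; only axis-aligned grids are supported"
        )
    spacing = np.diag(lin)
    if np.any(spacing <= 0):
        # negative diagonal = flipped axis; take magnitude but refuse zeros
        if np.any(spacing == 0):
            raise NonPositiveSpacingError("affine declares a zero voxel spacing")
        spacing = np.abs(spacing)
    origin = np.asarray(affine)[:3, 3]
    return ImageGrid(tuple(shape), tuple(spacing), tuple(origin))


def read_scalar_map(path: str | os.PathLike, expected_quantity: Quantity = "uptake") -> ScalarMap:
    """Read a 3-D NIfTI volume as a ScalarMap.

    Raises FileNotFoundError for a missing file, Not3DVolumeError for non-3-D
    data and NonPositiveSpacingError for degenerate headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise Not3DVolumeError(f"{path}: not a 3-D scalar volume (shape {data.shape})")
    grid = _grid_from_affine(data.shape, img.affine)
    return ScalarMap(grid, np.asarray(data, dtype=np.float64), expected_quantity)


def write_scalar_map(smap: ScalarMap, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(smap.values.astype(np.float64), smap.grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> ScalarMap:
    """Read a mask volume; any nonzero voxel maps to 1."""
    smap = read_scalar_map(path, "uptake")
    return ScalarMap(smap.grid, (smap.values != 0).astype(np.float64), "uptake")


def write_mask(mask: np.ndarray, grid: ImageGrid, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), grid.affine)
    nib.save(img, str(path))


def read_structure_set(manifest_path: str | os.PathLike) -> StructureSet:
    """Load a structure set from a manifest (YAML or JSON: role -> mask file).

    Relative mask paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    text = manifest_path.read_text()
    entries = (json.loads(text) if manifest_path.suffix == ".json"
               else yaml.safe_load(text))
    if not isinstance(entries, dict) or not entries:
        raise ValueError(f"{manifest_path}: manifest must map role names to files")
    grid = None
    masks = {}
    for role, rel in entries.items():
        mpath = manifest_path.parent / rel
        m = read_mask(mpath)
        if grid is None:
            grid = m.grid
        masks[role] = m.values != 0
    ss = StructureSet(grid, {})
    for role, arr in masks.items():
        ss.add(role, arr)
    ss._warn_nesting()
    return ss


def write_structure_set(structures: StructureSet, out_dir: str | os.PathLike,
                        manifest_name: str = "structures.yaml") -> Path:
    """Write each mask as <role>.nii.gz plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for role in structures.names():
        fname = f"{role.replace('/', '_')}.nii.gz"
        write_mask(structures[role], structures.grid, out_dir / fname)
        entries[role] = fname
    manifest = out_dir / manifest_name
    manifest.write_text(yaml.safe_dump(entries, sort_keys=True))
    return manifest
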