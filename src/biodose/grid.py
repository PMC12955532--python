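"""Regular-grid scalar fields, binary masks, and volume algebra.

All images in the package live on an :class:`ImageGrid` — an axis-aligned
regular 3-D grid defined by shape, spacing (mm) and origin (mm, world
coordinate of the centre of voxel (0,0,0)). Arrays are indexed (i,j,k) along
the grid's x/y/z world axes. Co-registration is assumed upstream: maps and
masks that interact must share one grid, enforced by equality checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Tuple

import numpy as np
from scipy import ndimage

from .errors import (
    DisjointExtentError,
    EmptyMaskError,
    GridMismatchError,
    NonPositiveSpacingError,
)

Quantity = Literal["uptake", "pO2_mmHg", "density_per_cm3", "dose_Gy"]

#: quantities that must be non-negative everywhere
_NONNEG = {"pO2_mmHg", "density_per_cm3", "dose_Gy"}


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned regular grid: voxel counts, spacing and origin in mm."""

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise NonPositiveSpacingError(f"spacing must be > 0, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in cm³ (spacing is mm, 1 cm³ = 1000 mm³)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index → world-mm affine (diagonal, voxel-centre convention)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff

    def world_extent(self) -> Tuple[np.ndarray, np.ndarray]:
        """(lo, hi) world coordinates of the outer voxel faces."""
        o = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        sh = np.asarray(self.shape)
        return o - sp / 2.0, o + (sh - 0.5) * sp

    def coordinate_arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis (1-D arrays)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )


@dataclass
class ScalarMap:
    """A scalar field on an :class:`ImageGrid` with a declared physical quantity."""

    grid: ImageGrid
    values: np.ndarray
    quantity: Quantity = "uptake"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.quantity in _NONNEG and np.any(self.values < 0):
            raise ValueError(f"{self.quantity} map contains negative values")

    def with_values(self, values: np.ndarray, quantity: Quantity | None = None) -> "ScalarMap":
        return ScalarMap(self.grid, values, quantity or self.quantity)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


class StructureSet:
    """Named binary masks sharing one grid.

    Clinical nesting (GTV ⊆ TV2 ⊆ TV1, HTV ⊆ TV2) is checked with a warning,
    not an error: real contour sets may disagree by a voxel.
    """

    def __init__(self, grid: ImageGrid, masks: dict | None = None):
        self.grid = grid
        self.masks: dict[str, np.ndarray] = {}
        for name, m in (masks or {}).items():
            self.add(name, m)
        self._warn_nesting()

    def add(self, name: str, mask: np.ndarray) -> None:
        m = _as_bool(mask)
        if m.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask '{name}' shape {m.shape} != grid shape {self.grid.shape}"
            )
        self.masks[name] = m

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> Iterable[str]:
        return self.masks.keys()

    def _warn_nesting(self) -> None:
        pairs = [("GTV", "TV2"), ("TV2", "TV1"), ("HTV", "TV2")]
        for inner, outer in pairs:
            if inner in self.masks and outer in self.masks:
                stray = int(np.count_nonzero(self.masks[inner] & ~self.masks[outer]))
                if stray:
                    warnings.warn(
                        f"{stray} voxels of {inner} lie outside {outer}; "
                        "expected nested structures",
                        stacklevel=3,
                    )


# ---------------------------------------------------------------------------
# volume algebra

def mask_algebra(a: np.ndarray, b: np.ndarray,
                 op: Literal["difference", "intersection", "union"]) -> np.ndarray:
    """Voxelwise set operation on two masks of identical shape."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if op == "difference":
        return a & ~b
    if op == "intersection":
        return a & b
    if op == "union":
        return a | b
    raise ValueError(f"unknown op {op!r}")


def mask_volume(mask: np.ndarray, grid: ImageGrid) -> float:
    """Volume of a mask in cm³ (voxel count × voxel volume)."""
    m = _as_bool(mask)
    if m.shape != grid.shape:
        raise GridMismatchError(f"mask shape {m.shape} != grid shape {grid.shape}")
    return float(np.count_nonzero(m)) * grid.voxel_volume


def subtarget_masks(structures: StructureSet) -> dict[str, np.ndarray]:
    """Build the dose-painting subtargets from TV2/GTV/HTV.

    Returns masks for "TV2-GTV" (TV2 excluding GTV), "GTV-HTV" (GTV excluding
    HTV) and "HTV". If HTV is absent or empty it is omitted and GTV-HTV
    degenerates to the whole GTV.
    """
    tv2, gtv = structures["TV2"], structures["GTV"]
    out = {"TV2-GTV": mask_algebra(tv2, gtv, "difference")}
    htv = structures.masks.get("HTV")
    if htv is not None and htv.any():
        out["GTV-HTV"] = mask_algebra(gtv, htv, "difference")
        out["HTV"] = htv.copy()
    else:
        out["GTV-HTV"] = gtv.copy()
    return out


# ---------------------------------------------------------------------------
# resampling

def resample_to_grid(smap: ScalarMap, target: ImageGrid,
                     mode: Literal["nearest", "linear"] = "linear") -> ScalarMap:
    """Resample a map onto another axis-aligned grid.

    World coordinates of target voxel centres are converted to fractional
    source indices and interpolated (order 0 for ``nearest``, 1 for
    ``linear``). Nearest mode maps binary inputs to binary outputs.
    """
    src = smap.grid
    if target == src:
        return ScalarMap(target, smap.values.copy(), smap.quantity)
    lo_s, hi_s = src.world_extent()
    lo_t, hi_t = target.world_extent()
    if np.any(hi_t < lo_s) or np.any(lo_t > hi_s):
        raise DisjointExtentError("target grid shares no physical extent with source")
    coords = np.meshgrid(*target.coordinate_arrays(), indexing="ij")
    idx = [
        (coords[a] - src.origin[a]) / src.spacing[a] for a in range(3)
    ]
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(
        smap.values, np.stack(idx), order=order, mode="nearest"
    )
    return ScalarMap(target, out.reshape(target.shape), smap.quantity)


def require_same_grid(*objs) -> ImageGrid:
    """Assert that all ScalarMaps/StructureSets share one grid; return it."""
    grids = [o.grid for o in objs]
    g0 = grids[0]
    for g in grids[1:]:
        if g != g0:
            raise GridMismatchError(f"grids differ: {g0} vs {g}")
    return g0


def masked_nonempty(mask: np.ndarray, what: str = "mask") -> np.ndarray:
    m = _as_bool(mask)
    if not m.any():
        raise EmptyMaskError(f"{what} is empty")
    return m
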