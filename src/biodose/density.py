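"""FDG uptake → clonogenic cell density, with a uniform fallback.

Normalized FDG uptake (muscle reference = 1) maps linearly onto clonogenic
cell density between two calibration anchors: baseline density 1e7 cells/cm³
at the reference uptake and the carrying capacity 1e9 cells/cm³ at the
cohort-maximum normalized uptake of ~30. Values are clamped to that range so
no voxel carries a zero or super-capacity clonogen load. Patients without an
FDG scan get a uniform 1e7 cells/cm³ throughout TV2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyReferenceError, GridMismatchError
from .grid import ImageGrid, ScalarMap, masked_nonempty


@dataclass(frozen=True)
class CellDensityParams:
    """Calibration anchors of the linear uptake→density map.

    slope_A (cells/cm³ per unit normalized uptake) is derived from the two
    anchors unless explicitly overridden.
    """

    U_ref: float = 1.0
    U_max: float = 30.0
    rho_base: float = 1e7
    rho_max: float = 1e9
    fallback_density: float = 1e7
    slope_A: float | None = None

    def __post_init__(self):
        if not self.rho_base < self.rho_max:
            raise ValueError("rho_base must be < rho_max")
        if not self.U_ref < self.U_max:
            raise ValueError("U_ref must be < U_max")

    @property
    def slope(self) -> float:
        if self.slope_A is not None:
            return self.slope_A
        return (self.rho_max - self.rho_base) / (self.U_max - self.U_ref)


def normalize_fdg(uptake: ScalarMap, muscle: np.ndarray) -> ScalarMap:
    """Divide an FDG image by its muscle-mask mean; muscle mean of output is 1."""
    m = masked_nonempty(muscle, "muscle reference region")
    if m.shape != uptake.grid.shape:
        raise GridMismatchError(
            f"muscle mask shape {m.shape} != image grid shape {uptake.grid.shape}")
    ref_mean = float(uptake.values[m].mean())
    if ref_mean <= 0:
        raise EmptyReferenceError(f"muscle reference mean is non-positive ({ref_mean})")
    return uptake.with_values(uptake.values / ref_mean, "uptake")


def uptake_to_density(U, params: CellDensityParams = CellDensityParams()):
    """ρ(U) = rho_base + A·(U − U_ref), clamped to [rho_base, rho_max].

    Exact at both anchors; monotone non-decreasing. Accepts scalar, array or
    ScalarMap (maps come back with quantity ``density_per_cm3``).
    """
    if isinstance(U, ScalarMap):
        return U.with_values(uptake_to_density(U.values, params), "density_per_cm3")
    u = np.asarray(U, dtype=np.float64)
    rho = params.rho_base + params.slope * (u - params.U_ref)
    rho = np.clip(rho, params.rho_base, params.rho_max)
    return float(rho) if np.ndim(U) == 0 else rho


def uniform_density(tv2: np.ndarray, grid: ImageGrid,
                    params: CellDensityParams = CellDensityParams()) -> ScalarMap:
    """Fallback when FDG is unavailable: fallback_density inside TV2, 0 outside."""
    m = masked_nonempty(tv2, "TV2")
    vals = np.where(m, params.fallback_density, 0.0)
    return ScalarMap(grid, vals, "density_per_cm3")
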