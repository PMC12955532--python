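"""Oxygen-modified linear-quadratic cell kill, Poisson TCP and EQD2.

Survival after n equal fractions of total dose D with per-fraction dose
d = D/n is

    SF = exp(−n·[α·(f·d) + β·(f·d)²]),

where f is a voxelwise dose-modifying factor derived from oxygen tension.
The oxygen enhancement ratio

    OER(p) = OER_max·(k + p) / (k + OER_max·p)

equals OER_max under anoxia and tends to 1 at full oxygenation; the survival
model applies its reciprocal, f = 1/OER, so that an anoxic voxel needs an
OER_max-fold larger dose for the same kill — hypoxia confers resistance.
(The two conventions for f found in the literature differ by this
reciprocal; applying OER itself as a dose multiplier would make hypoxic
voxels *more* sensitive, which is radiobiologically inconsistent with dose
escalation in hypoxic subvolumes. See docs/methods.md.)

Tumour control probability over a volume of interest is the Poisson
probability that no clonogen survives:

    TCP = ∏_i exp(−η_i·SF_i) = exp(−Σ_i η_i·SF_i),   η_i = v·ρ_i,

with v the voxel volume (cm³) and ρ_i the clonogen density (cells/cm³).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, GridMismatchError
from .grid import ScalarMap, require_same_grid


@dataclass(frozen=True)
class RadiobioParams:
    """LQ and oxygen-effect parameters.

    alpha (Gy⁻¹) and beta (Gy⁻²) are literature values typical of HNSCC
    (α/β = 10 Gy); OER_max and k (mmHg) shape the oxygen enhancement ratio;
    n_fractions is the number of equal fractions the total dose is split into.
    """

    alpha: float = 0.35
    beta: float = 0.035
    n_fractions: int = 35
    oer_max: float = 3.0
    k: float = 2.5

    def __post_init__(self):
        if self.alpha <= 0 or self.beta < 0:
            raise ValueError("alpha must be > 0 and beta >= 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.oer_max < 1 or self.k <= 0:
            raise ValueError("OER_max must be >= 1 and k > 0")


@dataclass(frozen=True)
class FractionationParams:
    """α/β ratios (Gy) used for EQD2 conversion of target and OAR doses."""

    ab_tumor: float = 10.0
    ab_oar: float = 3.0

    def __post_init__(self):
        if self.ab_tumor <= 0 or self.ab_oar <= 0:
            raise ValueError("alpha/beta ratios must be positive")


def _scalar_or_array(x, out):
    return float(out) if np.ndim(x) == 0 else out


def oer(pO2, params: RadiobioParams = RadiobioParams()):
    """Oxygen enhancement ratio OER(p) = OER_max·(k+p)/(k+OER_max·p).

    Strictly decreasing from OER_max at p = 0 toward 1 as p → ∞.
    Accepts scalar, array or ScalarMap.
    """
    if isinstance(pO2, ScalarMap):
        return pO2.with_values(oer(pO2.values, params), "uptake")
    p = np.asarray(pO2, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("pO2 must be >= 0")
    out = params.oer_max * (params.k + p) / (params.k + params.oer_max * p)
    return _scalar_or_array(pO2, out)


def dose_modifying_factor(pO2, params: RadiobioParams = RadiobioParams()):
    """f = 1/OER(pO2) ∈ [1/OER_max, 1]; the effective-dose multiplier in SF."""
    if isinstance(pO2, ScalarMap):
        return pO2.with_values(dose_modifying_factor(pO2.values, params), "uptake")
    return _scalar_or_array(pO2, 1.0 / oer(np.asarray(pO2, dtype=np.float64), params))


def surviving_fraction(total_dose, f, params: RadiobioParams = RadiobioParams()):
    """LQ surviving fraction for a total dose split into n equal fractions.

    SF = exp(−n·(α·f·d + β·(f·d)²)) with d = total_dose/n. Vectorized over
    dose and f (broadcast together).
    """
    D = np.asarray(total_dose, dtype=np.float64)
    if np.any(D < 0):
        raise ValueError("dose must be >= 0")
    fd = np.asarray(f, dtype=np.float64) * D / params.n_fractions
    out = np.exp(-params.n_fractions * (params.alpha * fd + params.beta * fd**2))
    return float(out) if out.ndim == 0 else out


def _eta_sf(dose: ScalarMap, density: ScalarMap, pO2: ScalarMap,
            voi: np.ndarray, params: RadiobioParams):
    grid = require_same_grid(dose, density, pO2)
    m = np.asarray(voi).astype(bool)
    if m.shape != grid.shape:
        raise GridMismatchError(f"VOI shape {m.shape} != grid shape {grid.shape}")
    if not m.any():
        raise EmptyMaskError("VOI is empty")
    f = dose_modifying_factor(pO2.values[m], params)
    sf = surviving_fraction(dose.values[m], f, params)
    eta = grid.voxel_volume * density.values[m]
    return grid, m, eta * sf


def tcp(dose: ScalarMap, density: ScalarMap, pO2: ScalarMap, voi: np.ndarray,
        params: RadiobioParams = RadiobioParams()) -> float:
    """Poisson TCP over a VOI: exp(−Σ expected surviving clonogens).

    Multiplicative over disjoint VOIs; voxels with zero density contribute a
    factor of 1.
    """
    _, _, survivors = _eta_sf(dose, density, pO2, voi, params)
    return float(np.exp(-survivors.sum()))


def surviving_cell_map(dose: ScalarMap, density: ScalarMap, pO2: ScalarMap,
                       voi: np.ndarray,
                       params: RadiobioParams = RadiobioParams()) -> ScalarMap:
    """Expected surviving clonogens η_i·SF_i per voxel inside the VOI, 0 outside.

    exp(−sum(map)) reproduces :func:`tcp` exactly.
    """
    grid, m, survivors = _eta_sf(dose, density, pO2, voi, params)
    out = np.zeros(grid.shape)
    out[m] = survivors
    return ScalarMap(grid, out, "density_per_cm3")


def eqd2(total_dose, n_fractions: int, ab: float):
    """Equivalent dose in 2-Gy fractions: EQD2 = D·(d + αβ)/(2 + αβ), d = D/n.

    Identity when d = 2 Gy; monotone increasing in D. Accepts scalar, array
    or ScalarMap.
    """
    if ab <= 0:
        raise ValueError("alpha/beta ratio must be positive")
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if isinstance(total_dose, ScalarMap):
        return total_dose.with_values(
            eqd2(total_dose.values, n_fractions, ab), "dose_Gy")
    D = np.asarray(total_dose, dtype=np.float64)
    if np.any(D < 0):
        raise ValueError("dose must be >= 0")
    out = D * (D / n_fractions + ab) / (2.0 + ab)
    return _scalar_or_array(total_dose, out)
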