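"""TCP-targeted dose prescription: voxelwise inversion and contour collapse.

The ideal dose map inverts the cell-kill model: every VOI voxel is assigned
an equal share of the allowed expected-survivor budget,

    η_i·SF_i(D_i) = −ln(TCP_target) / N,

so the Poisson product over the VOI reproduces the design TCP exactly. Per
voxel the per-fraction effective dose x = f_i·d_i solves the LQ quadratic
β·x² + α·x = −ln(s_i)/n in closed form (positive root), with s_i the
required per-voxel surviving fraction.

Dose painting by contours then replaces the heterogeneous ideal map with one
homogeneous dose per subtarget,

    D_P = D̄·[1 − (γ / (2·TCP_target))·(σ_D/D̄)²],

a second-order correction (TCP-curve slope γ) that lowers the prescription
below the in-contour mean D̄ in proportion to the squared relative spread
σ_D/D̄, and reduces to D̄ for a homogeneous ideal map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .cellkill import RadiobioParams, dose_modifying_factor
from .errors import EmptyMaskError, GridMismatchError
from .grid import ScalarMap, StructureSet, require_same_grid

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrescriptionParams:
    """Design TCP, TCP-curve slope γ, and a total-dose safety cap (Gy)."""

    tcp_target: float = 0.95
    gamma: float = 4.0
    max_total_dose: float = 120.0

    def __post_init__(self):
        if not 0 < self.tcp_target < 1:
            raise ValueError("tcp_target must lie in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class SubtargetPrescription:
    """Per-contour summary of the ideal dose map and its homogeneous collapse."""

    name: str
    mean_dose: float
    sd_dose: float
    homogeneous_dose: float
    voxel_count: int


def ideal_dose_map(density: ScalarMap, pO2: ScalarMap, voi: np.ndarray,
                   rb: RadiobioParams = RadiobioParams(),
                   rx: PrescriptionParams = PrescriptionParams()) -> ScalarMap:
    """Voxelwise total dose achieving the design TCP over the VOI.

    Requires strictly positive density at every VOI voxel. Voxels whose
    clonogen load is already below the per-voxel survivor budget (required
    SF ≥ 1) receive zero dose with a warning; doses above the safety cap are
    clamped with a warning.
    """
    grid = require_same_grid(density, pO2)
    m = np.asarray(voi).astype(bool)
    if m.shape != grid.shape:
        raise GridMismatchError(f"VOI shape {m.shape} != grid shape {grid.shape}")
    if not m.any():
        raise EmptyMaskError("VOI is empty")
    rho = density.values[m]
    if np.any(rho <= 0):
        raise ValueError("density must be > 0 at every VOI voxel")
    n_vox = int(m.sum())
    budget = -np.log(rx.tcp_target) / n_vox          # allowed survivors per voxel
    eta = grid.voxel_volume * rho
    s_req = budget / eta                              # required surviving fraction
    attainable = s_req < 1.0
    if not np.all(attainable):
        warnings.warn(
            f"{int((~attainable).sum())} VOI voxels already satisfy the control "
            "budget without dose; assigned 0 Gy")
    effect = np.zeros_like(s_req)
    effect[attainable] = -np.log(s_req[attainable]) / rb.n_fractions
    # positive root of beta*x^2 + alpha*x - effect = 0
    if rb.beta > 0:
        x = (-rb.alpha + np.sqrt(rb.alpha**2 + 4.0 * rb.beta * effect)) / (2.0 * rb.beta)
    else:
        x = effect / rb.alpha
    f = dose_modifying_factor(pO2.values[m], rb)
    total = rb.n_fractions * x / f
    over = total > rx.max_total_dose
    if np.any(over):
        warnings.warn(
            f"{int(over.sum())} VOI voxels exceed the {rx.max_total_dose} Gy "
            "safety cap; clamped")
        total = np.minimum(total, rx.max_total_dose)
    out = np.zeros(grid.shape)
    out[m] = total
    return ScalarMap(grid, out, "dose_Gy")


def contour_prescription(ideal: ScalarMap, subtargets: dict[str, np.ndarray] | StructureSet,
                         rx: PrescriptionParams = PrescriptionParams()
                         ) -> list[SubtargetPrescription]:
    """Collapse an ideal dose map to homogeneous per-contour prescriptions.

    ``subtargets`` maps contour names (TV2-GTV, GTV-HTV, HTV) to masks;
    empty or absent contours are omitted (a non-hypoxic case has no HTV row).
    """
    masks = subtargets.masks if isinstance(subtargets, StructureSet) else subtargets
    out: list[SubtargetPrescription] = []
    for name, mask in masks.items():
        m = np.asarray(mask).astype(bool)
        if m.shape != ideal.grid.shape:
            raise GridMismatchError(
                f"subtarget '{name}' shape {m.shape} != grid {ideal.grid.shape}")
        if not m.any():
            log.info("subtarget %s is empty; omitted from prescription", name)
            continue
        d = ideal.values[m]
        mean = float(d.mean())
        sd = float(d.std())
        if mean > 0:
            dp = mean * (1.0 - (rx.gamma / (2.0 * rx.tcp_target)) * (sd / mean) ** 2)
        else:
            dp = 0.0
        out.append(SubtargetPrescription(
            name=name, mean_dose=mean, sd_dose=sd,
            homogeneous_dose=dp, voxel_count=int(m.sum())))
    if not out:
        raise EmptyMaskError("no non-empty subtargets to prescribe")
    return out
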