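"""Plan evaluation: DVH metrics, OAR constraints, indices and biological volumes.

Dose-volume metrics use integer voxel-counting semantics: D at volume
fraction q is the minimum dose among the hottest ceil(q·N) voxels of the
structure (no DVH interpolation), so D2% on 100 voxels is the cooler of the
two hottest. Constraints are checked on EQD2-converted dose with the OAR
α/β. The conformity index is Paddick's

    CI = |VOI ∩ V_Rx|² / (|VOI|·|V_Rx|),

with V_Rx the isodose volume at the prescription, and the homogeneity index
is (D2% − D98%)/D50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .cellkill import FractionationParams, eqd2
from .errors import EmptyMaskError, GridMismatchError
from .grid import ScalarMap, StructureSet, mask_volume


@dataclass(frozen=True)
class DoseConstraint:
    """An OAR dose limit in EQD2 Gy.

    metric is "D2%" (near-maximum) or "Dmean". combination_rule="parotid"
    marks constraints that participate in the either-parotid sparing rule.
    """

    structure: str
    metric: Literal["D2%", "Dmean"]
    limit: float
    combination_rule: str | None = None

    def __post_init__(self):
        if self.limit <= 0:
            raise ValueError("constraint limit must be positive")


def default_constraints() -> list[DoseConstraint]:
    """Head-and-neck OAR constraint set (EQD2 Gy):

    spinal cord and brainstem D2% < 45; mandible D2% < 70 and mean < 54;
    parotid rule — mean < 20 Gy for at least one gland, or < 25 Gy combined.
    """
    return [
        DoseConstraint("spinal_cord", "D2%", 45.0),
        DoseConstraint("brainstem", "D2%", 45.0),
        DoseConstraint("mandible", "D2%", 70.0),
        DoseConstraint("mandible", "Dmean", 54.0),
        DoseConstraint("parotid_left", "Dmean", 20.0, combination_rule="parotid"),
        DoseConstraint("parotid_right", "Dmean", 20.0, combination_rule="parotid"),
    ]


PAROTID_COMBINED_LIMIT = 25.0


def _voi_values(dose: ScalarMap, voi: np.ndarray) -> np.ndarray:
    m = np.asarray(voi).astype(bool)
    if m.shape != dose.grid.shape:
        raise GridMismatchError(f"VOI shape {m.shape} != grid {dose.grid.shape}")
    if not m.any():
        raise EmptyMaskError("VOI is empty")
    return dose.values[m]


def dose_at_volume(dose: ScalarMap, voi: np.ndarray, fraction: float) -> float:
    """Minimum dose among the hottest ceil(fraction·N) voxels of the VOI."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    vals = np.sort(_voi_values(dose, voi))[::-1]
    n_hot = math.ceil(fraction * vals.size)
    return float(vals[n_hot - 1])


def mean_dose(dose: ScalarMap, voi: np.ndarray) -> float:
    """Arithmetic mean dose over the VOI voxels."""
    return float(_voi_values(dose, voi).mean())


@dataclass
class ConstraintResult:
    structure: str
    metric: str
    limit: float
    value: float | None            # None when the structure is missing
    passed: bool | None            # None = NA

    def as_dict(self) -> dict:
        return {
            "structure": self.structure, "metric": self.metric,
            "limit_Gy": self.limit,
            "value_Gy": None if self.value is None else round(self.value, 4),
            "passed": self.passed,
        }


def check_constraints(dose: ScalarMap, structures: StructureSet,
                      constraints: list[DoseConstraint] | None = None,
                      fx: FractionationParams = FractionationParams(),
                      n_fractions: int = 35) -> list[ConstraintResult]:
    """Evaluate OAR constraints on the EQD2-converted dose map.

    Missing structures degrade to NA results. Parotid-rule constraints pass
    collectively if either gland's mean is under its single-gland limit or
    the combined (pooled-voxel) mean is under the combined limit.
    """
    constraints = default_constraints() if constraints is None else constraints
    dose_eqd2 = eqd2(dose, n_fractions, fx.ab_oar)
    results: list[ConstraintResult] = []
    parotid_items: list[tuple[DoseConstraint, float]] = []
    for c in constraints:
        if c.structure not in structures or not structures[c.structure].any():
            results.append(ConstraintResult(c.structure, c.metric, c.limit, None, None))
            continue
        voi = structures[c.structure]
        value = (dose_at_volume(dose_eqd2, voi, 0.02) if c.metric == "D2%"
                 else mean_dose(dose_eqd2, voi))
        if c.combination_rule == "parotid":
            parotid_items.append((c, value))
            results.append(ConstraintResult(c.structure, c.metric, c.limit, value, None))
        else:
            results.append(ConstraintResult(c.structure, c.metric, c.limit,
                                            value, value < c.limit))
    if parotid_items:
        single_ok = any(v < c.limit for c, v in parotid_items)
        masks = [structures[c.structure] for c, _ in parotid_items]
        pooled = np.concatenate([dose_eqd2.values[np.asarray(m).astype(bool)]
                                 for m in masks])
        combined_ok = float(pooled.mean()) < PAROTID_COMBINED_LIMIT
        verdict = single_ok or combined_ok
        for r in results:
            if any(r.structure == c.structure and r.metric == c.metric
                   for c, _ in parotid_items):
                r.passed = verdict
    return results


def conformity_homogeneity(dose: ScalarMap, voi: np.ndarray,
                           prescription: float) -> tuple[float, float]:
    """(Paddick CI, ICRU-style HI) of a dose map for one target and prescription.

    V_Rx is the set of voxels at or above the prescription anywhere on the
    grid; CI = 0 when it is empty. HI = (D2% − D98%)/D50% over the VOI.
    """
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    m = np.asarray(voi).astype(bool)
    vals = _voi_values(dose, m)
    v_rx = dose.values >= prescription
    n_rx = int(v_rx.sum())
    if n_rx == 0:
        ci = 0.0
    else:
        ci = float((m & v_rx).sum()) ** 2 / (float(m.sum()) * n_rx)
    d2 = dose_at_volume(dose, m, 0.02)
    d98 = dose_at_volume(dose, m, 0.98)
    d50 = dose_at_volume(dose, m, 0.50)
    hi = (d2 - d98) / d50 if d50 > 0 else float("nan")
    return ci, hi


def characterize_volumes(pO2: ScalarMap, fdg: ScalarMap, tv2: np.ndarray,
                         htv: np.ndarray) -> dict:
    """Biological-volume summary of the hypoxic and FDG-avid compartments.

    VOI50 is the TV2 region at or above 50% of the maximum normalized FDG
    signal within TV2. Reports HTV and VOI50 volumes (cm³), the hypoxic
    fraction |HTV|/|TV2| and the overlap fraction 100·|HTV∩VOI50|/|VOI50| (%).
    """
    grid = pO2.grid
    tv2 = np.asarray(tv2).astype(bool)
    htv = np.asarray(htv).astype(bool)
    if tv2.shape != grid.shape or htv.shape != grid.shape:
        raise GridMismatchError("masks do not conform to the pO2 grid")
    if not tv2.any():
        raise EmptyMaskError("TV2 is empty")
    fdg_tv2 = fdg.values[tv2]
    voi50 = tv2 & (fdg.values >= 0.5 * fdg_tv2.max())
    n_voi50 = int(voi50.sum())
    overlap = 100.0 * float((htv & voi50).sum()) / n_voi50 if n_voi50 else float("nan")
    return {
        "htv_cm3": mask_volume(htv, grid),
        "voi50_cm3": mask_volume(voi50, grid),
        "hypoxic_fraction": float(htv.sum()) / float(tv2.sum()),
        "overlap_fraction_pct": overlap,
    }
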