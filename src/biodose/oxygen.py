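"""FMISO uptake ↔ oxygen tension conversion and hypoxic-volume segmentation.

The forward model links oxygen partial pressure p (mmHg) to normalized FMISO
uptake through a saturating binding curve

    U(p) = a − b·p / (p + c),

which falls from U(0) = a under anoxia toward the asymptote a − b at full
oxygenation. Voxel uptake is first normalized to a well-oxygenated reference
region (deep neck muscle, assigned 30 mmHg) so that the muscle mean sits
exactly on the model curve; the inverse map

    p(U) = c·(a − U) / (b + U − a)

then yields a pO2 map, clamped to [0, pO2_cap]. The hypoxic target volume
(HTV) is the set of TV2 voxels with pO2 at or below the hypoxia threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyReferenceError
from .grid import ImageGrid, ScalarMap, masked_nonempty, require_same_grid


@dataclass(frozen=True)
class OxyConversionParams:
    """Parameters of the uptake↔pO2 conversion.

    a, b are dimensionless (normalized-uptake units), c in mmHg. pO2_ref is
    the oxygen tension assigned to the muscle reference; pO2_cap bounds the
    inverse map where it diverges (U → a − b); hypoxia_threshold defines the
    HTV (inclusive comparison).
    """

    a: float = 10.9
    b: float = 10.7
    c: float = 2.5
    pO2_ref: float = 30.0
    pO2_cap: float = 100.0
    hypoxia_threshold: float = 10.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("a, b, c must be positive")
        if not 0 <= self.hypoxia_threshold < self.pO2_ref:
            raise ValueError("hypoxia_threshold must lie in [0, pO2_ref)")


def uptake_model(pO2, params: OxyConversionParams = OxyConversionParams()):
    """Normalized FMISO uptake predicted at oxygen tension ``pO2`` (mmHg).

    Strictly decreasing; equals ``a`` at anoxia and tends to ``a − b``.
    Accepts a scalar or array; raises ValueError on negative pO2.
    """
    p = np.asarray(pO2, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("pO2 must be >= 0")
    out = params.a - params.b * p / (p + params.c)
    return float(out) if np.isscalar(pO2) else out


def uptake_to_po2(U, params: OxyConversionParams = OxyConversionParams()):
    """Invert the uptake model: pO2 = c·(a − U)/(b + U − a), clamped.

    U ≥ a maps to 0 mmHg (more-than-anoxic uptake cannot be exceeded);
    U at or below the asymptote a − b maps to pO2_cap, where the analytic
    inverse diverges. Accepts a scalar, array, or ScalarMap (returns the
    matching kind; maps come back with quantity ``pO2_mmHg``).
    """
    if isinstance(U, ScalarMap):
        return U.with_values(uptake_to_po2(U.values, params), "pO2_mmHg")
    u = np.atleast_1d(np.asarray(U, dtype=np.float64))
    denom = params.b + u - params.a
    with np.errstate(divide="ignore", invalid="ignore"):
        p = params.c * (params.a - u) / denom
    p = np.where(denom <= 0, params.pO2_cap, p)
    p = np.clip(p, 0.0, params.pO2_cap)
    return float(p[0]) if np.isscalar(U) or np.ndim(U) == 0 else p.reshape(np.shape(U))


def normalize_fmiso(uptake: ScalarMap, muscle: np.ndarray,
                    params: OxyConversionParams = OxyConversionParams()) -> ScalarMap:
    """Normalize an FMISO image to the muscle reference.

    U(i) = x(i) / mean_muscle · U_model(pO2_ref), so the muscle-mask mean of
    the output equals the model-predicted uptake at the reference oxygen
    tension and the result is invariant to any global positive rescaling of
    the input image.
    """
    m = masked_nonempty(muscle, "muscle reference region")
    if m.shape != uptake.grid.shape:
        from .errors import GridMismatchError
        raise GridMismatchError(
            f"muscle mask shape {m.shape} != image grid shape {uptake.grid.shape}")
    ref_mean = float(uptake.values[m].mean())
    if ref_mean <= 0:
        raise EmptyReferenceError(f"muscle reference mean is non-positive ({ref_mean})")
    scale = uptake_model(params.pO2_ref, params) / ref_mean
    return uptake.with_values(uptake.values * scale, "uptake")


def segment_htv(pO2: ScalarMap, tv2: np.ndarray,
                params: OxyConversionParams = OxyConversionParams()) -> np.ndarray:
    """Hypoxic target volume: TV2 voxels with pO2 ≤ hypoxia_threshold."""
    tv2 = np.asarray(tv2).astype(bool)
    if tv2.shape != pO2.grid.shape:
        from .errors import GridMismatchError
        raise GridMismatchError(
            f"TV2 shape {tv2.shape} != pO2 grid shape {pO2.grid.shape}")
    return tv2 & (pO2.values <= params.hypoxia_threshold)
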