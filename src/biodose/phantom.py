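"""Synthetic dual-tracer phantoms and a crude deliverable-dose emulator.

A phantom is a set of co-registered maps on one grid: nested spherical
targets (TV1 ⊃ TV2 ⊃ GTV) around a hypoxic core, a deep-muscle reference
slab, box organs at risk, a ground-truth oxygen-tension field (background
oxygenation falling quadratically to a core minimum), a ground-truth
clonogen-density field (baseline rising quadratically to a peak at the GTV
centre), and the two PET images obtained by pushing the truth fields through
the forward uptake models, blurring with an isotropic Gaussian PSF and
applying multiplicative Gaussian noise of fixed coefficient of variation.
With zero blur and noise the imaging chain inverts the truth fields exactly,
which anchors the pipeline's round-trip tests.

The plan emulator stands in for a treatment planning system: it paints the
TV1 base dose, overwrites each subtarget with its homogeneous prescription
and convolves with an isotropic Gaussian kernel to mimic the finite dose
gradients of a deliverable plan. It makes no attempt at OAR sparing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .density import CellDensityParams
from .errors import InvalidGeometryError, MissingStructureError
from .grid import ImageGrid, ScalarMap, StructureSet
from .oxygen import OxyConversionParams, uptake_model
from .prescription import SubtargetPrescription


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, truth-field and corruption parameters of a phantom.

    Radii are mm; the target spheres share the grid-centre. po2 values are
    mmHg, densities cells/cm³; noise_cv is the multiplicative-noise
    coefficient of variation and psf_sigma_mm the PET blur.
    """

    grid: ImageGrid = field(default_factory=lambda: ImageGrid((64, 64, 64)))
    r_tv1_mm: float = 30.0
    r_tv2_mm: float = 22.0
    r_gtv_mm: float = 14.0
    r_core_mm: float = 10.0
    core_plateau_frac: float = 0.3
    po2_background: float = 30.0
    po2_core_min: float = 2.0
    density_peak: float = 5e8
    noise_cv: float = 0.05
    psf_sigma_mm: float = 2.0

    def __post_init__(self):
        radii = (self.r_core_mm, self.r_gtv_mm, self.r_tv2_mm, self.r_tv1_mm)
        if any(r <= 0 for r in radii) or any(
                radii[i] >= radii[i + 1] for i in range(3)):
            raise InvalidGeometryError(
                f"radii must be strictly nested core<GTV<TV2<TV1, got {radii}")
        if not self.po2_core_min < self.po2_background:
            raise InvalidGeometryError("po2_core_min must be < po2_background")
        if self.noise_cv < 0 or self.psf_sigma_mm < 0:
            raise InvalidGeometryError("noise_cv and psf_sigma_mm must be >= 0")
        if not 0 <= self.core_plateau_frac < 1:
            raise InvalidGeometryError("core_plateau_frac must lie in [0, 1)")


def _radius_map(grid: ImageGrid) -> np.ndarray:
    """Distance (mm) of each voxel centre from the grid centre."""
    xs, ys, zs = grid.coordinate_arrays()
    cx, cy, cz = (0.5 * (ax[0] + ax[-1]) for ax in (xs, ys, zs))
    X, Y, Z = np.meshgrid(xs - cx, ys - cy, zs - cz, indexing="ij")
    return np.sqrt(X**2 + Y**2 + Z**2)


def _box(grid: ImageGrid, lo_mm, hi_mm) -> np.ndarray:
    xs, ys, zs = grid.coordinate_arrays()
    m = np.ones(grid.shape, dtype=bool)
    for a, ax in enumerate((xs, ys, zs)):
        sel = (ax >= lo_mm[a]) & (ax <= hi_mm[a])
        m &= sel.reshape([-1 if i == a else 1 for i in range(3)])
    return m


def _oar_boxes(grid: ImageGrid) -> dict[str, np.ndarray]:
    """Fixed muscle slab and OAR boxes, placed clear of TV1 on the default grid."""
    ext = [grid.origin[a] + grid.spacing[a] * (grid.shape[a] - 1) for a in range(3)]
    o = grid.origin
    w = [ext[a] - o[a] for a in range(3)]

    def frac_box(lo, hi):
        return _box(grid, [o[a] + lo[a] * w[a] for a in range(3)],
                    [o[a] + hi[a] * w[a] for a in range(3)])

    return {
        "muscle": frac_box((0.02, 0.30, 0.30), (0.12, 0.70, 0.70)),
        "spinal_cord": frac_box((0.88, 0.42, 0.05), (0.97, 0.58, 0.60)),
        "brainstem": frac_box((0.88, 0.42, 0.72), (0.97, 0.58, 0.95)),
        "mandible": frac_box((0.35, 0.02, 0.35), (0.65, 0.12, 0.65)),
        "parotid_left": frac_box((0.35, 0.35, 0.02), (0.65, 0.65, 0.10)),
        "parotid_right": frac_box((0.35, 0.35, 0.90), (0.65, 0.65, 0.98)),
    }


def _blur_and_noise(values: np.ndarray, spec: PhantomSpec,
                    rng: np.random.Generator) -> np.ndarray:
    out = values
    if spec.psf_sigma_mm > 0:
        sigma_vox = [spec.psf_sigma_mm / s for s in spec.grid.spacing]
        out = ndimage.gaussian_filter(out, sigma_vox)
    if spec.noise_cv > 0:
        out = out * (1.0 + spec.noise_cv * rng.standard_normal(out.shape))
    return np.maximum(out, 1e-9)


def generate_phantom(spec: PhantomSpec = PhantomSpec(), seed: int = 0,
                     oxy: OxyConversionParams = OxyConversionParams(),
                     cd: CellDensityParams = CellDensityParams()) -> dict:
    """Build one phantom; identical (spec, seed) pairs give identical output.

    Returns ``{"fmiso", "fdg", "structures", "truth_po2", "truth_density"}``.
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid
    r = _radius_map(grid)

    masks = {
        "TV1": r <= spec.r_tv1_mm,
        "TV2": r <= spec.r_tv2_mm,
        "GTV": r <= spec.r_gtv_mm,
    }
    masks.update(_oar_boxes(grid))
    for name in ("muscle", "spinal_cord", "brainstem", "mandible",
                 "parotid_left", "parotid_right"):
        if (masks[name] & masks["TV1"]).any():
            raise InvalidGeometryError(f"{name} overlaps TV1; enlarge the grid")
    structures = StructureSet(grid, masks)

    # truth pO2: background everywhere; inside the core a flat plateau at
    # po2_core_min (necrotic/chronically hypoxic centre) rising quadratically
    # back to the background at the core boundary
    po2 = np.full(grid.shape, spec.po2_background)
    in_core = r < spec.r_core_mm
    r_plateau = spec.core_plateau_frac * spec.r_core_mm
    ramp = np.clip((r[in_core] - r_plateau) / (spec.r_core_mm - r_plateau), 0.0, 1.0)
    po2[in_core] = spec.po2_core_min + (
        spec.po2_background - spec.po2_core_min) * ramp ** 2
    truth_po2 = ScalarMap(grid, po2, "pO2_mmHg")

    # truth density: baseline everywhere, quadratic peak at the GTV centre
    rho = np.full(grid.shape, cd.rho_base)
    in_gtv = r < spec.r_gtv_mm
    rho[in_gtv] = spec.density_peak - (
        spec.density_peak - cd.rho_base) * (r[in_gtv] / spec.r_gtv_mm) ** 2
    truth_density = ScalarMap(grid, rho, "density_per_cm3")

    # forward imaging: FMISO through the uptake model (muscle sits at the
    # background oxygenation, so normalization recovers the model curve),
    # FDG as the inverse of the linear density calibration (muscle = 1)
    fmiso_vals = uptake_model(po2, oxy)
    fdg_vals = cd.U_ref + (rho - cd.rho_base) / cd.slope
    fmiso = ScalarMap(grid, _blur_and_noise(fmiso_vals, spec, rng), "uptake")
    fdg = ScalarMap(grid, _blur_and_noise(fdg_vals, spec, rng), "uptake")

    return {
        "fmiso": fmiso,
        "fdg": fdg,
        "structures": structures,
        "truth_po2": truth_po2,
        "truth_density": truth_density,
    }


@dataclass(frozen=True)
class PlanEmulatorSpec:
    """Base TV1 dose (Gy total) and the Gaussian smoothing kernel (mm)."""

    base_dose_tv1: float = 50.0
    kernel_sigma_mm: float = 3.0

    def __post_init__(self):
        if self.kernel_sigma_mm < 0:
            raise InvalidGeometryError("kernel_sigma_mm must be >= 0")
        if self.base_dose_tv1 < 0:
            raise InvalidGeometryError("base_dose_tv1 must be >= 0")


def emulate_plan(prescriptions: list[SubtargetPrescription],
                 subtargets: dict[str, np.ndarray],
                 tv1: np.ndarray,
                 grid: ImageGrid,
                 spec: PlanEmulatorSpec = PlanEmulatorSpec()) -> ScalarMap:
    """Paint base dose in TV1 and homogeneous prescriptions in the subtargets,
    then blur with an isotropic Gaussian; sigma = 0 returns the painted map.
    """
    dose = np.zeros(grid.shape)
    dose[np.asarray(tv1).astype(bool)] = spec.base_dose_tv1
    for p in prescriptions:
        if p.name not in subtargets:
            raise MissingStructureError(f"prescription references unknown "
                                        f"structure '{p.name}'")
        dose[np.asarray(subtargets[p.name]).astype(bool)] = p.homogeneous_dose
    if spec.kernel_sigma_mm > 0:
        sigma_vox = [spec.kernel_sigma_mm / s for s in grid.spacing]
        dose = ndimage.gaussian_filter(dose, sigma_vox)
    return ScalarMap(grid, dose, "dose_Gy")
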