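# Methods

This note records the modelling choices behind `biodose`: the equations as
implemented, the parameters that matter, what the synthetic phantoms do and
do not emulate, and the numerical conventions.

## Imaging model and oxygen mapping

All maps live on one axis-aligned regular grid (`ImageGrid`: shape, spacing,
origin; voxel-centre convention; NIfTI affines must be diagonal). The
package assumes co-registration upstream and enforces grid equality whenever
maps interact; `resample_to_grid` (nearest/linear) is provided for bringing
inputs onto a common grid.

FMISO uptake is normalized to the mean over a deep-neck-muscle mask (the
arithmetic mean — the plain reading of a reference-region average) and
rescaled so the muscle mean equals the forward-model uptake at the assigned
reference oxygenation of 30 mmHg. The conversion

    U(p) = a − b·p/(p + c)          a = 10.9, b = 10.7, c = 2.5 mmHg
    p(U) = c·(a − U)/(b + U − a)

is a strict inverse pair on (0, 100) mmHg, and the normalization makes the
pipeline invariant to any global rescaling of the PET image. Two clamps make
the inverse total: U ≥ a maps to 0 mmHg, and U at or below the asymptote
a − b maps to the 100 mmHg cap, where the analytic expression diverges. The
cap keeps downstream oxygen-enhancement factors finite and matters only for
voxels far brighter-than-anoxic or darker-than-plateau, which in practice
are noise. The hypoxic target volume is HTV = {i ∈ TV2 : pO₂(i) ≤ 10 mmHg};
the threshold comparison is inclusive and configurable.

## Cell density

Muscle-normalized FDG uptake maps linearly onto clonogen density through
two anchors: baseline 10⁷ cells·cm⁻³ at uptake 1 and carrying capacity
10⁹ cells·cm⁻³ at uptake 30 (a cohort-level maximum treated as a fixed
constant). The slope is derived from the anchors unless explicitly
overridden, keeping the calibration self-consistent. Values are clamped to
[10⁷, 10⁹]: sub-baseline uptake does not extrapolate to near-zero densities,
which would make voxels cost-free in the prescription; super-capacity uptake
does not exceed the biological ceiling. Without an FDG scan, TV2 receives a
uniform 10⁷ cells·cm⁻³.

## Cell kill, TCP, EQD2

Survival over n equal fractions of total dose D (dose per fraction
d = D/n) is

    SF = exp(−n·[α·(f·d) + β·(f·d)²]),

with α = 0.35 Gy⁻¹, β = 0.035 Gy⁻² (α/β = 10 Gy) as defaults. These are
literature-typical HNSCC values, stated as an explicit assumption and fully
configurable — absolute TCP values depend on them, structural behaviour
(orderings, round trips) does not.

**Direction of the oxygen effect.** The enhancement ratio
OER(p) = OER_max(k + p)/(k + OER_max·p) equals OER_max = 3 at anoxia and
tends to 1 when well oxygenated. Two sign conventions for the
dose-modifying factor circulate in the literature; applying OER itself as
the dose multiplier inside SF would make anoxic voxels *more* sensitive,
inverting the biology. `biodose` multiplies dose by f = 1/OER, so an anoxic
voxel needs exactly OER_max-fold dose for equal kill (recovered as a
closed-form identity when β = 0). This is the only reading consistent with
escalating dose into hypoxic subvolumes, and it is asserted by tests.

TCP over a volume of interest is the Poisson probability that no clonogen
survives, TCP = exp(−Σᵢ ηᵢ·SFᵢ), ηᵢ = v·ρᵢ. Voxels with zero density
contribute a factor of 1; TCP is multiplicative over disjoint volumes. The
surviving-cell map ηᵢ·SFᵢ is exposed for visualising likely recurrence
sites. EQD2 = D·(d + α/β)/(2 + α/β) uses α/β = 10 Gy for targets and
3 Gy for organs at risk.

## Dose prescription

The voxelwise ideal dose assigns every VOI voxel an equal share of the
allowed expected-survivor budget −ln(TCP_target)/N (design TCP 0.95). This
equal-burden allocation is the unique one making every voxel's Poisson
factor identical, and it makes the round trip exact: re-evaluating TCP on
the returned map reproduces the design target to machine precision (an
acceptance-level test). Per voxel, x = f·d solves β·x² + α·x = −ln(s)/n in
closed form (positive quadratic root, verified against bisection to
1e-9 Gy). Voxels whose clonogen load is already below budget get 0 Gy with
a warning; a 120 Gy safety cap (configurable) bounds the anoxic limit.

Dose painting by contours collapses the ideal map per subtarget
(TV2-GTV, GTV-HTV, HTV — disjoint by volume algebra) to

    D_P = D̄·[1 − (γ/(2·TCP))·(σ_D/D̄)²],    γ = 4,

a dimensionless second-order correction that reduces to D̄ for a
homogeneous map and always prescribes below the mean otherwise. TCP here is
the design target (0.95), not a per-contour value; this and the grouping of
the correction term are interpretations, chosen because this is the only
dimensionally consistent form that vanishes at σ_D = 0. An absent or empty
HTV (non-hypoxic case) simply drops its row.

## Plan evaluation conventions

- D_x%: minimum dose among the hottest ⌈x%·N⌉ voxels — integer voxel
  counting, no DVH interpolation, so results are exactly reproducible.
- Constraints (EQD2, α/β = 3 Gy): cord/brainstem D2% < 45 Gy; mandible
  D2% < 70 Gy and mean < 54 Gy; parotid rule — mean < 20 Gy for at least
  one gland or < 25 Gy pooled over both. Missing structures report NA
  rather than failing.
- Conformity index is Paddick's |VOI ∩ V_Rx|²/(|VOI|·|V_Rx|) with V_Rx the
  grid-wide isodose at the prescription; homogeneity index is
  (D2% − D98%)/D50%. Both are labelled interpretations of the standard
  indices.
- VOI50 (FDG-avid volume) is the TV2 region at or above 50% of the
  TV2-maximum normalized FDG signal; the search region is configurable.

## Synthetic phantoms

The generator emulates the study inputs, not PET physics. On a 64³, 2 mm
grid it places nested spheres (TV1 30 / TV2 22 / GTV 14 mm radius), a
muscle slab and box OARs clear of TV1. Ground truth: pO₂ is 30 mmHg
everywhere except a 10 mm core holding a 2 mmHg plateau over the inner 30%
of its radius and rising quadratically back to background — a plateau
rather than a point minimum, since necrotic/chronically hypoxic cores are
regionally, not punctually, hypoxic, and a resolvable plateau keeps the
PSF-induced partial-volume bias of the recovered HTV volume small (≈1% at
the defaults, versus ~30% shrinkage/inflation for point-dip or half-radius
plateaus). Density rises quadratically from the 10⁷ baseline to a
5·10⁸ cells·cm⁻³ peak at the GTV centre (below the carrying capacity, as a
solid tumour's viable fraction should be). The PET images are the truth
fields pushed through the forward uptake models, blurred by a 2 mm Gaussian
PSF and corrupted by 5% multiplicative Gaussian noise — CV-parameterized
noise on post-reconstruction SUV-like images, not Poisson count noise,
because reconstruction is out of scope. With corruption off, the imaging
chain inverts the truth exactly, anchoring the round-trip tests. All
randomness flows through one seeded generator.

What passing phantom tests does **not** show: robustness to registration
error, partial-volume correction, non-Gaussian reconstruction artefacts,
patient-to-patient anatomy, or kinetic (multi-timepoint) hypoxia — real
images differ in all of these.

The plan emulator paints the 50 Gy base dose in TV1, overwrites each
subtarget with its homogeneous prescription, and convolves with a 3 mm
isotropic Gaussian to mimic deliverable gradients. It performs no
optimization and no OAR sparing (constraint checking on its output
demonstrates the reporting path only). A known, intended consequence: the
penumbra is centred on each contour, so the outermost TV2 voxels fall
toward the base dose (~5 Gy cold at the rim). Each such voxel contributes
~10⁻⁴ expected surviving clonogens regardless of tumour size, so for a
realistic ~45 cm³ TV2 the rim alone caps whole-TV2 TCP near 0.91 and the
cohort evaluates to ~0.82 rather than the 0.95 design value — the same
TV2-rim cold-spot failure mode that plan optimization exists to remove.
Claims about clinical deliverability are therefore outside what the
emulator can support.

## Problem sizes and numerics

Default simulations use 64³ grids (≈5,600 TV2 voxels) and 10-seed cohorts,
sizes at which every pipeline stage is exactly reproducible and the full
cohort runs in seconds. Ties at the hypoxia threshold are included in the
HTV (≤); subtarget painting order is rim → GTV ring → HTV so the innermost
prescription wins on overlap; masks read from NIfTI treat any nonzero voxel
as inside; structure nesting (GTV ⊆ TV2 ⊆ TV1) is validated with a warning
rather than an error because clinical contours disagree by voxels.

## Known limitations

No repopulation or reoxygenation kinetics, no interpatient radiosensitivity
sampling, no NTCP. α/β are assumptions, so absolute TCP/EQD2 values are
model-based estimates. The emulator is deliberately crude (above). DICOM
RT-STRUCT, deformable registration and SUV computation from raw counts are
out of scope; inputs are NIfTI volumes on a common grid.
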