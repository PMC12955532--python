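"""DVH metrics, OAR constraint checking, indices and biological volumes."""

import numpy as np
import pytest

from biodose import (FractionationParams, ImageGrid, ScalarMap, StructureSet,
                     characterize_volumes, check_constraints,
                     conformity_homogeneity, dose_at_volume, mean_dose)
from biodose.errors import EmptyMaskError


def _dose(grid, values):
    return ScalarMap(grid, np.asarray(values, float), "dose_Gy")


class TestDoseAtVolume:
    def test_hottest_two_of_hundred(self, small_grid):
        vals = np.zeros(small_grid.shape)
        voi = np.zeros(small_grid.shape, bool)
        voi.ravel()[:100] = True
        vals.ravel()[:100] = np.arange(1, 101)       # doses 1..100 Gy
        assert dose_at_volume(_dose(small_grid, vals), voi, 0.02) == 99.0

    def test_uniform_dose_any_fraction(self, small_grid):
        d = _dose(small_grid, np.full(small_grid.shape, 54.0))
        voi = np.ones(small_grid.shape, bool)
        for q in (0.02, 0.5, 1.0):
            assert dose_at_volume(d, voi, q) == 54.0

    def test_full_fraction_is_minimum(self, small_grid, rng):
        vals = rng.uniform(10, 80, small_grid.shape)
        voi = rng.random(small_grid.shape) > 0.5
        assert dose_at_volume(_dose(small_grid, vals), voi, 1.0) == vals[voi].min()

    def test_quantile_ordering(self, small_grid, rng):
        d = _dose(small_grid, rng.uniform(0, 90, small_grid.shape))
        voi = rng.random(small_grid.shape) > 0.3
        d2 = dose_at_volume(d, voi, 0.02)
        d50 = dose_at_volume(d, voi, 0.50)
        d98 = dose_at_volume(d, voi, 0.98)
        assert d2 >= d50 >= d98

    def test_mean_dose_examples(self, small_grid, rng):
        voi = np.zeros(small_grid.shape, bool)
        voi.ravel()[:2] = True
        vals = np.zeros(small_grid.shape)
        vals.ravel()[:2] = [0.0, 40.0]
        assert mean_dose(_dose(small_grid, vals), voi) == 20.0
        vals = rng.uniform(0, 90, small_grid.shape)
        voi = rng.random(small_grid.shape) > 0.4
        assert mean_dose(_dose(small_grid, vals), voi) == pytest.approx(
            vals[voi].sum() / voi.sum(), rel=1e-12)

    def test_empty_voi_rejected(self, small_grid):
        with pytest.raises(EmptyMaskError):
            mean_dose(_dose(small_grid, np.zeros(small_grid.shape)),
                      np.zeros(small_grid.shape, bool))


def _structset(grid, **masks):
    return StructureSet(grid, masks)


def _uniform_physical_dose(grid, eqd2_value, n=35, ab=3.0):
    """Total physical dose whose EQD2 at n fractions equals eqd2_value."""
    # D(D/n + ab) = E(2 + ab): solve the quadratic for D
    a = 1.0 / n
    disc = ab * ab + 4 * a * eqd2_value * (2 + ab)
    return (-ab + np.sqrt(disc)) / (2 * a)


class TestConstraints:
    def test_spinal_cord_pass(self, small_grid):
        voi = np.zeros(small_grid.shape, bool)
        voi[:2] = True
        d_phys = _uniform_physical_dose(small_grid, 40.0)
        ss = _structset(small_grid, spinal_cord=voi)
        res = check_constraints(_dose(small_grid, np.where(voi, d_phys, 0.0)), ss)
        cord = next(r for r in res if r.structure == "spinal_cord")
        assert cord.value == pytest.approx(40.0, abs=1e-6)
        assert cord.passed is True

    def test_parotid_single_gland_rule(self, small_grid):
        left = np.zeros(small_grid.shape, bool)
        right = np.zeros(small_grid.shape, bool)
        left[:3], right[5:8] = True, True
        vals = np.where(left, _uniform_physical_dose(small_grid, 18.0), 0.0)
        vals = np.where(right, _uniform_physical_dose(small_grid, 30.0), vals)
        ss = _structset(small_grid, parotid_left=left, parotid_right=right)
        res = check_constraints(_dose(small_grid, vals), ss)
        verdicts = {r.structure: r.passed for r in res
                    if r.structure.startswith("parotid")}
        assert verdicts == {"parotid_left": True, "parotid_right": True}

    def test_parotid_combined_rule(self, small_grid):
        left = np.zeros(small_grid.shape, bool)
        right = np.zeros(small_grid.shape, bool)
        left[:3], right[5:8] = True, True
        # both glands between 20 and 25 → single-gland fails, combined passes
        vals = np.where(left | right, _uniform_physical_dose(small_grid, 23.0), 0.0)
        ss = _structset(small_grid, parotid_left=left, parotid_right=right)
        res = check_constraints(_dose(small_grid, vals), ss)
        assert all(r.passed for r in res if r.structure.startswith("parotid"))
        # both above 25 → rule fails outright
        vals = np.where(left | right, _uniform_physical_dose(small_grid, 30.0), 0.0)
        res = check_constraints(_dose(small_grid, vals), ss)
        assert not any(r.passed for r in res if r.structure.startswith("parotid"))

    def test_mandible_mixed_verdict(self, small_grid):
        voi = np.zeros(small_grid.shape, bool)
        voi[4:7] = True
        d_phys = _uniform_physical_dose(small_grid, 60.0)
        ss = _structset(small_grid, mandible=voi)
        res = check_constraints(_dose(small_grid, np.where(voi, d_phys, 0.0)), ss)
        by_metric = {r.metric: r.passed for r in res if r.structure == "mandible"}
        assert by_metric == {"D2%": True, "Dmean": False}   # <70 but ≥54

    def test_missing_structures_degrade_to_na(self, small_grid):
        ss = _structset(small_grid)
        res = check_constraints(_dose(small_grid, np.zeros(small_grid.shape)), ss)
        assert all(r.passed is None and r.value is None for r in res)

    def test_verdict_flips_across_limit(self, small_grid):
        voi = np.zeros(small_grid.shape, bool)
        voi[:2] = True
        ss = _structset(small_grid, spinal_cord=voi)
        for e, expect in ((44.9, True), (45.1, False)):
            d = np.where(voi, _uniform_physical_dose(small_grid, e), 0.0)
            cord = next(r for r in check_constraints(_dose(small_grid, d), ss)
                        if r.structure == "spinal_cord")
            assert cord.passed is expect


class TestConformityHomogeneity:
    def test_perfect_plan(self, small_grid):
        voi = np.zeros(small_grid.shape, bool)
        voi[3:6] = True
        d = _dose(small_grid, np.where(voi, 60.0, 0.0))
        ci, hi = conformity_homogeneity(d, voi, 60.0)
        assert ci == pytest.approx(1.0)
        assert hi == pytest.approx(0.0)

    def test_double_sized_isodose_halves_ci(self, small_grid):
        voi = np.zeros(small_grid.shape, bool)
        voi.ravel()[:100] = True
        spill = np.zeros(small_grid.shape, bool)
        spill.ravel()[100:200] = True
        d = _dose(small_grid, np.where(voi | spill, 70.0, 0.0))
        ci, _ = conformity_homogeneity(d, voi, 70.0)
        assert ci == pytest.approx(0.5)

    def test_no_coverage_gives_zero_ci(self, small_grid):
        voi = np.ones(small_grid.shape, bool)
        d = _dose(small_grid, np.full(small_grid.shape, 10.0))
        ci, _ = conformity_homogeneity(d, voi, 99.0)
        assert ci == 0.0

    def test_invariant_ranges_under_permutation(self, small_grid, rng):
        vals = rng.uniform(40, 80, small_grid.shape)
        voi = rng.random(small_grid.shape) > 0.5
        ci, hi = conformity_homogeneity(_dose(small_grid, vals), voi, 60.0)
        assert 0.0 <= ci <= 1.0 and hi >= 0.0
        perm = rng.permutation(vals.ravel()).reshape(vals.shape)
        voi_perm = voi                                     # same VOI, permuted dose
        ci2, hi2 = conformity_homogeneity(_dose(small_grid, perm), voi_perm, 60.0)
        assert 0.0 <= ci2 <= 1.0 and hi2 >= 0.0


class TestCharacterizeVolumes:
    def _setup(self, grid, htv_idx, voi50_idx, n_tv2=200):
        tv2 = np.zeros(grid.shape, bool)
        tv2.ravel()[:n_tv2] = True
        htv = np.zeros(grid.shape, bool)
        htv.ravel()[htv_idx] = True
        fdg = np.full(grid.shape, 0.1)
        fdg.ravel()[voi50_idx] = 10.0                  # ≥ 50% of max
        po2 = ScalarMap(grid, np.full(grid.shape, 30.0), "pO2_mmHg")
        return po2, ScalarMap(grid, fdg), tv2, htv

    def test_identical_regions_full_overlap(self, small_grid):
        idx = np.arange(0, 40)
        po2, fdg, tv2, htv = self._setup(small_grid, idx, idx)
        out = characterize_volumes(po2, fdg, tv2, htv)
        assert out["overlap_fraction_pct"] == pytest.approx(100.0)

    def test_disjoint_regions_zero_overlap(self, small_grid):
        po2, fdg, tv2, htv = self._setup(small_grid, np.arange(0, 20),
                                         np.arange(100, 140))
        out = characterize_volumes(po2, fdg, tv2, htv)
        assert out["overlap_fraction_pct"] == 0.0

    def test_partial_overlap_count_ratio(self, small_grid):
        # |VOI50| = 40, |HTV ∩ VOI50| = 10 → 25%
        po2, fdg, tv2, htv = self._setup(small_grid, np.arange(30, 60),
                                         np.arange(0, 40))
        out = characterize_volumes(po2, fdg, tv2, htv)
        assert out["overlap_fraction_pct"] == pytest.approx(25.0)
        assert out["voi50_cm3"] == pytest.approx(40 * small_grid.voxel_volume)

    def test_hypoxic_fraction(self, small_grid):
        po2, fdg, tv2, htv = self._setup(small_grid, np.arange(0, 20),
                                         np.arange(0, 40))
        out = characterize_volumes(po2, fdg, tv2, htv)
        assert out["hypoxic_fraction"] == pytest.approx(20 / 200)
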