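"""Morphometry arithmetic: densities, TIs, stereology, reconciliation.

Expected values are hand computations or closed-form oracles frozen into the
tests (e.g. the stereology example evaluates the areal-to-volumetric formula
independently of the implementation)."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import thymoquant as tq
from thymoquant.detect import SpotSet
from thymoquant.segment import CompartmentMask


def _all_cortex_mask(side_um=100.0, psz=1.0):
    n = int(side_um / psz)
    return CompartmentMask(labels=np.ones((n, n), np.uint8), pixel_size_xy=psz)


def _spots(coords):
    coords = np.asarray(coords, float).reshape(-1, 2)
    return SpotSet(coords_um=coords, peak_intensities=np.ones(len(coords)))


class TestCompartmentDensity:
    def test_zero_spots_zero_density(self):
        de = tq.compartment_density(_spots([]), _all_cortex_mask(), "cortex")
        assert de.density_per_1e4um2 == 0.0

    def test_five_spots_in_1e4_um2_is_density_five(self):
        de = tq.compartment_density(
            _spots([(10, 10), (20, 80), (50, 50), (80, 20), (90, 90)]),
            _all_cortex_mask(100.0), "cortex")
        assert de.density_per_1e4um2 == pytest.approx(5.0)
        assert de.tec_count == 5 and de.area_um2 == pytest.approx(1e4)

    def test_density_identity_holds(self):
        de = tq.compartment_density(_spots([(5, 5)]), _all_cortex_mask(50.0),
                                    "cortex")
        assert de.density_per_1e4um2 == de.tec_count / de.area_um2 * 1e4

    def test_zero_area_compartment_raises(self):
        with pytest.raises(ValueError, match="zero area"):
            tq.compartment_density(_spots([]), _all_cortex_mask(), "medulla")

    def test_guard_zone_excludes_boundary_spots(self):
        mask = _all_cortex_mask(100.0)
        de = tq.compartment_density(_spots([(1.0, 50.0), (50.0, 50.0)]),
                                    mask, "cortex", guard_um=10.0)
        assert de.tec_count == 1
        assert de.area_um2 < 1e4


class TestRatiosAndTIs:
    def test_ctec_mtec_ratio_examples(self):
        c = tq.DensityEstimate("cortex", 0, 1.0, 13.0)
        m = tq.DensityEstimate("medulla", 0, 1.0, 23.0)
        assert tq.ctec_mtec_ratio(c, m, (0.84, 0.16)) == pytest.approx(
            (13 * 0.84) / (23 * 0.16))  # ~2.97
        c2 = tq.DensityEstimate("cortex", 0, 1.0, 1.0)
        m2 = tq.DensityEstimate("medulla", 0, 1.0, 5.0)
        assert tq.ctec_mtec_ratio(c2, m2, (0.5, 0.5)) == pytest.approx(0.2)
        assert tq.ctec_mtec_ratio(c, c, (0.5, 0.5)) == 1.0

    def test_ctec_mtec_ratio_zero_denominator_flagged_as_inf(self):
        c = tq.DensityEstimate("cortex", 0, 1.0, 1.0)
        z = tq.DensityEstimate("medulla", 0, 1.0, 0.0)
        assert tq.ctec_mtec_ratio(c, z, (0.5, 0.5)) == float("inf")

    def test_ti_from_counts(self):
        assert tq.thymopoietic_index(100, 100).ti == 1.0
        assert tq.thymopoietic_index(6100, 100).ti == 61.0

    def test_ti_from_tec_fraction_inverse_rule(self):
        # a 0.1% TEC fraction is a TI of exactly 1,000
        assert tq.ti_from_tec_fraction(0.001).ti == 1000.0
        assert tq.ti_from_tec_fraction(0.001, exclusive=True).ti == 999.0

    def test_ti_zero_tecs_raises(self):
        with pytest.raises(ValueError):
            tq.thymopoietic_index(10, 0)

    def test_whole_organ_ti_weighted_mean(self):
        c = tq.thymopoietic_index(100, 1, scope="cortex")
        m = tq.thymopoietic_index(20, 1, scope="medulla")
        assert tq.whole_organ_ti(c, m, (0.5, 0.5)).ti == pytest.approx(60.0)
        assert tq.whole_organ_ti(c, m, (1.0, 0.0)).ti == 100.0
        assert tq.whole_organ_ti(c, c, (0.3, 0.7)).ti == 100.0

    def test_whole_organ_ti_degenerate_weights(self):
        c = tq.thymopoietic_index(10, 1)
        with pytest.raises(ValueError):
            tq.whole_organ_ti(c, c, (0.0, 0.0))

    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.integers(min_value=1, max_value=10 ** 6),
           st.integers(min_value=1, max_value=10 ** 6))
    def test_ti_scale_invariance(self, k, thy, tec):
        """Multiplying every count by k leaves the TI unchanged."""
        a = tq.thymopoietic_index(thy, tec).ti
        b = tq.thymopoietic_index(thy * k, tec * k).ti
        assert b == pytest.approx(a, rel=1e-9)


class TestStereology:
    def test_zero_densities_zero_total(self):
        scn = tq.make_scenario("P10")
        z = tq.DensityEstimate("cortex", 0, 1.0, 0.0)
        z2 = tq.DensityEstimate("medulla", 0, 1.0, 0.0)
        res = tq.extrapolate_total_tecs(z, z2, (0.5, 0.5), scn)
        assert res.total_tec_estimate == 0.0

    def test_worked_example_against_hand_formula(self):
        """cortex 0.9 and medulla 5 per 10^4 um^2, fractions 0.5/0.5,
        8 um sections, 6 um nuclei, 55.5 ul organ."""
        scn = tq.make_scenario("custom", cortical_tec_density=0.9,
                               medullary_tec_density=5.0,
                               cortex_area_fraction=0.5,
                               thymocyte_density_cortex=0.0,
                               thymocyte_density_medulla=0.0,
                               organ_volume=55.5, section_thickness=8.0,
                               mean_nuclear_diameter=6.0)
        c = tq.DensityEstimate("cortex", 0, 1.0, 0.9)
        m = tq.DensityEstimate("medulla", 0, 1.0, 5.0)
        res = tq.extrapolate_total_tecs(c, m, (0.5, 0.5), scn)
        # independent evaluation: (d/1e4)/(8+6) * 0.5 * 55.5e9, per compartment
        expected = ((0.9e-4 / 14.0) + (5e-4 / 14.0)) * 0.5 * 55.5e9
        assert expected == pytest.approx(1.1695e6, rel=1e-3)  # oracle value
        assert res.total_tec_estimate == pytest.approx(expected, rel=1e-12)
        assert res.total_tec_estimate == pytest.approx(
            res.cortical_total + res.medullary_total)

    def test_total_linear_in_organ_volume(self):
        scn = tq.make_scenario("P10")
        c = tq.DensityEstimate("cortex", 0, 1.0, 0.9)
        m = tq.DensityEstimate("medulla", 0, 1.0, 5.0)
        a = tq.extrapolate_total_tecs(c, m, (0.85, 0.15), scn)
        b = tq.extrapolate_total_tecs(
            c, m, (0.85, 0.15), scn.replace(organ_volume=2 * 55.5))
        assert b.total_tec_estimate == pytest.approx(
            2 * a.total_tec_estimate, rel=1e-12)

    def test_no_correction_mode_uses_bare_thickness(self):
        scn = tq.make_scenario("P10")
        c = tq.DensityEstimate("cortex", 0, 1.0, 1.0)
        m = tq.DensityEstimate("medulla", 0, 1.0, 1.0)
        plain = tq.extrapolate_total_tecs(c, m, (0.5, 0.5), scn,
                                          correction="none")
        corrected = tq.extrapolate_total_tecs(c, m, (0.5, 0.5), scn)
        assert plain.effective_thickness_um == 8.0
        assert corrected.effective_thickness_um == 14.0
        assert plain.total_tec_estimate == pytest.approx(
            corrected.total_tec_estimate * 14.0 / 8.0)

    def test_per_compartment_nuclear_diameter_override(self):
        scn = tq.make_scenario("P10")
        c = tq.DensityEstimate("cortex", 0, 1.0, 1.0)
        m = tq.DensityEstimate("medulla", 0, 1.0, 1.0)
        res = tq.extrapolate_total_tecs(c, m, (0.5, 0.5), scn,
                                        nuclear_diameter_medulla=10.0)
        assert res.medullary_total == pytest.approx(
            1e-4 / 18.0 * 0.5 * 55.5e9)


class TestReconcile:
    def test_p10_correction_factor(self):
        rec = tq.reconcile(61.0, 810.0, 1.12e5)
        assert rec.correction_factor == pytest.approx(810.0 / 61.0)
        assert round(rec.correction_factor) == 13
        assert rec.summary()["correction_factor"] == 13.0

    def test_corrected_total_identity(self):
        rec = tq.reconcile(1.0, 13.0, 1.12e5)
        assert rec.corrected_total == pytest.approx(1.456e6)

    def test_equal_tis_mean_full_recovery(self):
        rec = tq.reconcile(50.0, 50.0, 1000.0)
        assert rec.correction_factor == 1.0
        assert rec.recovery_rate == 1.0
        assert rec.recovery_rate_in_range

    def test_factor_times_recovery_is_one_when_ti_derived(self):
        rec = tq.reconcile(61.0, 810.0, 1.12e5)
        assert rec.correction_factor * rec.recovery_rate == pytest.approx(
            1.0, rel=1e-12)
        assert rec.assumptions  # TI-derived recovery records its assumption

    def test_measured_insitu_count_overrides_ti_recovery(self):
        rec = tq.reconcile(61.0, 810.0, 1.12e5, insitu_tec_count=1.5e6)
        assert rec.recovery_rate == pytest.approx(1.12e5 / 1.5e6)
        assert not rec.assumptions

    def test_nonpositive_ti_rejected(self):
        with pytest.raises(ValueError):
            tq.reconcile(0.0, 810.0, 1.0)


class TestFoldChange:
    def test_histology_fold_p0_to_p10(self):
        assert tq.fold_change(61.0, 23.0) == pytest.approx(2.652, abs=5e-3)

    def test_flow_fold_p0_to_p10(self):
        assert tq.fold_change(810.0, 216.0) == pytest.approx(3.75)

    def test_self_fold_is_one(self):
        assert tq.fold_change(7.3, 7.3) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            tq.fold_change(1.0, 0.0)
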