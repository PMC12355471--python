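"""Inference tests: the arithmetic that turns fitted parameters into
diffusion coefficients, sizes, brightness ratios, oligomeric states,
concentrations, and before/after electrophoresis verdicts."""

import math

import numpy as np
import pytest

from nanofcs import (
    ConfocalCalibration,
    PhysicalConditions,
    build_report,
    comparison_table,
    concentration,
    diffusion_coefficient,
    fixture_value,
    hydrodynamic_size,
    integrity_check,
    lipid_count_estimate,
    molecular_brightness,
    oligomeric_state,
    report_from_measurements,
)


CAL_330NM = ConfocalCalibration(beam_radius_xy=0.3265, structure_parameter=5.0)


class TestDiffusionCoefficient:
    def test_glpf_pair_is_consistent(self):
        # the (817 us, 32.6 um^2/s) pair implies w_xy ~ 326.5 nm
        assert diffusion_coefficient(817e-6, CAL_330NM) == pytest.approx(32.6, rel=5e-3)

    def test_doubling_residence_time_halves_d(self):
        d1 = diffusion_coefficient(400e-6, CAL_330NM)
        d2 = diffusion_coefficient(800e-6, CAL_330NM)
        assert d2 == pytest.approx(d1 / 2, rel=1e-12)

    def test_navms_pair_needs_slightly_different_calibration(self):
        # per-session calibration: 726 us -> 35.3 um^2/s requires w ~ 320 nm
        w = math.sqrt(4 * 35.3 * 726e-6)
        assert w == pytest.approx(0.320, abs=2e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            diffusion_coefficient(0.0, CAL_330NM)


class TestHydrodynamicSize:
    def test_glpf_tetramer_diameter_is_about_15_nm(self):
        _, diameter = hydrodynamic_size(32.6, PhysicalConditions(), "stokes_einstein")
        assert diameter == pytest.approx(15.0, abs=0.2)

    def test_as_printed_convention_omits_pi(self):
        r_se, _ = hydrodynamic_size(32.6, PhysicalConditions(), "stokes_einstein")
        r_ap, _ = hydrodynamic_size(32.6, PhysicalConditions(), "as_printed")
        assert r_ap == pytest.approx(r_se * math.pi / 2, rel=1e-12)
        assert r_ap == pytest.approx(11.8, abs=0.1)

    def test_size_vanishes_for_fast_diffusion(self):
        r, d = hydrodynamic_size(1e9, PhysicalConditions())
        assert r < 1e-6 and d == 2 * r

    def test_size_is_monotone_increasing_in_residence_time(self):
        taus = np.linspace(100e-6, 2000e-6, 20)
        diameters = [
            hydrodynamic_size(diffusion_coefficient(t, CAL_330NM))[1] for t in taus
        ]
        assert np.all(np.diff(diameters) > 0)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            hydrodynamic_size(30.0, PhysicalConditions(), "wrong")


class TestBrightnessAndState:
    def test_brightness_is_rate_over_occupancy(self):
        assert molecular_brightness(100.0, 4.0) == pytest.approx(25.0)

    def test_reported_tetramer_ratios(self):
        # 23.4 kHz vs the 7.5 kHz dye ruler: 3.12-fold, state 3, unflagged
        call = oligomeric_state(23.4)
        assert (call.state, call.ambiguous) == (3, False)
        assert call.ratio == pytest.approx(3.12, abs=5e-3)
        # 33 kHz: 4.4-fold, state 4, unflagged at the 25% threshold
        call = oligomeric_state(33.0)
        assert (call.state, call.ambiguous) == (4, False)
        assert call.ratio == pytest.approx(4.4, abs=1e-6)

    def test_ruler_self_comparison_is_monomer(self):
        call = oligomeric_state(7.5, 7.5)
        assert call.state == 1 and call.ratio == 1.0 and not call.ambiguous

    @pytest.mark.parametrize("k", range(1, 13))
    def test_exact_multiples_of_ruler_map_to_k(self, k):
        call = oligomeric_state(k * 7.5, 7.5)
        assert call.state == k and not call.ambiguous

    def test_large_deviation_is_flagged(self):
        call = oligomeric_state(1.4 * 7.5, 7.5)  # ratio 1.4 -> state 1, 40% off
        assert call.state == 1 and call.ambiguous

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            oligomeric_state(-1.0)
        with pytest.raises(ValueError):
            molecular_brightness(100.0, 0.0)


class TestConcentration:
    def test_single_particle_in_one_femtoliter(self):
        cal = ConfocalCalibration(0.33, 5.0)  # V_eff ~ 1.0005 fL
        assert concentration(1.0, cal) == pytest.approx(1.66, abs=0.01)

    def test_linear_in_occupancy(self):
        cal = ConfocalCalibration(0.33, 5.0)
        assert concentration(2.0, cal) == pytest.approx(2 * concentration(1.0, cal))


class TestIntegrity:
    def _reports(self, protein, gel_mode):
        reports = {}
        for stage in ("before", "after"):
            b, b_sd = fixture_value(protein, gel_mode, stage, "brightness")
            t, t_sd = fixture_value(protein, gel_mode, stage, "residence_time")
            reports[stage] = report_from_measurements(
                protein, gel_mode, stage,
                brightness=b, brightness_sd=b_sd,
                residence_time=t * 1e-6, residence_time_sd=t_sd * 1e-6,
            )
        return reports

    def test_coomassie_gel_preserves_size_but_quenches_brightness(self):
        reports = self._reports("GlpF", "BNE")
        verdict = integrity_check(reports["before"], reports["after"])
        assert verdict.residence_time_compatible
        assert not verdict.brightness_compatible
        assert verdict.quenching_flag

    def test_clear_native_gel_preserves_both(self):
        reports = self._reports("HpUreI", "CNE")
        verdict = integrity_check(reports["before"], reports["after"])
        assert verdict.residence_time_compatible
        assert verdict.brightness_compatible
        assert not verdict.quenching_flag

    def test_identical_reports_are_fully_compatible(self):
        rep = report_from_measurements(
            "X", "CNE", "before", brightness=30.0, brightness_sd=1.0,
            residence_time=800e-6, residence_time_sd=50e-6, concentration=2.0,
        )
        after = report_from_measurements(
            "X", "CNE", "after", brightness=30.0, brightness_sd=1.0,
            residence_time=800e-6, residence_time_sd=50e-6, concentration=2.0,
        )
        verdict = integrity_check(rep, after)
        assert verdict.residence_time_compatible and verdict.brightness_compatible
        assert verdict.concentration_ratio == pytest.approx(1.0)
        assert not verdict.quenching_flag and not verdict.low_confidence

    def test_missing_sd_degrades_to_low_confidence_point_comparison(self):
        before = report_from_measurements(
            "X", "CNE", "before", brightness=30.0, residence_time=800e-6
        )
        after = report_from_measurements(
            "X", "CNE", "after", brightness=30.5, residence_time=820e-6
        )
        verdict = integrity_check(before, after)
        assert verdict.low_confidence
        assert verdict.residence_time_compatible and verdict.brightness_compatible


class TestLipidCount:
    def test_annulus_formula_hand_value(self):
        expected = 2 * math.pi / 4 * (15**2 - 7.9**2) / 0.7
        assert lipid_count_estimate(15.0, 7.9) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(364.8, abs=0.1)

    def test_protein_filling_disc_has_no_lipids(self):
        assert lipid_count_estimate(10.0, 10.0) == 0.0

    def test_tetramer_to_monomer_ratio_is_order_ten(self):
        ratio = lipid_count_estimate(15.0, 7.9) / lipid_count_estimate(6.0, 4.0)
        assert 5 < ratio < 12  # ~8-fold, same order as the reported ~10x

    def test_oversized_protein_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            lipid_count_estimate(5.0, 6.0)


class TestReportBuilding:
    def test_empty_entry_list_gives_empty_table(self):
        assert build_report([]).empty

    def test_fixture_rows_pass_through_and_derive(self):
        from nanofcs import make_fixtures

        summary = make_fixtures()["summary"]
        entries = []
        for (protein, gel, stage), grp in summary.groupby(
            ["protein", "gel_mode", "stage"], sort=False
        ):
            vals = {row.quantity: (row.value, row.sd) for row in grp.itertuples()}
            entries.append(
                report_from_measurements(
                    protein, gel, stage,
                    brightness=vals["brightness"][0],
                    brightness_sd=vals["brightness"][1],
                    residence_time=vals["residence_time"][0] * 1e-6,
                    residence_time_sd=vals["residence_time"][1] * 1e-6,
                    diffusion=vals["diffusion_coefficient"][0],
                    diffusion_sd=vals["diffusion_coefficient"][1],
                )
            )
        table = build_report(entries)
        assert len(table) == 10
        glpf = table[(table.protein == "GlpF") & (table.stage == "before")].iloc[0]
        assert glpf.brightness_khz == 33.0  # identity pass-through
        assert glpf.diameter_nm == pytest.approx(15.0, abs=0.2)  # derived
        assert glpf.oligomeric_state == 4
        after = table[(table.protein == "GlpF") & (table.stage == "after")].iloc[0]
        assert after.size_preserved and not after.brightness_preserved
        assert after.quenching_flag

    def test_comparison_table_pairs_stages(self):
        before = report_from_measurements(
            "X", "CNE", "before", brightness=30.0, brightness_sd=1.0,
            residence_time=800e-6, residence_time_sd=40e-6, diffusion=33.0,
        )
        after = report_from_measurements(
            "X", "CNE", "after", brightness=29.0, brightness_sd=1.0,
            residence_time=810e-6, residence_time_sd=40e-6, diffusion=32.0,
        )
        table = comparison_table([before, after])
        assert len(table) == 1
        row = table.iloc[0]
        assert row.brightness_khz_before == 30.0
        assert row.brightness_khz_after == 29.0
        assert bool(row.size_preserved) and bool(row.brightness_preserved)
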