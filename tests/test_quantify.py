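"""Isotope-dilution arithmetic, A/B deconvolution, shared-standard
splitting, standard additions and the report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eadsa.quantify import (
    CalibrationError,
    QuantError,
    QuantModel,
    deconvolve_AB,
    free_total_report,
    percent_free,
    quant_single_point,
    split_shared_standard,
    standard_addition_fit,
)


class TestSinglePoint:
    def test_ratio_times_amount_over_volume(self):
        model = QuantModel(pa_unlabeled=200.0, pa_labeled=100.0)
        assert quant_single_point(model, 4.0, 0.1) == pytest.approx(80.0)

    def test_zero_analyte_signal_gives_zero(self):
        model = QuantModel(pa_unlabeled=0.0, pa_labeled=100.0)
        assert quant_single_point(model, 4.0, 0.1) == 0.0

    def test_missing_standard_signal_rejected(self):
        with pytest.raises(QuantError, match="internal standard"):
            quant_single_point(QuantModel(10.0, 0.0), 4.0, 0.1)

    @given(st.floats(1e-3, 1e6))
    def test_linearity_in_analyte_area(self, pa):
        """Doubling the unlabelled area exactly doubles the concentration."""
        c1 = quant_single_point(QuantModel(pa, 50.0), 2.0, 0.1)
        c2 = quant_single_point(QuantModel(2 * pa, 50.0), 2.0, 0.1)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_response_factor_scales_inversely(self):
        base = quant_single_point(QuantModel(100.0, 100.0), 4.0, 0.1)
        adj = quant_single_point(QuantModel(100.0, 100.0, rf_ratio=2.0), 4.0, 0.1)
        assert adj == pytest.approx(base / 2)


class TestDeconvolveAB:
    def test_hydroxy_is_A_minus_B(self, registry):
        h, o, basis, flags = deconvolve_AB(10.0, 4.0, registry.lookup("7a-HC"))
        assert (h, o, basis) == (6.0, 4.0, "A_minus_B")
        assert not flags

    def test_equal_fractions_leave_no_hydroxy(self, registry):
        h, o, basis, _ = deconvolve_AB(4.0, 4.0, registry.lookup("7a-HC"))
        assert (h, o) == (0.0, 4.0)

    def test_negative_difference_clipped_and_flagged(self, registry):
        h, o, basis, flags = deconvolve_AB(3.0, 4.0, registry.lookup("7a-HC"))
        assert h == 0.0 and o == 4.0
        assert "clipped_negative" in flags

    def test_side_chain_hydroxy_uses_fraction_A_alone(self, registry):
        h, o, basis, _ = deconvolve_AB(5.0, None, registry.lookup("24S-HC"))
        assert basis == "A_only" and h == 5.0

    def test_7_oxo_uses_fraction_B_alone(self, registry):
        h, o, basis, _ = deconvolve_AB(None, 3.0, registry.lookup("7-OC"))
        assert basis == "fraction_B" and o == 3.0

    def test_missing_required_fraction_rejected(self, registry):
        with pytest.raises(QuantError):
            deconvolve_AB(5.0, None, registry.lookup("7a-HC"))

    def test_conservation_against_brute_force(self, registry):
        """hydroxy + oxo == max(A, B) whenever A >= B."""
        sp = registry.lookup("7a-HC")
        for a in range(4):
            for b in range(4):
                h, o, _, _ = deconvolve_AB(float(a), float(b), sp)
                assert h == max(a - b, 0)
                assert o == b
                if a >= b:
                    assert h + o == max(a, b)


class TestSharedStandardSplit:
    def test_epimer_mixture_partition(self):
        s, r = split_shared_standard(80.0, [35.44 / 80.0, 44.56 / 80.0])
        assert s == pytest.approx(35.44)
        assert s + r == pytest.approx(80.0)

    def test_identity_fraction(self):
        assert split_shared_standard(80.0, [1.0]) == [80.0]

    def test_unnormalised_fractions_rejected(self):
        with pytest.raises(QuantError):
            split_shared_standard(80.0, [0.3, 0.3])

    @given(st.floats(1.0, 1e4), st.floats(0.01, 0.99))
    def test_components_sum_to_certified_total(self, total, f):
        parts = split_shared_standard(total, [f, 1 - f])
        assert sum(parts) == pytest.approx(total, rel=1e-9)


class TestStandardAdditionFit:
    def test_exact_line(self):
        slope, intercept, endo, r2 = standard_addition_fit(
            [0, 5, 10, 15, 20], [1.0, 1.5, 2.0, 2.5, 3.0]
        )
        assert slope == pytest.approx(0.1)
        assert intercept == pytest.approx(1.0)
        assert endo == pytest.approx(10.0)
        assert r2 == pytest.approx(1.0)

    def test_flat_ratios_fail_calibration(self):
        with pytest.raises(CalibrationError):
            standard_addition_fit([0, 5, 10, 15, 20], [2.0] * 5)

    def test_too_few_levels_rejected(self):
        with pytest.raises(CalibrationError):
            standard_addition_fit([0, 5], [1.0, 1.5])


class TestPercentFree:
    def test_quarter_free(self):
        assert percent_free(0.4, 1.6) == pytest.approx(25.0)

    def test_all_free(self):
        assert percent_free(2.0, 2.0) == pytest.approx(100.0)

    def test_over_100_permitted(self):
        assert percent_free(22.0, 20.0) == pytest.approx(110.0)

    def test_zero_total_rejected(self):
        with pytest.raises(QuantError):
            percent_free(1.0, 0.0)


class TestReportAssembly:
    def _report_row(self, analyte, conc, tier="absolute", basis="A_only"):
        return {"analyte": analyte, "tier": tier, "basis": basis,
                "conc_ng_per_ml": conc, "conc_A": conc, "conc_B": None,
                "surrogate": "s", "flags": ""}

    def test_free_total_merge_and_over100_flag(self):
        free = pd.DataFrame([self._report_row("a", 0.4),
                             self._report_row("b", 22.0)])
        total = pd.DataFrame([self._report_row("a", 1.6),
                              self._report_row("b", 20.0)])
        out = free_total_report(free, total).set_index("analyte")
        assert out.loc["a", "pct_free"] == pytest.approx(25.0)
        assert out.loc["b", "pct_free"] == pytest.approx(110.0)
        assert "free_exceeds_total" in out.loc["b", "flags"]
        assert "free_exceeds_total" not in out.loc["a", "flags"]


class TestQuantifyRunIntegration:
    def test_identified_only_species_have_blank_concentration(self, srm_free_report):
        row = srm_free_report.loc["22S-HCO"]
        assert row["tier"] == "identified_only"
        assert pd.isna(row["conc_ng_per_ml"])

    def test_tier_and_basis_bookkeeping(self, srm_free_report):
        assert srm_free_report.loc["7-OC", "basis"] == "fraction_B"
        assert srm_free_report.loc["7a-HC", "basis"] == "A_minus_B"
        assert srm_free_report.loc["24S-HC", "basis"] == "A_only"
        assert srm_free_report.loc["diHC-unk1", "tier"] == "approximate"

    def test_autoxidation_prone_species_flagged(self, srm_free_report):
        for sid in ("7a-HC", "7b-HC", "7-OC", "5a6b-diHC"):
            assert "autoxidation_prone" in srm_free_report.loc[sid, "flags"]

    def test_undetected_analyte_reports_zero(self, srm_free_report, srm_free_run):
        assert srm_free_run.ground_truth.true_conc("22R-HC") == 0.0
        assert srm_free_report.loc["22R-HC", "conc_ng_per_ml"] == 0.0

    def test_epimer_pair_recovered_through_shared_standard(
            self, srm_free_report, srm_free_run):
        gt = srm_free_run.ground_truth
        for sid in ("24S-HC", "24R-HC"):
            got = float(srm_free_report.loc[sid, "conc_ng_per_ml"])
            assert got == pytest.approx(gt.true_conc(sid), rel=0.01)

    def test_mrm_rescue_used_for_co_eluting_epimer(self, srm_free_report):
        assert "mrm_quantified" in srm_free_report.loc["24R-HC", "flags"]

    def test_m1_correction_applied_to_26hc_standard(self, srm_free_report):
        assert "m1_interference_corrected" in srm_free_report.loc["26R-HC", "flags"]

    def test_degradation_flag_only_in_hydrolysed_semi_tier(self, registry):
        from eadsa import quantify_simulated_run, scenario_preset, simulate_run
        run = simulate_run(scenario_preset("SRM1950_like"), 0.05,
                           hydrolysed=True, seed=4, registry=registry)
        rep = quantify_simulated_run(run, registry).set_index("analyte")
        assert "degradation_uncorrected" in rep.loc["3b-HCA", "flags"]
        # absolute-tier species with an exact surrogate are corrected
        assert "degradation_uncorrected" not in rep.loc["7a-HC", "flags"]
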