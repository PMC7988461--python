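"""Synthetic-run generator: workup arithmetic, signal conservation,
isotopologue envelopes, determinism and scenario presets."""

import numpy as np
import pytest
from scipy import stats

from eadsa import (
    InstrumentModel,
    TrueSampleState,
    derivative_ion,
    extract_ric,
    scenario_preset,
    simulate_chromatogram,
    simulate_run,
    simulate_workup,
)
from eadsa.runio import peak_table, read_run, write_run


class TestWorkup:
    def test_mix_aliquot_amounts_land_in_ground_truth(self, registry):
        state = TrueSampleState("plasma", 0.1, {})
        gt = simulate_workup(state, 0.05, False, registry=registry)
        total_24 = (gt.nominal_standard_ng["[2H7]24S-HC"]
                    + gt.nominal_standard_ng["[2H7]24R-HC"])
        assert total_24 == pytest.approx(4.0)

    def test_free_pool_only_without_hydrolysis(self, registry):
        state = TrueSampleState("plasma", 0.1, {"24S-HC": 10.0}, {"24S-HC": 30.0})
        gt = simulate_workup(state, 0.05, False, registry=registry)
        assert gt.fraction_amounts_ng["24S-HC"]["A"] == pytest.approx(1.0)
        assert gt.fraction_amounts_ng["24S-HC"]["B"] == 0.0

    def test_hydrolysis_releases_esterified_pool(self, registry):
        state = TrueSampleState("plasma", 0.1, {"24S-HC": 10.0}, {"24S-HC": 30.0})
        gt = simulate_workup(state, 0.05, True, registry=registry)
        assert gt.fraction_amounts_ng["24S-HC"]["A"] == pytest.approx(4.0)

    def test_base_loss_hits_analyte_and_exact_surrogate_equally(self, registry):
        state = TrueSampleState("plasma", 0.1, {"7a-HC": 20.0})
        gt = simulate_workup(state, 0.05, True, registry=registry,
                             base_loss_fraction=0.2)
        assert gt.fraction_amounts_ng["7a-HC"]["A"] == pytest.approx(2.0 * 0.8)
        assert gt.fraction_amounts_ng["[2H7]7a-HC"]["A"] == pytest.approx(3.0 * 0.8)
        # a species without the labile 7-hydroxy group is untouched
        assert gt.fraction_amounts_ng["[2H7]24S-HC"]["A"] == pytest.approx(
            4.0 * 35.44 / 80.0
        )

    def test_oxo_species_without_3b_hydroxy_cannot_be_esterified(self, registry):
        state = TrueSampleState("plasma", 0.1, {}, {"7a-HCO": 5.0})
        with pytest.raises(ValueError, match="esterified"):
            simulate_workup(state, 0.05, True, registry=registry)

    def test_autoxidation_increments_are_seeded_and_coupled(self, registry):
        state = scenario_preset("SRM1950_like", autoxidation=True)
        gt1 = simulate_workup(state, 0.05, False, seed=5, registry=registry)
        gt2 = simulate_workup(state, 0.05, False, seed=5, registry=registry)
        gt3 = simulate_workup(state, 0.05, False, seed=6, registry=registry)
        assert gt1.autoxidation_added_ng == gt2.autoxidation_added_ng
        assert gt1.autoxidation_added_ng != gt3.autoxidation_added_ng
        # labelled artifacts scale with the [2H7]cholesterol spike
        ratio = (gt1.nominal_standard_ng["[2H7]cholesterol"]
                 / (state.free_ng_per_ml["cholesterol"] * 0.1))
        assert gt1.autoxidation_added_ng["[2H7]7a-HC"] == pytest.approx(
            gt1.autoxidation_added_ng["7a-HC"] * ratio
        )


class TestChromatogramSynthesis:
    def test_noiseless_ric_area_conserves_amount(self, registry):
        """With zero noise the monoisotopic-channel RIC integrates to
        amount × area_per_ng × response_factor within 0.1%."""
        state = TrueSampleState("plasma", 0.1, {"25-HC": 12.0})
        inst = InstrumentModel()
        run = simulate_run(state, 0.0, False, seed=0, instrument=inst,
                           registry=registry)
        mz = derivative_ion(registry.lookup("25-HC"), "A").mz
        ric = extract_ric(run, mz, 5.0)
        area = np.trapezoid(ric.intensities, ric.times_min * 60.0)
        assert area == pytest.approx(1.2 * inst.area_per_ng, rel=1e-3)

    def test_empty_state_emits_no_signal(self, registry):
        from eadsa.ledger import StandardMixLedger
        bare_ledger = StandardMixLedger(sample_additions_ng={})
        state = TrueSampleState("plasma", 0.1, {})
        run = simulate_chromatogram(
            simulate_workup(state, 0.0, False, registry=registry,
                            ledger=bare_ledger),
            registry=registry,
        )
        assert all(len(s.mz) == 0 for s in run.ms1_scans())

    def test_m1_satellite_matches_binomial_closed_form(self, registry):
        state = TrueSampleState("plasma", 0.1, {"25-HC": 10.0})
        inst = InstrumentModel()
        run = simulate_run(state, 0.0, False, instrument=inst, registry=registry)
        m0 = derivative_ion(registry.lookup("25-HC"), "A", isotopologue_k=0).mz
        m1 = derivative_ion(registry.lookup("25-HC"), "A", isotopologue_k=1).mz
        a0 = np.trapezoid(extract_ric(run, m0, 5).intensities,
                          extract_ric(run, m0, 5).times_min * 60)
        a1 = np.trapezoid(extract_ric(run, m1, 5).intensities,
                          extract_ric(run, m1, 5).times_min * 60)
        expected = stats.binom.pmf(1, 34, inst.p13C)
        assert a1 / a0 == pytest.approx(expected, rel=1e-3)

    def test_d5_impurity_emitted_at_15_percent(self, registry):
        from eadsa.extract import integrate_window
        state = TrueSampleState("plasma", 0.1, {})
        run = simulate_run(state, 0.05, False, registry=registry)
        d5 = derivative_ion(registry.lookup("[2H5]26R-HC"), "A").mz
        d6 = derivative_ion(registry.lookup("[2H6]26R-HC"), "A").mz
        # integrate the (25R)26 standards' own elution window; the d6 channel
        # also carries the [2H6]25-HC standard two conformer-widths earlier
        a5 = integrate_window(extract_ric(run, d5, 5), 7.5, 8.4)
        a6 = integrate_window(extract_ric(run, d6, 10), 7.5, 8.4)
        leak = stats.binom.pmf(1, 34, run.instrument.p13C)
        assert a5 / (a6 / (1 + 0.15 * leak)) == pytest.approx(0.15, rel=1e-2)

    def test_labeled_standards_elute_slightly_earlier(self, registry):
        state = TrueSampleState("plasma", 0.1, {"25-HC": 10.0})
        run = simulate_run(state, 0.05, False, registry=registry)
        mz_u = derivative_ion(registry.lookup("25-HC"), "A").mz
        mz_l = derivative_ion(registry.lookup("[2H6]25-HC"), "A").mz

        def apex_near(mz, lo=6.6, hi=7.4):
            ric = extract_ric(run, mz, 5)
            sel = (ric.times_min >= lo) & (ric.times_min <= hi)
            return ric.times_min[sel][np.argmax(ric.intensities[sel])]

        assert apex_near(mz_l) < apex_near(mz_u)


class TestDeterminismAndIO:
    def test_identical_seed_identical_peak_table_bytes(self, registry, tmp_path):
        state = scenario_preset("CSF_QC_like")
        inst = InstrumentModel(noise_sd=5.0, area_cv=0.05)
        paths = []
        for i in (1, 2):
            run = simulate_run(state, 0.02, False, seed=42, instrument=inst,
                               registry=registry)
            p = tmp_path / f"run{i}.csv"
            write_run(run, p, "peak_table_csv")
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_centroid_jsonl_round_trip(self, registry, tmp_path):
        state = TrueSampleState("plasma", 0.1, {"25-HC": 10.0, "7-OC": 3.0})
        run = simulate_run(state, 0.05, False, seed=3, registry=registry)
        p = tmp_path / "run.jsonl"
        write_run(run, p, "centroid_jsonl")
        back = read_run(p)
        assert len(back.scans) == len(run.scans)
        assert back.ground_truth.fraction_amounts_ng == run.ground_truth.fraction_amounts_ng
        i = len(run.scans) // 2
        np.testing.assert_allclose(back.scans[i].mz, run.scans[i].mz, atol=1e-6)
        np.testing.assert_allclose(back.scans[i].intensity,
                                   run.scans[i].intensity, atol=1e-5)

    def test_peak_table_row_per_species_fraction_conformer(self, registry):
        state = TrueSampleState("plasma", 0.1, {"25-HC": 10.0})
        run = simulate_run(state, 0.0, False, registry=registry)
        table = peak_table(run)
        rows = table[table["species_id"] == "25-HC"]
        # fraction A only, one row per syn/anti conformer
        assert list(rows["fraction"]) == ["A", "A"]
        assert set(rows["conformer_index"]) == {0, 1}
        assert rows["area"].sum() == pytest.approx(1.0 * run.instrument.area_per_ng)

    def test_mzml_export_round_trips_binary_arrays(self, registry, tmp_path):
        import base64
        import struct
        import zlib
        from xml.etree import ElementTree

        state = TrueSampleState("plasma", 0.1, {"25-HC": 10.0})
        run = simulate_run(state, 0.0, False, registry=registry)
        p = tmp_path / "run.mzML"
        write_run(run, p, "mzml")
        ns = {"mz": "http://psi.hupo.org/ms/mzml"}
        tree = ElementTree.parse(p)
        spectra = tree.findall(".//mz:spectrum", ns)
        assert len(spectra) == len(run.scans)
        nonempty_idx = next(i for i, s in enumerate(run.scans) if len(s.mz))
        binaries = spectra[nonempty_idx].findall(".//mz:binary", ns)
        raw = zlib.decompress(base64.b64decode(binaries[0].text))
        mzs = struct.unpack(f"<{len(raw) // 8}d", raw)
        np.testing.assert_allclose(mzs, run.scans[nonempty_idx].mz, atol=1e-9)


class TestScenarioPresets:
    def test_ctx_lacks_26_hydroxycholesterol(self):
        state = scenario_preset("CTX")
        assert state.free_ng_per_ml["26R-HC"] == 0.0
        assert state.esterified_ng_per_ml["26R-HC"] == 0.0
        assert state.free_ng_per_ml["7a-HCO"] > scenario_preset(
            "SRM1950_like").free_ng_per_ml["7a-HCO"]

    def test_acox2_inverts_c27_acid_epimer_ratio(self):
        state = scenario_preset("ACOX2")
        assert (state.free_ng_per_ml["7aH3OCA-25S"]
                > state.free_ng_per_ml["7aH3OCA-25R"])
        normal = scenario_preset("SRM1950_like")
        assert (normal.free_ng_per_ml["7aH3OCA-25R"]
                > normal.free_ng_per_ml["7aH3OCA-25S"])

    def test_srm1950_cholesterol_scale(self):
        state = scenario_preset("SRM1950_like")
        total = (state.free_ng_per_ml["cholesterol"]
                 + state.esterified_ng_per_ml["cholesterol"])
        assert total == pytest.approx(1.541e6, rel=0.05)   # ~1.5 mg/mL
        free_pct = 100 * state.free_ng_per_ml["cholesterol"] / total
        assert free_pct == pytest.approx(25.0, abs=3.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            scenario_preset("nope")
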