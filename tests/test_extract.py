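"""RIC/MRM extraction, peak integration, conformer merging and the M+1
isotopologue interference correction."""

import numpy as np
import pytest
from scipy import stats

from eadsa.extract import (
    Chromatogram,
    PeakMeasurement,
    correct_m1_interference,
    detect_and_integrate,
    extract_mrm,
    extract_ric,
    integrate_window,
    m1_fraction,
    merge_conformers,
)
from eadsa.registry import transition_path
from eadsa.simulate import Scan, TrueSampleState, simulate_run


def _scan(t, mzs, intens, level=1, prec=()):
    return Scan(t, level, prec, np.asarray(mzs, float), np.asarray(intens, float))


class TestExtractRic:
    def test_single_centroid_reproduced(self):
        scans = [_scan(0.0, [500.0], [100.0]), _scan(1 / 60, [], [])]
        ric = extract_ric(scans, 500.0, 5.0)
        assert list(ric.intensities) == [100.0, 0.0]

    def test_window_boundary_is_in_ppm(self):
        mz = 500.0
        scans = [_scan(0.0, [mz * (1 + 6e-6)], [50.0])]
        assert extract_ric(scans, mz, 5.0).intensities[0] == 0.0
        assert extract_ric(scans, mz, 7.0).intensities[0] == 50.0

    def test_empty_scan_list_rejected(self):
        with pytest.raises(ValueError):
            extract_ric([], 500.0, 5.0)

    def test_matches_brute_force_double_loop(self, registry):
        state = TrueSampleState("plasma", 0.1, {"25-HC": 10.0, "24S-HC": 5.0})
        run = simulate_run(state, 0.05, False, seed=2, registry=registry)
        scans = run.ms1_scans()[:100]
        mz, ppm = 539.4368, 5.0
        ric = extract_ric(scans, mz, ppm)
        tol = mz * ppm * 1e-6
        for i, s in enumerate(scans):
            brute = sum(
                inten for m, inten in zip(s.mz, s.intensity)
                if abs(m - mz) <= tol
            )
            assert ric.intensities[i] == pytest.approx(brute, rel=1e-12, abs=1e-12)

    def test_linearity_over_run_superposition(self, registry):
        """RIC of the pointwise sum of two runs equals the sum of RICs."""
        s1 = TrueSampleState("plasma", 0.1, {"25-HC": 10.0})
        s2 = TrueSampleState("plasma", 0.1, {"25-HC": 4.0})
        r1 = simulate_run(s1, 0.0, False, registry=registry)
        r2 = simulate_run(s2, 0.0, False, registry=registry)
        merged = [
            _scan(a.time_min, np.concatenate([a.mz, b.mz]),
                  np.concatenate([a.intensity, b.intensity]))
            for a, b in zip(r1.ms1_scans(), r2.ms1_scans())
        ]
        mz = 555.4317
        lhs = extract_ric(merged, mz, 5.0).intensities
        rhs = (extract_ric(r1, mz, 5.0).intensities
               + extract_ric(r2, mz, 5.0).intensities)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


class TestExtractMrm:
    def test_26hc_transparent_to_353_transition(self, registry):
        """(25R)26-HC lacks the m/z 353.3 fragment, so the 24-HC MRM stays
        flat when only (25R)26-HC is present."""
        state = TrueSampleState("plasma", 0.1, {"26R-HC": 50.0})
        run = simulate_run(state, 0.0, False, registry=registry)
        path = transition_path(registry.lookup("24R-HC"), "A")
        mrm = extract_mrm(run, path)
        assert mrm.intensities.max() == 0.0

    def test_own_path_yields_doublet(self, registry):
        state = TrueSampleState("plasma", 0.1, {"24S-HC": 20.0})
        run = simulate_run(state, 0.0, False, registry=registry)
        path = transition_path(registry.lookup("24S-HC"), "A")
        mrm = extract_mrm(run, path)
        peaks = detect_and_integrate(mrm, 6.75, window_min=0.3)
        assert len(peaks) == 2

    def test_matches_brute_force_scan_filter(self, registry):
        state = TrueSampleState("plasma", 0.1, {"24S-HC": 20.0, "26R-HC": 30.0})
        run = simulate_run(state, 0.05, False, registry=registry)
        path = transition_path(registry.lookup("24S-HC"), "A")
        mrm = extract_mrm(run, path, frag_tol=0.3)
        expected = {}
        for s in run.msn_scans():
            if (abs(s.precursors[0] - path.levels[0]) <= 0.3
                    and abs(s.precursors[1] - path.levels[1]) <= 0.3):
                v = sum(i for m, i in zip(s.mz, s.intensity)
                        if abs(m - path.levels[2]) <= 0.3)
                expected[s.time_min] = expected.get(s.time_min, 0.0) + v
        got = dict(zip(mrm.times_min, mrm.intensities))
        assert got == pytest.approx(expected)


class TestDetectAndIntegrate:
    def _gaussian(self, area=1000.0, rt=5.0, sigma=0.03):
        t = np.arange(4.0, 6.0, 1 / 60)
        y = area * stats.norm.pdf(t * 60, rt * 60, sigma * 60)
        return Chromatogram(t, y)

    def test_noiseless_gaussian_area_within_1pct(self):
        chrom = self._gaussian(area=1234.5)
        peaks = detect_and_integrate(chrom, 5.0, 0.2)
        assert len(peaks) == 1
        assert peaks[0].area == pytest.approx(1234.5, rel=0.01)
        assert peaks[0].rt_apex_min == pytest.approx(5.0, abs=0.02)

    def test_flat_trace_yields_nothing(self):
        chrom = Chromatogram(np.linspace(0, 1, 61), np.zeros(61))
        assert detect_and_integrate(chrom, 0.5, 0.2) == []

    def test_two_separated_gaussians_integrate_independently(self):
        t = np.arange(4.0, 6.5, 1 / 60)
        y = (800.0 * stats.norm.pdf(t * 60, 5.0 * 60, 1.8)
             + 300.0 * stats.norm.pdf(t * 60, 5.6 * 60, 1.8))
        chrom = Chromatogram(t, y)
        peaks = detect_and_integrate(chrom, 5.3, 0.5)
        assert len(peaks) == 2
        assert peaks[0].area == pytest.approx(800.0, rel=0.01)
        assert peaks[1].area == pytest.approx(300.0, rel=0.01)

    def test_window_integration_of_full_trace(self):
        chrom = self._gaussian(area=500.0)
        assert integrate_window(chrom, 4.0, 6.0) == pytest.approx(500.0, rel=1e-3)


class TestMergeConformers:
    def _peaks(self, specs):
        from eadsa.extract import Peak
        return [Peak(a, rt, rt - 0.05, rt + 0.05, a) for rt, a in specs]

    def test_doublet_sums_to_one_measurement(self):
        pm = merge_conformers(self._peaks([(5.0, 600.0), (5.3, 400.0)]),
                              "x", "A", 5.0)
        assert pm.area == 1000.0
        assert pm.n_conformers_merged == 2
        assert pm.rt_apex_min == 5.0

    def test_single_peak_passes_through(self):
        pm = merge_conformers(self._peaks([(5.0, 600.0)]), "x", "A", 5.0)
        assert pm.n_conformers_merged == 1
        assert not pm.flags

    def test_three_candidates_flag_coelution_keep_two_largest(self):
        pm = merge_conformers(
            self._peaks([(5.0, 600.0), (5.05, 50.0), (5.3, 400.0)]),
            "x", "A", 5.0)
        assert "coelution" in pm.flags
        assert pm.area == 1000.0

    def test_misaligned_neighbour_rejected(self):
        """A peak 0.15 min off both conformer positions belongs to another
        species and must not be absorbed into this doublet."""
        pm = merge_conformers(self._peaks([(4.85, 900.0)]), "x", "A", 5.0)
        assert pm.area == 0.0
        assert "below_snr" in pm.flags

    def test_no_candidates_reports_below_snr(self):
        pm = merge_conformers([], "x", "A", 5.0)
        assert pm.area == 0.0 and "below_snr" in pm.flags


class TestM1Correction:
    def test_binomial_leak_fraction(self):
        # 34 carbons at natural 13C abundance
        assert m1_fraction(34, 0.0107) == pytest.approx(
            34 * 0.0107 * (1 - 0.0107) ** 33, rel=1e-12
        )

    def test_algebraic_subtraction(self):
        target = PeakMeasurement("t", "A", 1000.0, 5.0)
        donor = PeakMeasurement("d", "A", 1000.0, 5.0)
        out = correct_m1_interference(target, donor, 34, 0.0107)
        assert out.area == pytest.approx(1000.0 - 255.5, abs=1.0)
        assert "m1_interference_corrected" in out.flags

    def test_zero_donor_leaves_target_unchanged(self):
        target = PeakMeasurement("t", "A", 123.0, 5.0)
        donor = PeakMeasurement("d", "A", 0.0, 5.0)
        assert correct_m1_interference(target, donor).area == 123.0

    def test_negative_result_floored_and_flagged(self):
        target = PeakMeasurement("t", "A", 10.0, 5.0)
        donor = PeakMeasurement("d", "A", 1000.0, 5.0)
        out = correct_m1_interference(target, donor)
        assert out.area == 0.0
        assert "clipped_negative" in out.flags
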