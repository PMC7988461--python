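"""Reconstructed-ion / MRM chromatogram extraction and peak integration.

Turns centroided scans into per-analyte, per-fraction integrated areas:
narrow-ppm RIC extraction from MS1 scans, pseudo-MRM traces from MS3 scans
that follow a precursor → [M−pyridine]+ → diagnostic-fragment path, apex
detection with local-minimum/1%-of-apex boundaries and trapezoidal
integration, merging of syn/anti conformer doublets, and the algebraic
correction for the 13C M+1 satellite of a co-eluting one-dalton-lighter
isotopologue (the [2H6]/[2H7] interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats

from .registry import (
    FRAGMENT_TOL,
    Fraction,
    Registry,
    TransitionPath,
    build_default_registry,
    derivative_ion,
    transition_path,
)
from .simulate import Scan, SimulatedRun


@dataclass(frozen=True)
class Chromatogram:
    """Extracted-ion trace: ascending times (min) and non-negative signal."""

    times_min: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, float)
        y = np.asarray(self.intensities, float)
        if t.shape != y.shape:
            raise ValueError("times and intensities differ in length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("negative intensity")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "intensities", y)

    @property
    def times_s(self) -> np.ndarray:
        return self.times_min * 60.0


@dataclass
class Peak:
    area: float          # intensity * s
    rt_apex_min: float
    left_min: float
    right_min: float
    height: float


@dataclass
class PeakMeasurement:
    species_id: str
    fraction: str
    area: float
    rt_apex_min: float
    n_conformers_merged: int = 1
    channel: str = "RIC"   # RIC | MRM
    flags: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("negative peak area")


@dataclass
class ExtractionConfig:
    ppm_tol: float = 5.0
    rt_window_min: float = 0.15
    snr_min: float = 3.0
    frag_tol: float = FRAGMENT_TOL
    integration: str = "peaks"      # "peaks" | "window"
    smooth: bool = False            # optional 3-point moving average
    #: apex-to-expected-rt alignment tolerance; tight enough to tell the
    #: partially co-eluting 24R/(25R)26 epimer pair (0.15 min apart) apart
    apex_tol_min: float = 0.1
    #: wider window used for interference-correction workflows, where the
    #: mass-unresolved M+1 satellite of a 1-Da-lighter co-eluter must fall
    #: inside the integrated channel for the algebraic subtraction to hold
    interference_ppm: float = 10.0

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0:
            raise ValueError("ppm_tol must be positive")


# ---------------------------------------------------------------------------
# trace extraction
# ---------------------------------------------------------------------------

def _scan_list(run_or_scans) -> List[Scan]:
    if isinstance(run_or_scans, SimulatedRun):
        return run_or_scans.scans
    return list(run_or_scans)


def extract_ric(run_or_scans, mz: float, ppm: float = 5.0) -> Chromatogram:
    """Sum centroid intensity within a closed ±ppm window, per MS1 scan."""
    scans = [s for s in _scan_list(run_or_scans) if s.ms_level == 1]
    if not scans:
        raise ValueError("no MS1 scans to extract from")
    tol = mz * ppm * 1e-6
    times = np.array([s.time_min for s in scans])
    intens = np.empty(len(scans))
    for i, s in enumerate(scans):
        if len(s.mz) == 0:
            intens[i] = 0.0
            continue
        m = np.asarray(s.mz)
        sel = np.abs(m - mz) <= tol
        intens[i] = float(np.asarray(s.intensity)[sel].sum())
    return Chromatogram(times, intens)


def extract_mrm(run_or_scans, path: TransitionPath,
                frag_tol: float = FRAGMENT_TOL) -> Chromatogram:
    """Pseudo-MRM trace from MSn scans following *path*.

    Scans whose precursor chain matches level 1 and level 2 within
    ``frag_tol`` contribute: the summed product intensity within
    ``frag_tol`` of level 3 if the path has one, else the scan's total ion
    current (the TIC m1 → m2 → usage).
    """
    scans = [s for s in _scan_list(run_or_scans) if s.ms_level > 1]
    times, intens = [], []
    for s in scans:
        if len(s.precursors) < 2:
            raise ValueError("MSn scan lacks a two-level precursor path")
        if abs(s.precursors[0] - path.levels[0]) > frag_tol:
            continue
        if abs(s.precursors[1] - path.levels[1]) > frag_tol:
            continue
        if len(path.levels) > 2:
            sel = np.abs(np.asarray(s.mz) - path.levels[2]) <= frag_tol
            v = float(np.asarray(s.intensity)[sel].sum())
        else:
            v = float(np.asarray(s.intensity).sum())
        times.append(s.time_min)
        intens.append(v)
    if not times:
        return Chromatogram(np.array([0.0]), np.array([0.0]))
    order = np.argsort(times)
    return Chromatogram(np.asarray(times)[order], np.asarray(intens)[order])


# ---------------------------------------------------------------------------
# peak detection / integration
# ---------------------------------------------------------------------------

def _smooth3(y: np.ndarray) -> np.ndarray:
    if len(y) < 3:
        return y
    out = y.copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def detect_and_integrate(
    chrom: Chromatogram,
    expected_rt_min: float,
    window_min: float = 0.2,
    min_height: float = 0.0,
    smooth: bool = False,
) -> List[Peak]:
    """Local maxima near the expected rt, integrated by the trapezoid rule.

    Peak boundaries extend from the apex to the flanking local minimum or to
    the 1%-of-apex crossing, whichever comes first.  Returns an empty list
    when nothing rises above ``min_height`` inside the window.
    """
    if len(chrom.times_min) == 0:
        raise ValueError("empty chromatogram")
    y = _smooth3(chrom.intensities) if smooth else chrom.intensities
    t = chrom.times_min
    idx, _ = _signal.find_peaks(y, height=max(min_height, 0.0) or None)
    lo, hi = expected_rt_min - window_min, expected_rt_min + window_min
    peaks: List[Peak] = []
    for i in idx:
        if not (lo <= t[i] <= hi):
            continue
        floor = 0.01 * y[i]
        left = i
        while left > 0 and y[left - 1] < y[left] and y[left - 1] > floor:
            left -= 1
        right = i
        n = len(y) - 1
        while right < n and y[right + 1] < y[right] and y[right + 1] > floor:
            right += 1
        seg = slice(left, right + 1)
        area = float(np.trapezoid(y[seg], chrom.times_s[seg]))
        peaks.append(Peak(area, float(t[i]), float(t[left]), float(t[right]), float(y[i])))
    return peaks


def integrate_window(chrom: Chromatogram, t0_min: float, t1_min: float) -> float:
    """Plain trapezoidal area of the trace between two times (no detection)."""
    sel = (chrom.times_min >= t0_min) & (chrom.times_min <= t1_min)
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(chrom.intensities[sel], chrom.times_s[sel]))


def merge_conformers(
    peaks: Sequence[Peak],
    species_id: str,
    fraction: str,
    expected_rt_min: float,
    gap_max_min: float = 0.45,
    channel: str = "RIC",
    conformer_gap_min: float = 0.3,
    apex_tol_min: float = 0.1,
) -> PeakMeasurement:
    """Merge the syn/anti hydrazone doublet into one measurement.

    Candidates are detected peaks within ``gap_max_min`` of the expected
    first apex whose apex also aligns (within ``apex_tol_min``) with one of
    the two expected conformer positions — a misaligned peak belongs to a
    neighbouring species, not to this doublet.  More than two candidates
    sets the ``coelution`` flag and the two largest are kept.
    """
    flags: Set[str] = set()
    expected_apexes = (expected_rt_min, expected_rt_min + conformer_gap_min)
    cands = [
        p for p in peaks
        if expected_rt_min - gap_max_min <= p.rt_apex_min <= expected_rt_min + gap_max_min
        and min(abs(p.rt_apex_min - e) for e in expected_apexes) <= apex_tol_min
    ]
    if not cands:
        return PeakMeasurement(species_id, fraction, 0.0, expected_rt_min,
                               0, channel, {"below_snr"})
    if len(cands) > 2:
        flags.add("coelution")
        cands = sorted(cands, key=lambda p: p.area, reverse=True)[:2]
    area = sum(p.area for p in cands)
    apex = max(cands, key=lambda p: p.height).rt_apex_min
    return PeakMeasurement(species_id, fraction, area, apex, len(cands),
                           channel, flags)


# ---------------------------------------------------------------------------
# M+1 isotopologue interference correction
# ---------------------------------------------------------------------------

def m1_fraction(carbon_count: int, p13c: float = 0.0107) -> float:
    """Binomial probability that exactly one carbon is 13C."""
    return float(stats.binom.pmf(1, carbon_count, p13c))


def correct_m1_interference(
    target: PeakMeasurement,
    donor: PeakMeasurement,
    carbon_count: int = 34,
    p13c: float = 0.0107,
) -> PeakMeasurement:
    """Subtract the donor's M+1 satellite from the target's channel area.

    The donor is the one-dalton-lighter co-eluting isotopologue (e.g. the
    [2H6] standard under a [2H7] channel): its M+1 satellite is
    mass-unresolved from the target, so the target area is inflated by
    ``donor.area × C·p·(1−p)^(C−1)``.  Both areas must be integrated over
    the same time window for the subtraction to be exact.  A negative
    result is floored at zero and flagged.
    """
    leak = donor.area * m1_fraction(carbon_count, p13c)
    corrected = target.area - leak
    flags = set(target.flags) | {"m1_interference_corrected"}
    if corrected < 0:
        corrected = 0.0
        flags.add("clipped_negative")
    return replace(target, area=corrected, flags=flags)


# ---------------------------------------------------------------------------
# run-level orchestration
# ---------------------------------------------------------------------------

def extract_run(
    run: SimulatedRun,
    registry: Optional[Registry] = None,
    config: Optional[ExtractionConfig] = None,
    species_ids: Optional[Iterable[str]] = None,
    window_species: Optional[Iterable[str]] = None,
    window_halfwidth_min: float = 0.45,
) -> pd.DataFrame:
    """Measure every requested (species, fraction) in a run.

    For each target the RIC at the derivative m/z is integrated around the
    expected retention time (conformer doublet merged); species with a
    library diagnostic fragment additionally get an MRM measurement.
    Species listed in ``window_species`` are integrated over a fixed window
    instead of detected peaks (used for interference-correction workflows,
    where target and donor must share boundaries).  Returns a peak table
    with one row per measurement.
    """
    registry = registry or build_default_registry()
    config = config or ExtractionConfig()
    inst = run.instrument
    window_species = set(window_species or ())
    ids = list(species_ids) if species_ids is not None else sorted(
        run.ground_truth.fraction_amounts_ng
    )
    noise_floor = inst.noise_sd * config.snr_min
    rows = []
    for sid in ids:
        sp = registry.lookup(sid)
        if sp.nominal_rt_min is None:
            continue
        rt = sp.nominal_rt_min + (inst.rt_shift_labeled_min if sp.label_count else 0.0)
        for fraction in (Fraction.A, Fraction.B):
            if not sp.derivatized_in(fraction):
                continue
            ion = derivative_ion(sp, fraction)
            measurements: List[PeakMeasurement] = []
            if sid in window_species:
                ric = extract_ric(run, ion.mz, config.interference_ppm)
                area = integrate_window(
                    ric, rt - window_halfwidth_min,
                    rt + inst.conformer_rt_gap_min + window_halfwidth_min,
                )
                pm = PeakMeasurement(sid, fraction.value, area, rt,
                                     2, "RIC", {"window_integrated"})
                measurements.append(pm)
            else:
                ric = extract_ric(run, ion.mz, config.ppm_tol)
                peaks = detect_and_integrate(
                    ric, rt + inst.conformer_rt_gap_min / 2.0,
                    window_min=inst.conformer_rt_gap_min / 2.0 + config.rt_window_min,
                    min_height=noise_floor, smooth=config.smooth,
                )
                measurements.append(
                    merge_conformers(peaks, sid, fraction.value, rt,
                                     gap_max_min=inst.conformer_rt_gap_min
                                     + config.rt_window_min,
                                     conformer_gap_min=inst.conformer_rt_gap_min,
                                     apex_tol_min=config.apex_tol_min)
                )
            path = transition_path(sp, fraction)
            if len(path.levels) > 2:
                mrm = extract_mrm(run, path, config.frag_tol)
                if sid in window_species:
                    area = integrate_window(
                        mrm, rt - window_halfwidth_min,
                        rt + inst.conformer_rt_gap_min + window_halfwidth_min,
                    )
                    measurements.append(PeakMeasurement(
                        sid, fraction.value, area, rt, 2, "MRM",
                        {"window_integrated"}))
                else:
                    mpeaks = detect_and_integrate(
                        mrm, rt + inst.conformer_rt_gap_min / 2.0,
                        window_min=inst.conformer_rt_gap_min / 2.0 + config.rt_window_min,
                        smooth=config.smooth,
                    )
                    measurements.append(
                        merge_conformers(mpeaks, sid, fraction.value, rt,
                                         gap_max_min=inst.conformer_rt_gap_min
                                         + config.rt_window_min,
                                         channel="MRM",
                                         conformer_gap_min=inst.conformer_rt_gap_min,
                                         apex_tol_min=config.apex_tol_min)
                    )
            for pm in measurements:
                rows.append({
                    "species_id": pm.species_id,
                    "fraction": pm.fraction,
                    "channel": pm.channel,
                    "area": pm.area,
                    "rt_min": pm.rt_apex_min,
                    "n_conformers": pm.n_conformers_merged,
                    "flags": ";".join(sorted(pm.flags)),
                })
    return pd.DataFrame(
        rows, columns=["species_id", "fraction", "channel", "area",
                       "rt_min", "n_conformers", "flags"]
    )
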