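"""Synthetic LC-MS(MSn) runs with known ground truth.

The generator emulates the assay end to end: spiking a plasma or CSF sample
with the isotope-labelled standard mix, optional alkaline hydrolysis of the
esterified sterol pool (with base-catalysed losses of labile 7-hydroxy
species), the A/B split-and-derivatise step, and acquisition of centroided
MS1 spectra with interleaved MS3 scans on a 17-min gradient.

Modelled instrument behaviour: Gaussian peaks split into syn/anti hydrazone
conformer doublets, a deterministic binomial 13C isotopologue envelope,
finite mass resolving power (near-isobaric centroids are merged into one
intensity-weighted centroid, which is what makes the M+1 interference between
the [2H6](25R)26-HC satellite and [2H7]24R-HC emerge naturally), the [2H5]
impurity of the [2H6](25R)26-HC standard, additive detector noise and an
optional per-peak area jitter.  Not modelled: peak tailing, saturation and
ion suppression.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .elements import DEFAULT_MASSES, neutral_mass
from .ledger import StandardMixLedger, default_ledger
from .registry import (
    FRAGMENT_LIBRARY,
    GP_FOR_FRACTION,
    Fraction,
    Registry,
    SterolSpecies,
    build_default_registry,
    derivative_ion,
    transition_path,
)

_H2O_MASS = 18.0105646


@dataclass
class TrueSampleState:
    """Ground-truth composition of a simulated biofluid sample."""

    matrix: str = "plasma"  # "plasma" | "CSF"
    volume_ml: float = 0.1
    free_ng_per_ml: Dict[str, float] = field(default_factory=dict)
    esterified_ng_per_ml: Dict[str, float] = field(default_factory=dict)
    #: Max ex-vivo autoxidation increment (ng/mL equivalents) per artifact-
    #: prone species; the realised increment is drawn once per run.
    autoxidation_max_ng_per_ml: Dict[str, float] = field(default_factory=dict)

    def validate(self, registry: Registry) -> None:
        for sid, conc in {**self.free_ng_per_ml, **self.esterified_ng_per_ml}.items():
            if sid not in registry:
                raise KeyError(f"unknown species in sample state: {sid}")
            if conc < 0:
                raise ValueError(f"negative concentration for {sid}")
        for sid, conc in self.esterified_ng_per_ml.items():
            if conc > 0 and not registry.lookup(sid).esterifiable:
                raise ValueError(
                    f"{sid} has no 3β-hydroxy group and cannot be esterified"
                )


@dataclass
class InstrumentModel:
    """Chromatography/detector parameters of the simulated LC-MS system."""

    response_factor: Dict[str, float] = field(default_factory=dict)
    rt_sigma_min: float = 0.03       # Gaussian peak sigma
    rt_shift_labeled_min: float = -0.05
    conformer_split: float = 0.6     # area share of the earlier conformer
    conformer_rt_gap_min: float = 0.3
    noise_sd: float = 0.0            # additive centroid noise (intensity)
    area_cv: float = 0.0             # per-peak multiplicative area jitter
    p13C: float = 0.0107
    area_per_ng: float = 1.0e5       # intensity*s per ng on the M channel
    resolving_power: float = 120000.0
    gradient_min: float = 17.0
    ms1_hz: float = 1.0
    ms3_period_s: float = 2.0
    ms3_yield: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.conformer_split <= 1.0):
            raise ValueError("conformer_split must be in (0, 1]")
        if not (0.0 < self.p13C < 0.02):
            raise ValueError("p13C outside plausible range (0, 0.02)")

    def rf(self, species_id: str) -> float:
        return self.response_factor.get(species_id, 1.0)


@dataclass
class Scan:
    time_min: float
    ms_level: int
    precursors: Tuple[float, ...]
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class GroundTruth:
    """Everything a recovery test needs to score the pipeline."""

    matrix: str
    sample_volume_ml: float
    mix_volume_ml: float
    hydrolysed: bool
    seed: int
    free_ng_per_ml: Dict[str, float]
    esterified_ng_per_ml: Dict[str, float]
    #: actual ng of each species present in the processed extract, per
    #: fraction (post hydrolysis losses and autoxidation increments)
    fraction_amounts_ng: Dict[str, Dict[str, float]]
    #: nominal standard amounts (ledger arithmetic) used for quantification
    nominal_standard_ng: Dict[str, float]
    autoxidation_added_ng: Dict[str, float] = field(default_factory=dict)
    base_loss_fraction: float = 0.0

    def true_conc(self, species_id: str) -> float:
        """ng/mL the assay should report for this analyte in this run."""
        free = self.free_ng_per_ml.get(species_id, 0.0)
        if self.hydrolysed:
            return free + self.esterified_ng_per_ml.get(species_id, 0.0)
        return free


@dataclass
class SimulatedRun:
    scans: List[Scan]
    ground_truth: GroundTruth
    seed: int
    instrument: InstrumentModel

    def ms1_scans(self) -> List[Scan]:
        return [s for s in self.scans if s.ms_level == 1]

    def msn_scans(self) -> List[Scan]:
        return [s for s in self.scans if s.ms_level > 1]


# ---------------------------------------------------------------------------
# workup
# ---------------------------------------------------------------------------

def simulate_workup(
    state: TrueSampleState,
    mix_volume_ml: float,
    hydrolysed: bool,
    seed: int = 0,
    registry: Optional[Registry] = None,
    ledger: Optional[StandardMixLedger] = None,
    base_loss_fraction: float = 0.2,
    analyte_recovery: float = 1.0,
) -> GroundTruth:
    """Sample prep bookkeeping: ng of every species entering each fraction.

    Fraction A receives everything that can be charge-tagged after the
    oxidase step; fraction B only species with a native oxo group.  With
    hydrolysis the esterified pool is released, and species carrying the
    labile 7-hydroxy group lose ``base_loss_fraction`` of their amount —
    analyte and its exact isotope surrogate alike, which is what lets
    isotope dilution cancel the loss.  Ex-vivo autoxidation increments are
    drawn once per run and added to the unlabeled artifact species and, in
    proportion to the [2H7]cholesterol spike, to their labelled analogues.
    """
    registry = registry or build_default_registry()
    ledger = ledger or default_ledger()
    if state.volume_ml < 0 or mix_volume_ml < 0:
        raise ValueError("volumes must be non-negative")
    state.validate(registry)
    rng = np.random.default_rng(seed)

    # analyte_recovery models matrix-bound losses that the free-solution
    # internal standards do not share (the "apparent" extraction efficiency)
    amounts: Dict[str, float] = {}
    for sid, free in state.free_ng_per_ml.items():
        ng = free * state.volume_ml * analyte_recovery
        if hydrolysed:
            ng += (state.esterified_ng_per_ml.get(sid, 0.0)
                   * state.volume_ml * analyte_recovery)
        if ng > 0:
            amounts[sid] = amounts.get(sid, 0.0) + ng
    for sid, est in state.esterified_ng_per_ml.items():
        if hydrolysed and sid not in state.free_ng_per_ml and est > 0:
            amounts[sid] = amounts.get(sid, 0.0) + est * state.volume_ml * analyte_recovery

    nominal = ledger.standard_amounts_ng(
        mix_volume_ml, matrix=state.matrix, registry=registry
    )
    for sid, ng in nominal.items():
        if ng > 0:
            amounts[sid] = amounts.get(sid, 0.0) + ng

    # autoxidation artifacts (drawn before degradation: they form during
    # workup, and the hydrolysis losses below act on whatever is present)
    autox_added: Dict[str, float] = {}
    chol_ng = amounts.get("cholesterol", 0.0)
    d7chol_ng = amounts.get("[2H7]cholesterol", 0.0)
    label_scale = (d7chol_ng / chol_ng) if chol_ng > 0 else 0.0
    labeled_artifact = {
        "7a-HC": "[2H7]7a-HC",
        "7b-HC": "[2H7]7b-HC",
        "7-OC": "[2H7]7-OC",
        "5a6b-diHC": "[2H7]5a6b-diHC",
    }
    for sid, max_inc in state.autoxidation_max_ng_per_ml.items():
        if max_inc <= 0:
            continue
        inc = float(rng.uniform(0.0, max_inc)) * state.volume_ml
        amounts[sid] = amounts.get(sid, 0.0) + inc
        autox_added[sid] = inc
        lab = labeled_artifact.get(sid)
        if lab and label_scale > 0:
            lab_inc = inc * label_scale
            amounts[lab] = amounts.get(lab, 0.0) + lab_inc
            autox_added[lab] = lab_inc

    if hydrolysed and base_loss_fraction > 0:
        for sid in list(amounts):
            if registry.lookup(sid).has_7_hydroxy:
                amounts[sid] *= 1.0 - base_loss_fraction

    fraction_amounts: Dict[str, Dict[str, float]] = {}
    for sid, ng in amounts.items():
        sp = registry.lookup(sid)
        if not sp.derivatizable or sp.nominal_rt_min is None:
            continue
        fraction_amounts[sid] = {
            "A": ng if sp.derivatized_in(Fraction.A) else 0.0,
            "B": ng if sp.derivatized_in(Fraction.B) else 0.0,
        }

    return GroundTruth(
        matrix=state.matrix,
        sample_volume_ml=state.volume_ml,
        mix_volume_ml=mix_volume_ml,
        hydrolysed=hydrolysed,
        seed=seed,
        free_ng_per_ml=dict(state.free_ng_per_ml),
        esterified_ng_per_ml=dict(state.esterified_ng_per_ml),
        fraction_amounts_ng=fraction_amounts,
        nominal_standard_ng=nominal,
        autoxidation_added_ng=autox_added,
        base_loss_fraction=base_loss_fraction if hydrolysed else 0.0,
    )


# ---------------------------------------------------------------------------
# chromatogram / spectra synthesis
# ---------------------------------------------------------------------------

def _envelope(carbons: int, p13c: int | float, kmax: int = 2) -> np.ndarray:
    """Satellite areas relative to the monoisotopic channel.

    M+k carries ``binom.pmf(k, C, p)`` of the monoisotopic area; the common
    (1-p)^C attenuation of the M channel itself is absorbed into
    ``area_per_ng`` and cancels in every isotope-dilution ratio (all GP
    derivatives here are C34).
    """
    ks = np.arange(kmax + 1)
    rel = stats.binom.pmf(ks, carbons, p13c)
    rel = rel / 1.0
    rel[0] = 1.0
    return rel


def _merge_centroids(mz: np.ndarray, inten: np.ndarray, resolving_power: float):
    """Merge centroids closer than the instrument FWHM (weighted mean m/z)."""
    if len(mz) == 0:
        return mz, inten
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    out_mz: List[float] = []
    out_i: List[float] = []
    cur_mz, cur_i = mz[0], inten[0]
    for m, i in zip(mz[1:], inten[1:]):
        if m - cur_mz < cur_mz / resolving_power:
            tot = cur_i + i
            if tot > 0:
                cur_mz = (cur_mz * cur_i + m * i) / tot
            cur_i = tot
        else:
            out_mz.append(cur_mz)
            out_i.append(cur_i)
            cur_mz, cur_i = m, i
    out_mz.append(cur_mz)
    out_i.append(cur_i)
    return np.asarray(out_mz), np.asarray(out_i)


class _Emitter:
    """Per-(species, fraction) peak model: channels, conformers, intensity."""

    def __init__(self, sp: SterolSpecies, fraction: Fraction, amount_ng: float,
                 instrument: InstrumentModel, rng: np.random.Generator):
        self.sp = sp
        self.fraction = fraction
        gp = GP_FOR_FRACTION[fraction]
        self.gp = gp
        ion0 = derivative_ion(sp, fraction, gp, 0)
        carbons = ion0.ion_formula.count("C")
        rel = _envelope(carbons, instrument.p13C)
        self.channel_mz = np.array(
            [derivative_ion(sp, fraction, gp, k).mz for k in range(len(rel))]
        )
        self.rel = rel
        rt = sp.nominal_rt_min
        if sp.label_count > 0:
            rt = rt + instrument.rt_shift_labeled_min
        self.rts = [rt]
        self.splits = [instrument.conformer_split]
        if instrument.conformer_split < 1.0:
            self.rts.append(rt + instrument.conformer_rt_gap_min)
            self.splits.append(1.0 - instrument.conformer_split)
        self.sigma = instrument.rt_sigma_min
        area = amount_ng * instrument.area_per_ng * instrument.rf(sp.id)
        if instrument.area_cv > 0:
            area *= max(0.05, 1.0 + float(rng.normal(0.0, instrument.area_cv)))
        self.total_area_s = area
        self.pyloss = gp.pyridine_loss_mass()

    def ms1_intensity(self, t_min: np.ndarray | float) -> np.ndarray | float:
        """Monoisotopic-channel intensity (per second) at time t."""
        t = np.asarray(t_min, dtype=float)
        sigma_s = self.sigma * 60.0
        y = np.zeros_like(t)
        for rt, split in zip(self.rts, self.splits):
            z = (t - rt) * 60.0 / sigma_s
            y = y + split * np.exp(-0.5 * z * z) / (sigma_s * np.sqrt(2 * np.pi))
        return y * self.total_area_s

    def fragments(self, k: int) -> List[Tuple[float, float]]:
        """Product-ion list for MS3 of the M+k precursor."""
        frags = list(FRAGMENT_LIBRARY.get(self.sp.id, ()))
        generic = (self.channel_mz[k] - self.pyloss - _H2O_MASS, 0.6)
        return frags + [generic]


def simulate_chromatogram(
    truth: GroundTruth,
    instrument: Optional[InstrumentModel] = None,
    seed: int = 0,
    registry: Optional[Registry] = None,
) -> SimulatedRun:
    """Render the workup amounts into centroided MS1 + MS3 scans."""
    registry = registry or build_default_registry()
    instrument = instrument or InstrumentModel()
    rng = np.random.default_rng(seed)

    emitters: List[_Emitter] = []
    for sid, fracs in sorted(truth.fraction_amounts_ng.items()):
        sp = registry.lookup(sid)
        for fraction in (Fraction.A, Fraction.B):
            ng = fracs.get(fraction.value, 0.0)
            if ng > 0:
                emitters.append(_Emitter(sp, fraction, ng, instrument, rng))

    dt_s = 1.0 / instrument.ms1_hz
    times_min = np.arange(0.0, instrument.gradient_min * 60.0 + dt_s, dt_s) / 60.0

    # channel list for baseline noise
    noise_channels = sorted({m for e in emitters for m in e.channel_mz})

    # precompute MS1 profiles
    profiles = [e.ms1_intensity(times_min) for e in emitters]

    scans: List[Scan] = []
    for i, t in enumerate(times_min):
        mzs: List[float] = []
        intens: List[float] = []
        for e, prof in zip(emitters, profiles):
            base = prof[i]
            if base <= 0 or base * max(e.rel) < 1e-12:
                continue
            for mz_k, rel_k in zip(e.channel_mz, e.rel):
                v = base * rel_k
                if v > 1e-9:
                    mzs.append(mz_k)
                    intens.append(v)
        mz_arr, i_arr = _merge_centroids(
            np.asarray(mzs), np.asarray(intens), instrument.resolving_power
        )
        if instrument.noise_sd > 0:
            present = {round(m, 3) for m in mz_arr}
            extra_mz = [m for m in noise_channels if round(m, 3) not in present]
            mz_arr = np.concatenate([mz_arr, extra_mz]) if extra_mz else mz_arr
            i_arr = np.concatenate(
                [i_arr, np.zeros(len(extra_mz))]
            ) if extra_mz else i_arr
            i_arr = np.clip(i_arr + rng.normal(0, instrument.noise_sd, len(i_arr)), 0, None)
            keep = i_arr > 0
            mz_arr, i_arr = mz_arr[keep], i_arr[keep]
        scans.append(Scan(float(t), 1, (), mz_arr, i_arr))

    # MS3 scheduling: one scan per unique (rounded) precursor path per cycle
    paths: Dict[Tuple[float, float], Tuple[float, float]] = {}
    for e in emitters:
        p = transition_path(e.sp, e.fraction, e.gp)
        key = (round(p.levels[0], 1), round(p.levels[1], 1))
        paths.setdefault(key, (p.levels[0], p.levels[1]))
    ms3_times = np.arange(0.0, instrument.gradient_min * 60.0, instrument.ms3_period_s) / 60.0
    ms1_at_ms3 = {id(e): e.ms1_intensity(ms3_times) for e in emitters}
    for key, (l1, l2) in sorted(paths.items()):
        # precursor-chain matching: which (emitter, isotopologue) pairs are
        # co-isolated with this path at both MSn selection stages
        members = []
        for e in emitters:
            for k, (mz_k, rel_k) in enumerate(zip(e.channel_mz, e.rel)):
                if abs(mz_k - l1) > 0.3:
                    continue
                if abs((mz_k - e.pyloss) - l2) > 0.3:
                    continue
                members.append((e, k, rel_k, e.fragments(k)))
        if not members:
            continue
        for i, t in enumerate(ms3_times):
            mzs, intens = [], []
            for e, k, rel_k, frags in members:
                base = ms1_at_ms3[id(e)][i]
                if base < 1e-9:
                    continue
                level = base * rel_k * instrument.ms3_yield
                for fmz, ri in frags:
                    mzs.append(fmz)
                    intens.append(level * ri)
            if not mzs:
                continue
            mz_arr = np.asarray(mzs)
            i_arr = np.asarray(intens)
            if instrument.noise_sd > 0:
                i_arr = np.clip(
                    i_arr + rng.normal(0, instrument.noise_sd * instrument.ms3_yield, len(i_arr)),
                    0, None,
                )
            order = np.argsort(mz_arr)
            scans.append(Scan(float(t), 3, (l1, l2), mz_arr[order], i_arr[order]))

    scans.sort(key=lambda s: (s.time_min, s.ms_level, s.precursors))
    return SimulatedRun(scans, truth, seed, instrument)


def simulate_run(
    state: TrueSampleState,
    mix_volume_ml: float = 0.05,
    hydrolysed: bool = False,
    seed: int = 0,
    instrument: Optional[InstrumentModel] = None,
    registry: Optional[Registry] = None,
    ledger: Optional[StandardMixLedger] = None,
    base_loss_fraction: float = 0.2,
    analyte_recovery: float = 1.0,
) -> SimulatedRun:
    """Workup + acquisition in one call (both stages share the seed)."""
    registry = registry or build_default_registry()
    truth = simulate_workup(
        state, mix_volume_ml, hydrolysed, seed=seed,
        registry=registry, ledger=ledger, base_loss_fraction=base_loss_fraction,
        analyte_recovery=analyte_recovery,
    )
    run = simulate_chromatogram(truth, instrument, seed=seed + 1, registry=registry)
    run.seed = seed
    return run


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def _srm1950_like() -> TrueSampleState:
    free = {
        "24S-HC": 15.0, "24R-HC": 0.4, "25-HC": 1.2, "26R-HC": 26.0,
        "7a-HC": 24.0, "7b-HC": 3.0, "4b-HC": 8.0, "22R-HC": 0.0,
        "7-OC": 4.0, "7a-HCO": 25.0, "5a6b-diHC": 5.0,
        "7a25-diHC": 0.07, "7a26-diHC": 0.15,
        "7a25-diHCO": 0.4, "7a26-diHCO": 1.0,
        "7aH3OCA-25R": 40.0, "7aH3OCA-25S": 7.0,
        "3b7a-diHCA-25R": 15.0, "3b7a-diHCA-25S": 5.0,
        "3b7b-diHCA-25R": 3.5, "3b7b-diHCA-25S": 0.5,
        "3b-HCA": 10.0, "3O-CA": 1.0,
        "7a12a-diHC": 0.5, "7a12a-diHCO": 1.5, "diHC-unk1": 0.3,
        "7a24-diH3OCA": 1.0, "7a25-diH3OCA": 1.5,
        "3b7a24-triHCA": 0.3, "3b7a25-triHCA": 0.4,
        "cholesterol": 385000.0,
    }
    esterified = {
        "24S-HC": 45.0, "24R-HC": 1.2, "25-HC": 2.8, "26R-HC": 134.0,
        "7a-HC": 96.0, "7b-HC": 5.0, "4b-HC": 22.0,
        "7-OC": 6.0, "5a6b-diHC": 7.0,
        "7a25-diHC": 0.23, "7a26-diHC": 0.45,
        "3b7a-diHCA-25R": 2.0, "3b7a-diHCA-25S": 0.7,
        "3b7b-diHCA-25R": 1.0, "3b7b-diHCA-25S": 0.2,
        "7a12a-diHC": 1.0, "diHC-unk1": 0.5,
        "cholesterol": 1156000.0,
    }
    return TrueSampleState("plasma", 0.1, free, esterified)


def scenario_preset(name: str, autoxidation: bool = False) -> TrueSampleState:
    """Study-condition presets.

    ``SRM1950_like``: pooled-plasma order-of-magnitude concentrations.
    ``CSF_QC_like``: cerebrospinal fluid with abundant cholestenoic acids and
    sub-ng/mL free oxysterols.  ``ACOX2``: the C27-acid 25S epimers exceed
    the 25R epimers (loss of peroxisomal 25S-specific oxidation).  ``CTX``:
    (25R)26-HC absent and 7α-HCO elevated (CYP27A1 deficiency).
    """
    if name == "SRM1950_like":
        state = _srm1950_like()
    elif name == "CSF_QC_like":
        free = {
            "7aH3OCA-25R": 12.0, "7aH3OCA-25S": 8.0,
            "3b7a-diHCA-25R": 2.0, "3b7a-diHCA-25S": 1.0,
            "3b-HCA": 1.5, "3O-CA": 0.2,
            "7a24-diH3OCA": 1.2, "7a25-diH3OCA": 2.0,
            "24S-HC": 0.3, "25-HC": 0.02, "26R-HC": 0.15,
            "7a25-diHC": 0.01, "7a26-diHC": 0.02,
            "cholesterol": 1200.0,
        }
        esterified = {
            "24S-HC": 1.2, "25-HC": 0.08, "26R-HC": 0.85,
            "7a25-diHC": 0.04, "7a26-diHC": 0.08,
            "cholesterol": 2800.0,
        }
        state = TrueSampleState("CSF", 0.1, free, esterified)
    elif name == "ACOX2":
        state = _srm1950_like()
        state.free_ng_per_ml.update({
            "7aH3OCA-25R": 10.0, "7aH3OCA-25S": 30.0,
            "3b7a-diHCA-25R": 4.0, "3b7a-diHCA-25S": 12.0,
            "3b7b-diHCA-25R": 2.0, "3b7b-diHCA-25S": 1.0,
        })
    elif name == "CTX":
        state = _srm1950_like()
        state.free_ng_per_ml.update({
            "26R-HC": 0.0, "7a-HCO": 120.0, "24R-HC": 1.5,
            "7aH3OCA-25R": 20.0, "7aH3OCA-25S": 20.0,
        })
        state.esterified_ng_per_ml["26R-HC"] = 0.0
    else:
        raise ValueError(f"unknown scenario preset: {name}")
    if autoxidation:
        state.autoxidation_max_ng_per_ml = {
            "7a-HC": 2.0, "7b-HC": 1.5, "7-OC": 2.0, "5a6b-diHC": 1.5,
        }
    return copy.deepcopy(state)
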