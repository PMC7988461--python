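"""Isotope-dilution quantification and fraction A/B deconvolution.

The quantification model is a single linear relation between area ratio and
concentration ratio,

    PA_u / PA_l = (Rf_u / Rf_l) · (C_u / C_l) + constant,

where ``u`` is the endogenous (unlabelled) analyte, ``l`` the co-processed
isotope-labelled standard of known amount, and Rf the response factors
(assumed equal for an exact isotopologue pair).  Single-point mode sets the
constant to zero and inverts the relation directly; standard-addition mode
fits slope and intercept over spiked levels and reads the endogenous
concentration off the x-intercept.

Fraction bookkeeping: sterols with a native 3-oxo-4-ene (or 7-oxo) group are
quantified from fraction B; species carrying only the 3β-hydroxy-5-ene
function appear exclusively in fraction A; redox pairs that share a
fraction-A derivative (e.g. 7α-HC and 7α-HCO) are deconvolved as
hydroxy = A − B, oxo = B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .extract import PeakMeasurement, correct_m1_interference, m1_fraction
from .registry import Fraction, Registry, SterolSpecies, Tier, build_default_registry


class QuantError(ValueError):
    pass


class CalibrationError(QuantError):
    pass


@dataclass
class QuantModel:
    """Terms of the area-ratio / concentration-ratio relation."""

    pa_unlabeled: float
    pa_labeled: float
    conc_labeled: float = 0.0
    rf_ratio: float = 1.0
    constant: float = 0.0
    slope: float = 0.0

    def __post_init__(self) -> None:
        if self.rf_ratio <= 0:
            raise QuantError("rf_ratio must be positive")


@dataclass
class QuantResult:
    analyte_id: str
    conc_ng_per_ml: Optional[float]
    tier: Tier
    basis: str                       # fraction_B | A_minus_B | A_only | none
    flags: Set[str] = field(default_factory=set)
    surrogate_id: Optional[str] = None
    conc_A: Optional[float] = None
    conc_B: Optional[float] = None


def quant_single_point(
    model: QuantModel, standard_amount_ng: float, sample_volume_ml: float
) -> float:
    """Endogenous concentration (ng/mL) from one area ratio.

    conc = (PA_u / PA_l) / rf_ratio × amount_standard / V_sample.  The
    constant of the linear relation is taken as zero: in a plain sample
    there is no spiked offset to absorb.
    """
    if model.pa_labeled <= 0:
        raise QuantError("no internal standard signal (PA_labeled = 0)")
    if sample_volume_ml <= 0:
        raise QuantError("sample volume must be positive")
    ratio = model.pa_unlabeled / model.pa_labeled
    return ratio / model.rf_ratio * standard_amount_ng / sample_volume_ml


def deconvolve_AB(
    conc_A: Optional[float],
    conc_B: Optional[float],
    species: SterolSpecies,
) -> Tuple[float, float, str, Set[str]]:
    """Split fraction totals into hydroxy (A−B) and oxo (B) forms.

    Species without any 3-oxo analogue are taken from fraction A alone;
    7-oxo species from fraction B alone.  A negative A−B difference is
    clipped to zero and flagged rather than reported negative.
    """
    flags: Set[str] = set()
    if species.has_7oxo:
        if conc_B is None:
            raise QuantError(f"{species.id}: fraction B required")
        return 0.0, conc_B, "fraction_B", flags
    if species.has_native_3oxo_4ene:
        if conc_B is None:
            raise QuantError(f"{species.id}: fraction B required")
        return 0.0, conc_B, "fraction_B", flags
    if conc_A is None:
        raise QuantError(f"{species.id}: fraction A required")
    if species.oxo_partner_id is None:
        return conc_A, 0.0, "A_only", flags
    if conc_B is None:
        raise QuantError(f"{species.id}: fraction B of {species.oxo_partner_id} required")
    hydroxy = conc_A - conc_B
    if hydroxy < 0:
        hydroxy = 0.0
        flags.add("clipped_negative")
    return hydroxy, conc_B, "A_minus_B", flags


def split_shared_standard(
    combined_conc: float, component_fractions: Sequence[float]
) -> List[float]:
    """Partition a certified epimer-mixture concentration by area fraction.

    Assumes identical response factors for the components (chromatographic
    epimers of one compound); fractions must sum to 1.
    """
    total = float(np.sum(component_fractions))
    if abs(total - 1.0) > 1e-6:
        raise QuantError(f"component fractions sum to {total}, not 1")
    return [combined_conc * f for f in component_fractions]


def standard_addition_fit(
    added_concs: Sequence[float], pa_ratios: Sequence[float]
) -> Tuple[float, float, float, float]:
    """OLS of area ratio on added concentration.

    Returns (slope, intercept, endogenous_conc, R²).  With a constant
    internal-standard amount the x-intercept of the line is minus the
    endogenous concentration, so endogenous = intercept / slope.
    """
    x = np.asarray(added_concs, float)
    y = np.asarray(pa_ratios, float)
    if len(np.unique(x)) < 3:
        raise CalibrationError("need at least 3 distinct addition levels")
    if x.shape != y.shape:
        raise CalibrationError("levels and ratios differ in length")
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise CalibrationError("non-positive calibration slope")
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    endogenous = intercept / slope
    return float(slope), float(intercept), float(endogenous), float(r2)


def percent_free(free_conc: float, total_conc: float) -> float:
    """100 × free/total; may exceed 100 (flagged downstream) when the
    hydrolysis correction is imperfect."""
    if total_conc <= 0:
        raise QuantError("total concentration must be positive")
    return 100.0 * free_conc / total_conc


# ---------------------------------------------------------------------------
# run-level quantification
# ---------------------------------------------------------------------------

@dataclass
class SurrogateAssignment:
    """How one analyte maps onto internal standards, per fraction.

    ``standards_A``/``standards_B`` list the standard species whose signals
    co-elute as one peak in that fraction (e.g. [2H7]7α-HC and [2H7]7α-HCO
    are indistinguishable after oxidase treatment, so the fraction-A
    standard amount is their sum).
    """

    analyte_id: str
    tier: Tier
    standards_A: List[str] = field(default_factory=list)
    standards_B: List[str] = field(default_factory=list)


def default_surrogate_map(registry: Optional[Registry] = None) -> Dict[str, SurrogateAssignment]:
    registry = registry or build_default_registry()
    out: Dict[str, SurrogateAssignment] = {}
    for sp in registry.analytes():
        if sp.tier is Tier.IDENTIFIED_ONLY or sp.surrogate_standard_id is None:
            out[sp.id] = SurrogateAssignment(sp.id, Tier.IDENTIFIED_ONLY)
            continue
        std = registry.lookup(sp.surrogate_standard_id)
        asn = SurrogateAssignment(sp.id, sp.tier)
        # fraction A group: own surrogate plus the partner's surrogate when
        # the two standards merge into one fraction-A peak
        group = [std.id]
        if sp.oxo_partner_id is not None:
            partner = registry.lookup(sp.oxo_partner_id)
            pstd_id = partner.surrogate_standard_id
            if pstd_id and pstd_id != std.id and pstd_id in registry:
                pstd = registry.lookup(pstd_id)
                same_rt = (
                    std.nominal_rt_min is not None
                    and pstd.nominal_rt_min is not None
                    and abs(std.nominal_rt_min - pstd.nominal_rt_min) < 1e-9
                )
                if same_rt and pstd.derivatized_in(Fraction.A):
                    group.append(pstd.id)
        asn.standards_A = group if std.derivatized_in(Fraction.A) else []
        if std.derivatized_in(Fraction.B):
            asn.standards_B = [std.id]
        out[sp.id] = asn
    return out


def _meas_lookup(measurements: pd.DataFrame):
    table: Dict[Tuple[str, str, str], Tuple[float, Set[str]]] = {}
    for _, row in measurements.iterrows():
        flags = set(str(row.get("flags", "")).split(";")) - {"", "nan"}
        table[(row["species_id"], row["fraction"], row["channel"])] = (
            float(row["area"]), flags
        )
    return table


#: Default algebraic M+1 corrections: (target, donor, fraction).  Order
#: matters — the donor must itself be corrected first when it is also a
#: target (the [2H5] impurity inflates the [2H6] standard, whose M+1 in turn
#: sits under the [2H7]24R channel).
DEFAULT_M1_CORRECTIONS: List[Tuple[str, str, str]] = [
    ("[2H6]26R-HC", "[2H5]26R-HC", "A"),
    ("[2H7]24R-HC", "[2H6]26R-HC", "A"),
]


def apply_m1_corrections(
    table: Dict[Tuple[str, str, str], Tuple[float, Set[str]]],
    corrections: Iterable[Tuple[str, str, str]] = DEFAULT_M1_CORRECTIONS,
    carbon_count: int = 34,
    p13c: float = 0.0107,
) -> None:
    """In-place M+1 subtraction on the RIC areas of a measurement table."""
    for target_id, donor_id, fraction in corrections:
        tkey = (target_id, fraction, "RIC")
        dkey = (donor_id, fraction, "RIC")
        if tkey not in table or dkey not in table:
            continue
        t_area, t_flags = table[tkey]
        d_area, _ = table[dkey]
        target = PeakMeasurement(target_id, fraction, t_area, 0.0, 1, "RIC", t_flags)
        donor = PeakMeasurement(donor_id, fraction, d_area, 0.0, 1, "RIC")
        corrected = correct_m1_interference(target, donor, carbon_count, p13c)
        table[tkey] = (corrected.area, set(corrected.flags))


def quantify_run(
    measurements: pd.DataFrame,
    standard_amounts_ng: Mapping[str, float],
    sample_volume_ml: float,
    registry: Optional[Registry] = None,
    surrogate_map: Optional[Dict[str, SurrogateAssignment]] = None,
    hydrolysed: bool = False,
    rf_ratios: Optional[Mapping[str, float]] = None,
    m1_corrections: Iterable[Tuple[str, str, str]] = DEFAULT_M1_CORRECTIONS,
    p13c: float = 0.0107,
) -> pd.DataFrame:
    """Tier-aware single-point quantification of an extracted run.

    For each mapped analyte the per-fraction concentration is computed
    against its surrogate standard group, the A/B deconvolution applied, and
    tier plus quality flags attached.  The MRM channel replaces the RIC for
    a pair when either side prefers it or the RIC is coelution-flagged and a
    diagnostic fragment is available for both analyte and standard.
    """
    registry = registry or build_default_registry()
    surrogate_map = surrogate_map or default_surrogate_map(registry)
    rf_ratios = rf_ratios or {}
    table = _meas_lookup(measurements)
    apply_m1_corrections(table, m1_corrections, p13c=p13c)

    def area(sid: str, fraction: str, channel: str):
        return table.get((sid, fraction, channel))

    def conc_in_fraction(analyte: SterolSpecies, fraction: str,
                         std_ids: List[str]) -> Tuple[Optional[float], Set[str]]:
        flags: Set[str] = set()
        if not std_ids:
            return None, flags
        std0 = registry.lookup(std_ids[0])
        std_fraction = fraction if all(
            registry.lookup(s).derivatized_in(fraction) for s in std_ids
        ) else "A"
        # channel choice: MRM when preferred/needed and available both sides
        channel = "RIC"
        a_ric = area(analyte.id, fraction, "RIC")
        s_ric = area(std0.id, std_fraction, "RIC")
        want_mrm = analyte.prefer_mrm or std0.prefer_mrm
        if not want_mrm:
            for m in (a_ric, s_ric):
                if m is not None and "coelution" in m[1]:
                    want_mrm = True
        if want_mrm:
            a_mrm = area(analyte.id, fraction, "MRM")
            s_mrm = area(std0.id, std_fraction, "MRM")
            if a_mrm is not None and s_mrm is not None:
                channel = "MRM"
        a_meas = area(analyte.id, fraction, channel)
        s_meas = area(std0.id, std_fraction, channel)
        if s_meas is None or s_meas[0] <= 0:
            raise QuantError(
                f"{analyte.id}: no internal standard signal for {std0.id} "
                f"in fraction {std_fraction}"
            )
        amount = sum(standard_amounts_ng.get(s, 0.0) for s in std_ids)
        if amount <= 0:
            raise QuantError(f"{analyte.id}: zero standard amount for {std_ids}")
        pa_u = a_meas[0] if a_meas is not None else 0.0
        if a_meas is not None:
            flags |= a_meas[1]
        flags |= {f for f in s_meas[1] if f == "m1_interference_corrected"}
        if channel == "MRM":
            flags.add("mrm_quantified")
        rf = rf_ratios.get(analyte.id, 1.0)
        model = QuantModel(pa_unlabeled=pa_u, pa_labeled=s_meas[0], rf_ratio=rf)
        return quant_single_point(model, amount, sample_volume_ml), flags

    rows: List[QuantResult] = []
    for sp in registry.analytes():
        if sp.nominal_rt_min is None or not sp.derivatizable:
            continue
        asn = surrogate_map.get(sp.id)
        if asn is None or asn.tier is Tier.IDENTIFIED_ONLY:
            rows.append(QuantResult(sp.id, None, Tier.IDENTIFIED_ONLY, "none"))
            continue
        flags: Set[str] = set()
        conc_A = conc_B = None
        if sp.derivatized_in(Fraction.A) and asn.standards_A:
            conc_A, fl = conc_in_fraction(sp, "A", asn.standards_A)
            flags |= fl
        if sp.derivatized_in(Fraction.B):
            std_B = asn.standards_B or asn.standards_A
            conc_B, fl = conc_in_fraction(sp, "B", std_B)
            flags |= fl
        elif sp.oxo_partner_id is not None:
            partner = registry.lookup(sp.oxo_partner_id)
            pasn = surrogate_map.get(partner.id)
            if pasn is not None:
                std_B = pasn.standards_B or pasn.standards_A
                conc_B, fl = conc_in_fraction(partner, "B", std_B)
                flags |= fl
        hydroxy, oxo, basis, dflags = deconvolve_AB(conc_A, conc_B, sp)
        flags |= dflags
        conc = oxo if basis == "fraction_B" else hydroxy
        if sp.autoxidation_prone:
            flags.add("autoxidation_prone")
        if hydrolysed and asn.tier is not Tier.ABSOLUTE:
            std_ids = asn.standards_A or asn.standards_B
            std_7oh = any(
                registry.lookup(s).has_7_hydroxy for s in std_ids
            ) if std_ids else False
            # base-catalysed dehydration of 7-hydroxy skeletons is only
            # cancelled by an exact isotope surrogate; a redox/7-OH mismatch
            # between analyte and surrogate leaves the loss uncorrected
            if sp.has_7_hydroxy or std_7oh:
                flags.add("degradation_uncorrected")
        rows.append(QuantResult(
            sp.id, conc, asn.tier, basis, flags,
            surrogate_id=(asn.standards_A or asn.standards_B or [None])[0],
            conc_A=conc_A, conc_B=conc_B,
        ))

    return pd.DataFrame([
        {
            "analyte": r.analyte_id,
            "tier": r.tier.value,
            "basis": r.basis,
            "conc_ng_per_ml": r.conc_ng_per_ml,
            "conc_A": r.conc_A,
            "conc_B": r.conc_B,
            "surrogate": r.surrogate_id,
            "flags": ";".join(sorted(r.flags)),
        }
        for r in rows
    ])


def free_total_report(
    free_run: pd.DataFrame, total_run: pd.DataFrame
) -> pd.DataFrame:
    """Merge non-hydrolysed and hydrolysed quantification into one table
    with percent free (flagged when it exceeds 100%)."""
    f = free_run.set_index("analyte")
    t = total_run.set_index("analyte")
    rows = []
    for analyte in f.index:
        free = f.loc[analyte, "conc_ng_per_ml"]
        total = t.loc[analyte, "conc_ng_per_ml"] if analyte in t.index else None
        pct = None
        flags = set(str(f.loc[analyte, "flags"]).split(";")) - {"", "nan"}
        if total is not None and pd.notna(total) and total > 0 and pd.notna(free):
            pct = percent_free(free, total)
            if pct > 100.0:
                flags.add("free_exceeds_total")
        rows.append({
            "analyte": analyte,
            "tier": f.loc[analyte, "tier"],
            "basis": f.loc[analyte, "basis"],
            "free_ng_per_ml": free,
            "total_ng_per_ml": total,
            "pct_free": pct,
            "flags": ";".join(sorted(flags)),
        })
    return pd.DataFrame(rows)
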