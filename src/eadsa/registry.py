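"""Sterol species registry and Girard-P derivative mass calculus.

The registry is the chemical bookkeeping layer of the pipeline: every sterol,
oxysterol and cholestenoic acid the assay targets is registered with its
intact molecular formula, its functional-group flags (which decide whether it
is charge-tagged in fraction A, fraction B, or both), its deuterium label
count, its quantification tier and its surrogate internal standard.

Fraction logic
--------------
Samples are split and derivatised twice: in fraction A cholesterol oxidase
first converts 3β-hydroxy-5-ene groups to 3-oxo-4-enes and the [2H5]GP reagent
tags every resulting (or native) oxo group; in fraction B no oxidase is used,
so only sterols carrying a native 3-oxo-4-ene or a 7-oxo group are tagged,
with [2H0]GP.  Subtracting fraction-B from fraction-A quantities therefore
isolates the sterols that originally carried the 3β-hydroxy-5-ene function.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Optional

import yaml

from .elements import (
    DEFAULT_MASSES,
    H2,
    H2O,
    ElementMassTable,
    MolecularFormula,
    monoisotopic_mz,
    neutral_mass,
)


class NonDerivatizableError(ValueError):
    """Species carries neither a 3β-hydroxy-5-ene nor any oxo group."""


class NotDerivatizedInFractionB(ValueError):
    """Species needs cholesterol oxidase, so it is absent from fraction B."""


class RegistryError(KeyError):
    pass


class Fraction(str, Enum):
    A = "A"
    B = "B"


class Tier(str, Enum):
    ABSOLUTE = "absolute"
    SEMI = "semi"
    APPROXIMATE = "approximate"
    IDENTIFIED_ONLY = "identified_only"


@dataclass(frozen=True)
class GPVariant:
    """A Girard-P charge-tagging reagent (pyridinium acetohydrazide).

    The hydrazide condenses with a ketone, losing water, and leaves a fixed
    positive charge.  The deuterated variant carries its five deuteriums on
    the pyridine ring, so the characteristic MSn neutral loss is
    [2H5]-pyridine rather than pyridine.
    """

    label: str
    reagent_cation: MolecularFormula
    pyridine_loss: MolecularFormula

    def pyridine_loss_mass(self, table: ElementMassTable = DEFAULT_MASSES) -> float:
        return neutral_mass(self.pyridine_loss, table)


GP_2H0 = GPVariant(
    "GP_2H0",
    MolecularFormula({"C": 7, "H": 10, "N": 3, "O": 1}, charge=+1),
    MolecularFormula({"C": 5, "H": 5, "N": 1}),
)
GP_2H5 = GPVariant(
    "GP_2H5",
    MolecularFormula({"C": 7, "H": 5, "2H": 5, "N": 3, "O": 1}, charge=+1),
    MolecularFormula({"C": 5, "2H": 5, "N": 1}),
)

#: Reagent used per fraction in the standard workflow.
GP_FOR_FRACTION: Dict[Fraction, GPVariant] = {Fraction.A: GP_2H5, Fraction.B: GP_2H0}

GP_VARIANTS = {"GP_2H0": GP_2H0, "GP_2H5": GP_2H5}


@dataclass(frozen=True)
class SterolSpecies:
    """One registered sterol/oxysterol/cholestenoic-acid species.

    ``has_3b_hydroxy_5ene``, ``has_native_3oxo_4ene`` and ``has_7oxo`` are the
    flags that drive fraction membership; exactly one of them must be set for
    a derivatizable species.  ``oxo_partner_id`` links a 3β-hydroxy-5-ene
    species to the 3-oxo-4-ene species that shares its fraction-A derivative
    (e.g. 7α-HC ↔ 7α-HCO), which is what makes the A−B deconvolution work.
    """

    id: str
    name: str
    intact_formula: MolecularFormula
    family: str = "other"
    has_3b_hydroxy_5ene: bool = False
    has_native_3oxo_4ene: bool = False
    has_7oxo: bool = False
    dehydrates_on_derivatization: bool = False
    has_7_hydroxy: bool = False
    esterifiable: bool = False
    autoxidation_prone: bool = False
    label_count: int = 0
    nominal_rt_min: Optional[float] = None
    tier: Tier = Tier.ABSOLUTE
    surrogate_standard_id: Optional[str] = None
    oxo_partner_id: Optional[str] = None
    mix_conc_ng_per_ml: Optional[float] = None
    parent_standard_id: Optional[str] = None
    epimer_fraction: float = 1.0
    #: quantify on the diagnostic-fragment MRM channel rather than the RIC
    #: (the rescue for species that co-elute with a mass-unresolved isomer)
    prefer_mrm: bool = False
    systematic_name: str = ""

    def __post_init__(self) -> None:
        flags = [self.has_3b_hydroxy_5ene, self.has_native_3oxo_4ene, self.has_7oxo]
        if sum(flags) > 1:
            raise ValueError(
                f"{self.id}: exactly one fraction-membership flag may be set"
            )
        if self.label_count > self.intact_formula.deuterium_count:
            raise ValueError(f"{self.id}: label_count exceeds deuterium in formula")

    @property
    def is_standard(self) -> bool:
        return self.label_count > 0

    @property
    def derivatizable(self) -> bool:
        return self.has_3b_hydroxy_5ene or self.has_native_3oxo_4ene or self.has_7oxo

    def derivatized_in(self, fraction: Fraction | str) -> bool:
        fraction = Fraction(fraction)
        if fraction is Fraction.A:
            return self.derivatizable
        return self.has_native_3oxo_4ene or self.has_7oxo


@dataclass(frozen=True)
class DerivativeIon:
    species_id: str
    oxidase_applied: bool
    gp: GPVariant
    ion_formula: MolecularFormula
    isotopologue_k: int
    mz: float


@dataclass(frozen=True)
class TransitionPath:
    """Precursor → [M−Py]+ → (optional diagnostic fragment) m/z ladder."""

    levels: tuple
    diagnostic_fragment_source: str = "none"

    def display(self) -> str:
        s = f"{self.levels[0]:.1f} → {self.levels[1]:.1f}→"
        if len(self.levels) > 2:
            s += f"{self.levels[2]:.1f}"
        return s


#: Static diagnostic MS3 fragment library (m/z, relative intensity).  These
#: are taken from characterised fragmentation of the GP hydrazones; they are
#: looked up, never predicted.  The first entry is the diagnostic fragment
#: used as the third MRM level.
FRAGMENT_LIBRARY: Dict[str, List[tuple]] = {
    "24S-HC": [(353.3, 1.0)],
    "24R-HC": [(353.3, 1.0)],
    "[2H7]24S-HC": [(353.3, 1.0)],
    "[2H7]24R-HC": [(353.3, 1.0)],
    "22R-HCO": [(353.3, 0.8)],
    "[2H7]22S-HCO": [(353.3, 0.8)],
    "7a24-diH3OCA": [(427.3, 1.0)],
    "7a25-diH3OCA": [(455.3, 1.0)],
}

#: Match tolerance for library fragments (ion-trap, 1-decimal notation).
FRAGMENT_TOL = 0.3


def compose_derivative(
    species: SterolSpecies, oxidase_applied: bool, gp: GPVariant
) -> MolecularFormula:
    """Formula of the GP-hydrazone cation of *species*.

    Cholesterol oxidase removes H2 when it converts a 3β-hydroxy-5-ene to a
    3-oxo-4-ene; cholestane-3β,5α,6β-triol additionally loses water during
    derivatisation; hydrazone condensation with the GP cation loses one more
    water.  Without oxidase only species with a native oxo group react.
    """
    if not species.derivatizable:
        raise NonDerivatizableError(
            f"{species.id} has neither a 3β-hydroxy-5-ene nor an oxo group"
        )
    if not oxidase_applied and not (
        species.has_native_3oxo_4ene or species.has_7oxo
    ):
        raise NotDerivatizedInFractionB(
            f"{species.id} not derivatized in fraction B (no oxo group)"
        )
    f = species.intact_formula
    if oxidase_applied and species.has_3b_hydroxy_5ene:
        f = f - H2
    if species.dehydrates_on_derivatization:
        f = f - H2O
    f = f + gp.reagent_cation
    f = f - H2O
    return f


def derivative_ion(
    species: SterolSpecies,
    fraction: Fraction | str,
    gp: GPVariant | None = None,
    isotopologue_k: int = 0,
    table: ElementMassTable = DEFAULT_MASSES,
) -> DerivativeIon:
    fraction = Fraction(fraction)
    if gp is None:
        gp = GP_FOR_FRACTION[fraction]
    oxidase = fraction is Fraction.A
    formula = compose_derivative(species, oxidase, gp)
    mz = monoisotopic_mz(formula, isotopologue_k, table)
    return DerivativeIon(species.id, oxidase, gp, formula, isotopologue_k, mz)


def transition_path(
    species: SterolSpecies,
    fraction: Fraction | str,
    gp: GPVariant | None = None,
    table: ElementMassTable = DEFAULT_MASSES,
) -> TransitionPath:
    """MSn path [M]+ → [M−Py]+ → diagnostic fragment (if the library has one)."""
    fraction = Fraction(fraction)
    if gp is None:
        gp = GP_FOR_FRACTION[fraction]
    ion = derivative_ion(species, fraction, gp, 0, table)
    level2 = ion.mz - gp.pyridine_loss_mass(table)
    frags = FRAGMENT_LIBRARY.get(species.id)
    if frags:
        return TransitionPath((ion.mz, level2, frags[0][0]), "library")
    return TransitionPath((ion.mz, level2), "none")


class Registry:
    """Keyed collection of :class:`SterolSpecies` with duplicate protection."""

    def __init__(self, species: Iterable[SterolSpecies] = ()) -> None:
        self._species: Dict[str, SterolSpecies] = {}
        for sp in species:
            self.add(sp)

    def add(self, sp: SterolSpecies) -> None:
        if sp.id in self._species:
            raise RegistryError(f"duplicate species id: {sp.id}")
        self._species[sp.id] = sp

    def lookup(self, species_id: str) -> SterolSpecies:
        try:
            return self._species[species_id]
        except KeyError:
            raise RegistryError(f"unknown species: {species_id}") from None

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._species

    def __iter__(self):
        return iter(self._species.values())

    def __len__(self) -> int:
        return len(self._species)

    def ids(self) -> List[str]:
        return list(self._species)

    def analytes(self) -> List[SterolSpecies]:
        return [s for s in self if not s.is_standard]

    def standards(self) -> List[SterolSpecies]:
        return [s for s in self if s.is_standard]

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        records = []
        for sp in self:
            rec = {
                "id": sp.id,
                "name": sp.name,
                "formula": sp.intact_formula.hill(),
                "family": sp.family,
                "flags": {
                    "3b_hydroxy_5ene": sp.has_3b_hydroxy_5ene,
                    "native_3oxo_4ene": sp.has_native_3oxo_4ene,
                    "7oxo": sp.has_7oxo,
                    "dehydrates": sp.dehydrates_on_derivatization,
                    "7_hydroxy": sp.has_7_hydroxy,
                    "esterifiable": sp.esterifiable,
                    "autoxidation_prone": sp.autoxidation_prone,
                },
                "label_count": sp.label_count,
                "rt_min": sp.nominal_rt_min,
                "tier": sp.tier.value,
                "surrogate": sp.surrogate_standard_id,
                "oxo_partner": sp.oxo_partner_id,
                "mix_conc_ng_per_ml": sp.mix_conc_ng_per_ml,
                "parent_standard": sp.parent_standard_id,
                "epimer_fraction": sp.epimer_fraction,
                "prefer_mrm": sp.prefer_mrm,
            }
            records.append(rec)
        with open(path, "w") as fh:
            yaml.safe_dump(records, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "Registry":
        with open(path) as fh:
            records = yaml.safe_load(fh)
        species = []
        for rec in records:
            flags = rec.get("flags", {})
            species.append(
                SterolSpecies(
                    id=rec["id"],
                    name=rec.get("name", rec["id"]),
                    intact_formula=MolecularFormula.parse(rec["formula"]),
                    family=rec.get("family", "other"),
                    has_3b_hydroxy_5ene=flags.get("3b_hydroxy_5ene", False),
                    has_native_3oxo_4ene=flags.get("native_3oxo_4ene", False),
                    has_7oxo=flags.get("7oxo", False),
                    dehydrates_on_derivatization=flags.get("dehydrates", False),
                    has_7_hydroxy=flags.get("7_hydroxy", False),
                    esterifiable=flags.get("esterifiable", False),
                    autoxidation_prone=flags.get("autoxidation_prone", False),
                    label_count=rec.get("label_count", 0),
                    nominal_rt_min=rec.get("rt_min"),
                    tier=Tier(rec.get("tier", "absolute")),
                    surrogate_standard_id=rec.get("surrogate"),
                    oxo_partner_id=rec.get("oxo_partner"),
                    mix_conc_ng_per_ml=rec.get("mix_conc_ng_per_ml"),
                    parent_standard_id=rec.get("parent_standard"),
                    epimer_fraction=rec.get("epimer_fraction", 1.0),
                    prefer_mrm=rec.get("prefer_mrm", False),
                )
            )
        return cls(species)


def _F(text: str) -> MolecularFormula:
    return MolecularFormula.parse(text)


#: Measured epimer area fractions of the shared [2H7]24R/S-HC standard
#: (determined once per standard lot from a standards-only run; the certified
#: 80 ng/mL splits 35.44 / 44.56 ng/mL between the 24S and 24R epimers).
D7_24S_FRACTION = 35.44 / 80.0
#: The [2H3]7αH,3O-CA standard is an R/S epimer mixture; no per-epimer split
#: is certified, so equal response and abundance are assumed.
D3_CA_25R_FRACTION = 0.5
#: [2H5](25R)26-HC impurity level relative to the [2H6] isotopologue.
D5_IMPURITY_FRACTION = 0.15


def build_default_registry() -> Registry:
    """The assay's default species registry.

    Contains the 13 components of the commercial isotope-labelled standard
    mix (with certified ng/mL), the additional quantitative single standards,
    the plasma and CSF target analytes with their quantification tiers and
    surrogate assignments, and the [2H5](25R)26-HC impurity registered at 15%
    of the [2H6] level.  Retention times refer to the default 17-min gradient.
    """
    reg = Registry()

    def add(id, name, formula, **kw):
        reg.add(SterolSpecies(id=id, name=name, intact_formula=_F(formula), **kw))

    # --- unlabeled analytes: monohydroxycholesterols (fraction A) ----------
    monoHC = dict(
        family="monoHC", has_3b_hydroxy_5ene=True, esterifiable=True,
        surrogate_standard_id=None, tier=Tier.ABSOLUTE,
    )
    add("24S-HC", "24S-hydroxycholesterol", "C27H46O2", nominal_rt_min=6.6,
        surrogate_standard_id="[2H7]24S-HC", **{k: v for k, v in monoHC.items() if k != "surrogate_standard_id"})
    add("25-HC", "25-hydroxycholesterol", "C27H46O2", nominal_rt_min=7.1,
        surrogate_standard_id="[2H6]25-HC", **{k: v for k, v in monoHC.items() if k != "surrogate_standard_id"})
    add("24R-HC", "24R-hydroxycholesterol", "C27H46O2", nominal_rt_min=7.70,
        prefer_mrm=True,
        surrogate_standard_id="[2H7]24R-HC", **{k: v for k, v in monoHC.items() if k != "surrogate_standard_id"})
    add("26R-HC", "(25R)26-hydroxycholesterol", "C27H46O2", nominal_rt_min=7.85,
        systematic_name="(25R)-cholest-5-ene-3β,26-diol",
        surrogate_standard_id="[2H6]26R-HC", **{k: v for k, v in monoHC.items() if k != "surrogate_standard_id"})
    add("22R-HC", "22R-hydroxycholesterol", "C27H46O2", nominal_rt_min=6.1,
        surrogate_standard_id="[2H7]22R-HC", **{k: v for k, v in monoHC.items() if k != "surrogate_standard_id"})
    add("4b-HC", "4β-hydroxycholesterol", "C27H46O2", nominal_rt_min=10.4,
        surrogate_standard_id="[2H7]4b-HC", **{k: v for k, v in monoHC.items() if k != "surrogate_standard_id"})
    add("7a-HC", "7α-hydroxycholesterol", "C27H46O2", family="monoHC",
        has_3b_hydroxy_5ene=True, has_7_hydroxy=True, esterifiable=True,
        autoxidation_prone=True, nominal_rt_min=8.8, tier=Tier.ABSOLUTE,
        surrogate_standard_id="[2H7]7a-HC", oxo_partner_id="7a-HCO")
    add("7b-HC", "7β-hydroxycholesterol", "C27H46O2", family="monoHC",
        has_3b_hydroxy_5ene=True, has_7_hydroxy=True, esterifiable=True,
        autoxidation_prone=True, nominal_rt_min=9.4, tier=Tier.ABSOLUTE,
        surrogate_standard_id="[2H7]7b-HC")

    # --- oxo sterols (fraction B) ------------------------------------------
    add("7-OC", "7-oxocholesterol", "C27H44O2", family="HCO", has_7oxo=True,
        esterifiable=True, autoxidation_prone=True, nominal_rt_min=10.9,
        tier=Tier.ABSOLUTE, surrogate_standard_id="[2H7]7-OC")
    add("7a-HCO", "7α-hydroxycholest-4-en-3-one", "C27H44O2", family="HCO",
        has_native_3oxo_4ene=True, has_7_hydroxy=True, nominal_rt_min=8.8,
        tier=Tier.ABSOLUTE, surrogate_standard_id="[2H7]7a-HCO")
    add("22S-HCO", "22S-hydroxycholest-4-en-3-one", "C27H44O2", family="HCO",
        has_native_3oxo_4ene=True, nominal_rt_min=5.6, tier=Tier.IDENTIFIED_ONLY)
    add("22R-HCO", "22R-hydroxycholest-4-en-3-one", "C27H44O2", family="HCO",
        has_native_3oxo_4ene=True, nominal_rt_min=6.1, tier=Tier.IDENTIFIED_ONLY)

    # --- dihydroxycholesterols / dihydroxycholestenones --------------------
    add("5a6b-diHC", "cholestane-3β,5α,6β-triol", "C27H48O3",
        family="diHC", has_3b_hydroxy_5ene=True, dehydrates_on_derivatization=True,
        esterifiable=True, autoxidation_prone=True, nominal_rt_min=9.9,
        tier=Tier.ABSOLUTE, surrogate_standard_id="[2H7]5a6b-diHC")
    add("7a25-diHC", "7α,25-dihydroxycholesterol", "C27H46O3", family="diHC",
        has_3b_hydroxy_5ene=True, has_7_hydroxy=True, esterifiable=True,
        nominal_rt_min=3.6, tier=Tier.ABSOLUTE,
        surrogate_standard_id="[2H6]7a25-diHC", oxo_partner_id="7a25-diHCO")
    add("7a26-diHC", "7α,(25R/S)26-dihydroxycholesterol", "C27H46O3",
        family="diHC", has_3b_hydroxy_5ene=True, has_7_hydroxy=True,
        esterifiable=True, nominal_rt_min=4.3, tier=Tier.ABSOLUTE,
        surrogate_standard_id="[2H6]7a26-diHC", oxo_partner_id="7a26-diHCO")
    add("7a25-diHCO", "7α,25-dihydroxycholest-4-en-3-one", "C27H44O3",
        family="diHCO", has_native_3oxo_4ene=True, has_7_hydroxy=True,
        nominal_rt_min=3.6, tier=Tier.ABSOLUTE,
        surrogate_standard_id="[2H6]7a25-diHC")
    add("7a26-diHCO", "7α,(25R/S)26-dihydroxycholest-4-en-3-one", "C27H44O3",
        family="diHCO", has_native_3oxo_4ene=True, has_7_hydroxy=True,
        nominal_rt_min=4.3, tier=Tier.ABSOLUTE,
        surrogate_standard_id="[2H6]7a26-diHC")
    add("7a12a-diHC", "7α,12α-dihydroxycholesterol", "C27H46O3",
        family="diHC", has_3b_hydroxy_5ene=True, has_7_hydroxy=True,
        esterifiable=True, nominal_rt_min=5.0, tier=Tier.SEMI,
        surrogate_standard_id="[2H6]7a25-diHC", oxo_partner_id="7a12a-diHCO")
    add("7a12a-diHCO", "7α,12α-dihydroxycholest-4-en-3-one", "C27H44O3",
        family="diHCO", has_native_3oxo_4ene=True, has_7_hydroxy=True,
        nominal_rt_min=5.0, tier=Tier.SEMI, surrogate_standard_id="[2H6]7a25-diHC")
    add("diHC-unk1", "dihydroxycholesterol (presumptive)", "C27H46O3",
        family="diHC", has_3b_hydroxy_5ene=True, esterifiable=True,
        nominal_rt_min=5.8, tier=Tier.APPROXIMATE,
        surrogate_standard_id="[2H6]7a25-diHC")

    # --- cholestenoic acids -------------------------------------------------
    add("7aH3OCA-25R", "7α-hydroxy-3-oxocholest-4-en-(25R)26-oic acid",
        "C27H42O4", family="HOCA", has_native_3oxo_4ene=True, has_7_hydroxy=True,
        nominal_rt_min=4.9, tier=Tier.ABSOLUTE,
        surrogate_standard_id="[2H3]7aH3OCA-25R")
    add("7aH3OCA-25S", "7α-hydroxy-3-oxocholest-4-en-(25S)26-oic acid",
        "C27H42O4", family="HOCA", has_native_3oxo_4ene=True, has_7_hydroxy=True,
        nominal_rt_min=5.6, tier=Tier.ABSOLUTE,
        surrogate_standard_id="[2H3]7aH3OCA-25S")
    add("3b7a-diHCA-25R", "3β,7α-dihydroxycholest-5-en-(25R)26-oic acid",
        "C27H44O4", family="diHCA", has_3b_hydroxy_5ene=True, has_7_hydroxy=True,
        esterifiable=True, nominal_rt_min=4.9, tier=Tier.ABSOLUTE,
        surrogate_standard_id="[2H3]7aH3OCA-25R", oxo_partner_id="7aH3OCA-25R")
    add("3b7a-diHCA-25S", "3β,7α-dihydroxycholest-5-en-(25S)26-oic acid",
        "C27H44O4", family="diHCA", has_3b_hydroxy_5ene=True, has_7_hydroxy=True,
        esterifiable=True, nominal_rt_min=5.6, tier=Tier.ABSOLUTE,
        surrogate_standard_id="[2H3]7aH3OCA-25S", oxo_partner_id="7aH3OCA-25S")
    add("3b7b-diHCA-25R", "3β,7β-dihydroxycholest-5-en-(25R)26-oic acid",
        "C27H44O4", family="diHCA", has_3b_hydroxy_5ene=True, has_7_hydroxy=True,
        esterifiable=True, nominal_rt_min=6.3, tier=Tier.SEMI,
        surrogate_standard_id="[2H3]7aH3OCA-25R")
    add("3b7b-diHCA-25S", "3β,7β-dihydroxycholest-5-en-(25S)26-oic acid",
        "C27H44O4", family="diHCA", has_3b_hydroxy_5ene=True, has_7_hydroxy=True,
        esterifiable=True, nominal_rt_min=7.0, tier=Tier.SEMI,
        surrogate_standard_id="[2H3]7aH3OCA-25R")
    add("3b-HCA", "3β-hydroxycholest-5-en-(25R)26-oic acid", "C27H44O3",
        family="CA", has_3b_hydroxy_5ene=True, esterifiable=True,
        nominal_rt_min=6.0, tier=Tier.SEMI,
        surrogate_standard_id="[2H3]7aH3OCA-25R", oxo_partner_id="3O-CA")
    add("3O-CA", "3-oxocholest-4-en-(25R)26-oic acid", "C27H42O3", family="CA",
        has_native_3oxo_4ene=True, nominal_rt_min=6.0, tier=Tier.SEMI,
        surrogate_standard_id="[2H3]7aH3OCA-25R")
    add("7a24-diH3OCA", "7α,24-dihydroxy-3-oxocholest-4-en-26-oic acid",
        "C27H42O5", family="diHCA", has_native_3oxo_4ene=True, has_7_hydroxy=True,
        nominal_rt_min=3.7, tier=Tier.SEMI, surrogate_standard_id="[2H3]7aH3OCA-25R")
    add("7a25-diH3OCA", "7α,25-dihydroxy-3-oxocholest-4-en-26-oic acid",
        "C27H42O5", family="diHCA", has_native_3oxo_4ene=True, has_7_hydroxy=True,
        nominal_rt_min=2.9, tier=Tier.SEMI, surrogate_standard_id="[2H3]7aH3OCA-25R")
    add("3b7a24-triHCA", "3β,7α,24-trihydroxycholest-5-en-26-oic acid",
        "C27H44O5", family="diHCA", has_3b_hydroxy_5ene=True, has_7_hydroxy=True,
        esterifiable=True, nominal_rt_min=3.7, tier=Tier.SEMI,
        surrogate_standard_id="[2H3]7aH3OCA-25R", oxo_partner_id="7a24-diH3OCA")
    add("3b7a25-triHCA", "3β,7α,25-trihydroxycholest-5-en-26-oic acid",
        "C27H44O5", family="diHCA", has_3b_hydroxy_5ene=True, has_7_hydroxy=True,
        esterifiable=True, nominal_rt_min=2.9, tier=Tier.SEMI,
        surrogate_standard_id="[2H3]7aH3OCA-25R", oxo_partner_id="7a25-diH3OCA")

    # --- cholesterol and identified-only entries ----------------------------
    add("cholesterol", "cholesterol", "C27H46O", family="cholesterol-like",
        has_3b_hydroxy_5ene=True, esterifiable=True, nominal_rt_min=14.0,
        tier=Tier.ABSOLUTE, surrogate_standard_id="[2H7]cholesterol")
    add("22S-HC", "22S-hydroxycholesterol", "C27H46O2", family="monoHC",
        has_3b_hydroxy_5ene=True, esterifiable=True, nominal_rt_min=5.05,
        tier=Tier.IDENTIFIED_ONLY)

    # --- isotope-labelled standard mix (certified ng/mL in the mix) ---------
    # The 24R/S and the acid standards are epimer mixtures: the mix component
    # is registered with the certified total, and each chromatographically
    # resolved epimer is registered as a child carrying its area fraction.
    add("[2H7]24RS-HC", "[2H7]24R/S-hydroxycholesterol (mix component)",
        "C27H39[2H]7O2", family="monoHC", has_3b_hydroxy_5ene=True,
        label_count=7, mix_conc_ng_per_ml=80.0, tier=Tier.ABSOLUTE)
    add("[2H7]24S-HC", "[2H7]24S-hydroxycholesterol", "C27H39[2H]7O2",
        family="monoHC", has_3b_hydroxy_5ene=True, label_count=7,
        nominal_rt_min=6.55, parent_standard_id="[2H7]24RS-HC",
        epimer_fraction=D7_24S_FRACTION,
        mix_conc_ng_per_ml=80.0 * D7_24S_FRACTION)
    add("[2H7]24R-HC", "[2H7]24R-hydroxycholesterol", "C27H39[2H]7O2",
        family="monoHC", has_3b_hydroxy_5ene=True, label_count=7,
        nominal_rt_min=7.65, parent_standard_id="[2H7]24RS-HC",
        epimer_fraction=1.0 - D7_24S_FRACTION, prefer_mrm=True,
        mix_conc_ng_per_ml=80.0 * (1.0 - D7_24S_FRACTION))
    add("[2H6]25-HC", "[2H6]25-hydroxycholesterol", "C27H40[2H]6O2",
        family="monoHC", has_3b_hydroxy_5ene=True, label_count=6,
        nominal_rt_min=7.05, mix_conc_ng_per_ml=10.0)
    add("[2H6]26R-HC", "[2H6](25R)26-hydroxycholesterol", "C27H40[2H]6O2",
        family="monoHC", has_3b_hydroxy_5ene=True, label_count=6,
        nominal_rt_min=7.80, mix_conc_ng_per_ml=160.0)
    add("[2H5]26R-HC", "[2H5](25R)26-hydroxycholesterol (impurity)",
        "C27H41[2H]5O2", family="monoHC", has_3b_hydroxy_5ene=True,
        label_count=5, nominal_rt_min=7.80,
        mix_conc_ng_per_ml=160.0 * D5_IMPURITY_FRACTION)
    add("[2H7]7a-HC", "[2H7]7α-hydroxycholesterol", "C27H39[2H]7O2",
        family="monoHC", has_3b_hydroxy_5ene=True, has_7_hydroxy=True,
        autoxidation_prone=True, label_count=7, nominal_rt_min=8.75,
        mix_conc_ng_per_ml=60.0)
    add("[2H7]7b-HC", "[2H7]7β-hydroxycholesterol", "C27H39[2H]7O2",
        family="monoHC", has_3b_hydroxy_5ene=True, has_7_hydroxy=True,
        autoxidation_prone=True, label_count=7, nominal_rt_min=9.35,
        mix_conc_ng_per_ml=10.0)
    add("[2H7]7-OC", "[2H7]7-oxocholesterol", "C27H37[2H]7O2", family="HCO",
        has_7oxo=True, autoxidation_prone=True, label_count=7,
        nominal_rt_min=10.85, mix_conc_ng_per_ml=30.0)
    add("[2H7]7a-HCO", "[2H7]7α-hydroxycholest-4-en-3-one",
        "C27H37[2H]7O2", family="HCO", has_native_3oxo_4ene=True,
        has_7_hydroxy=True, label_count=7, nominal_rt_min=8.75,
        mix_conc_ng_per_ml=20.0)
    add("[2H6]7a25-diHC", "[2H6]7α,25-dihydroxycholesterol",
        "C27H40[2H]6O3", family="diHC", has_3b_hydroxy_5ene=True,
        has_7_hydroxy=True, label_count=6, nominal_rt_min=3.55,
        mix_conc_ng_per_ml=1.0)
    add("[2H6]7a26-diHC", "[2H6]7α,(25R/S)26-dihydroxycholesterol",
        "C27H40[2H]6O3", family="diHC", has_3b_hydroxy_5ene=True,
        has_7_hydroxy=True, label_count=6, nominal_rt_min=4.25,
        mix_conc_ng_per_ml=2.0)
    add("[2H3]7aH3OCA", "[2H3]7αH,3O-CA(25R/S) (mix component)",
        "C27H39[2H]3O4", family="HOCA", has_native_3oxo_4ene=True,
        has_7_hydroxy=True, label_count=3, mix_conc_ng_per_ml=70.0)
    add("[2H3]7aH3OCA-25R", "[2H3]7αH,3O-CA(25R)", "C27H39[2H]3O4",
        family="HOCA", has_native_3oxo_4ene=True, has_7_hydroxy=True,
        label_count=3, nominal_rt_min=4.85, parent_standard_id="[2H3]7aH3OCA",
        epimer_fraction=D3_CA_25R_FRACTION,
        mix_conc_ng_per_ml=70.0 * D3_CA_25R_FRACTION)
    add("[2H3]7aH3OCA-25S", "[2H3]7αH,3O-CA(25S)", "C27H39[2H]3O4",
        family="HOCA", has_native_3oxo_4ene=True, has_7_hydroxy=True,
        label_count=3, nominal_rt_min=5.55, parent_standard_id="[2H3]7aH3OCA",
        epimer_fraction=1.0 - D3_CA_25R_FRACTION,
        mix_conc_ng_per_ml=70.0 * (1.0 - D3_CA_25R_FRACTION))
    add("[2H7]4b-HC", "[2H7]4β-hydroxycholesterol", "C27H39[2H]7O2",
        family="monoHC", has_3b_hydroxy_5ene=True, label_count=7,
        nominal_rt_min=10.35, mix_conc_ng_per_ml=30.0)
    add("[2H7]22R-HC", "[2H7]22R-hydroxycholesterol", "C27H39[2H]7O2",
        family="monoHC", has_3b_hydroxy_5ene=True, label_count=7,
        nominal_rt_min=6.05, mix_conc_ng_per_ml=5.0)
    add("[2H7]5a6b-diHC", "[2H7]cholestane-3β,5α,6β-triol",
        "C27H41[2H]7O3", family="diHC", has_3b_hydroxy_5ene=True,
        dehydrates_on_derivatization=True, autoxidation_prone=True,
        label_count=7, nominal_rt_min=9.85, mix_conc_ng_per_ml=10.0)

    # --- quantitative singles (added by amount, not via the mix) -----------
    add("[2H7]22S-HCO", "[2H7]22S-hydroxycholest-4-en-3-one", "C27H37[2H]7O2",
        family="HCO", has_native_3oxo_4ene=True, label_count=7,
        nominal_rt_min=5.55)
    add("[2H7]cholesterol", "[2H7]cholesterol", "C27H39[2H]7O",
        family="cholesterol-like", has_3b_hydroxy_5ene=True, label_count=7,
        nominal_rt_min=13.95)
    add("[2H6]24RS-HC", "[2H6]24R/S-hydroxycholesterol (quantitative single)",
        "C27H40[2H]6O2", family="monoHC", has_3b_hydroxy_5ene=True,
        label_count=6, nominal_rt_min=6.6)
    return reg


def inclusion_list(
    registry: Registry,
    ppm_window: float = 5.0,
    fractions: Iterable[Fraction] = (Fraction.A, Fraction.B),
    species_ids: Optional[Iterable[str]] = None,
) -> List[dict]:
    """Rows for a targeted-acquisition inclusion list.

    One row per derivatizable (species, fraction): derivative m/z with its ppm
    window and the MSn transition levels.
    """
    rows = []
    ids = list(species_ids) if species_ids is not None else registry.ids()
    for sid in ids:
        sp = registry.lookup(sid)
        if sp.nominal_rt_min is None:
            continue
        for fraction in fractions:
            if not sp.derivatized_in(fraction):
                continue
            gp = GP_FOR_FRACTION[Fraction(fraction)]
            ion = derivative_ion(sp, fraction, gp)
            path = transition_path(sp, fraction, gp)
            rows.append(
                {
                    "species_id": sp.id,
                    "fraction": Fraction(fraction).value,
                    "gp": gp.label,
                    "mz": round(ion.mz, 4),
                    "ppm_window": ppm_window,
                    "rt_min": sp.nominal_rt_min,
                    "transition": path.display(),
                }
            )
    return rows
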