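"""Standard-mix ledger: certified concentrations and aliquot arithmetic.

The commercial mix carries 13 isotope-labelled standards at certified ng/mL;
an aliquot of ``v`` mL therefore delivers ``conc × v`` ng of each standard
into the sample.  A handful of quantitative single standards (e.g.
[2H7]cholesterol) are added per sample as fixed amounts, not via the mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import yaml

from .registry import Registry, build_default_registry


class LedgerError(ValueError):
    pass


#: The 13 mix components with certified concentrations (ng/mL in the mix).
DEFAULT_MIX_NG_PER_ML: Dict[str, float] = {
    "[2H7]24RS-HC": 80.0,
    "[2H6]25-HC": 10.0,
    "[2H6]26R-HC": 160.0,
    "[2H7]7a-HC": 60.0,
    "[2H7]7b-HC": 10.0,
    "[2H7]7-OC": 30.0,
    "[2H7]7a-HCO": 20.0,
    "[2H6]7a25-diHC": 1.0,
    "[2H6]7a26-diHC": 2.0,
    "[2H3]7aH3OCA": 70.0,
    "[2H7]4b-HC": 30.0,
    "[2H7]22R-HC": 5.0,
    "[2H7]5a6b-diHC": 10.0,
}

#: Quantitative single-standard stock concentrations (ng/mL).
DEFAULT_SINGLES_NG_PER_ML: Dict[str, float] = {
    "[2H6]24RS-HC": 51950.0,
    "[2H7]cholesterol": 526010.0,
}

#: Fixed per-sample additions (ng) used in the plasma and CSF protocols.
DEFAULT_SAMPLE_ADDITIONS_NG: Dict[str, Dict[str, float]] = {
    "plasma": {"[2H7]22S-HCO": 10.0, "[2H7]cholesterol": 20000.0},
    "CSF": {"[2H7]22S-HCO": 1.0, "[2H7]cholesterol": 200.0},
}


@dataclass
class StandardMixLedger:
    """Certified standard concentrations plus aliquot/amount arithmetic."""

    mix_ng_per_ml: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIX_NG_PER_ML)
    )
    singles_ng_per_ml: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SINGLES_NG_PER_ML)
    )
    sample_additions_ng: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_SAMPLE_ADDITIONS_NG.items()
        }
    )

    def __post_init__(self) -> None:
        for sid, conc in {**self.mix_ng_per_ml, **self.singles_ng_per_ml}.items():
            if conc <= 0:
                raise LedgerError(f"non-positive concentration for {sid}")
        missing = set(DEFAULT_MIX_NG_PER_ML) - set(self.mix_ng_per_ml)
        if missing:
            raise LedgerError(
                "ledger missing mix components: " + ", ".join(sorted(missing))
            )

    def mix_amounts_ng(self, mix_volume_ml: float) -> Dict[str, float]:
        """ng of each mix component delivered by an aliquot of the mix."""
        if mix_volume_ml < 0:
            raise LedgerError("negative mix volume")
        return {sid: c * mix_volume_ml for sid, c in self.mix_ng_per_ml.items()}

    def standard_amounts_ng(
        self,
        mix_volume_ml: float,
        matrix: str = "plasma",
        registry: Optional[Registry] = None,
        include_impurity: bool = True,
    ) -> Dict[str, float]:
        """Per-standard ng in one prepared sample, epimer splits applied.

        Mix components that are epimer mixtures are expanded to their
        chromatographically resolved children using the registered area
        fractions; the [2H5] isotopic impurity of the [2H6](25R)26-HC
        standard is included at its registered relative level.
        """
        registry = registry or build_default_registry()
        amounts = self.mix_amounts_ng(mix_volume_ml)
        amounts.update(self.sample_additions_ng.get(matrix, {}))
        out: Dict[str, float] = {}
        for sid, ng in amounts.items():
            children = [
                sp for sp in registry if sp.parent_standard_id == sid
            ]
            if children:
                for ch in children:
                    out[ch.id] = ng * ch.epimer_fraction
            else:
                out[sid] = ng
        if include_impurity and "[2H6]26R-HC" in out and "[2H5]26R-HC" in registry:
            d5 = registry.lookup("[2H5]26R-HC")
            d6 = registry.lookup("[2H6]26R-HC")
            out["[2H5]26R-HC"] = out["[2H6]26R-HC"] * (
                (d5.mix_conc_ng_per_ml or 0.0) / (d6.mix_conc_ng_per_ml or 1.0)
            )
        return out

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "mix_ng_per_ml": dict(self.mix_ng_per_ml),
            "singles_ng_per_ml": dict(self.singles_ng_per_ml),
            "sample_additions_ng": {
                k: dict(v) for k, v in self.sample_additions_ng.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "StandardMixLedger":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            mix_ng_per_ml=doc["mix_ng_per_ml"],
            singles_ng_per_ml=doc.get("singles_ng_per_ml", {}),
            sample_additions_ng=doc.get("sample_additions_ng", {}),
        )


def default_ledger() -> StandardMixLedger:
    return StandardMixLedger()


def load_ledger(path) -> StandardMixLedger:
    """Load and validate a ledger config; raises listing missing components."""
    return StandardMixLedger.from_yaml(path)
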