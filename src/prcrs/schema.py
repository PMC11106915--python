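"""Canonical clinical factor catalogue for CRS risk prediction.

Input factors are organised in four clinically coherent panels:

1. coagulation & tumor load (9 factors)
2. blood routine (10 factors)
3. biochemistry (16 factors)
4. cytokines (7 factors)

The full feature vector concatenates the panels in that order (42 factors).
A model variant is configured by a *panel combination*: a subset of panels,
written as a digit string such as ``"1234"`` (all panels) or ``"23"``
(blood routine + biochemistry).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

PANEL_1_COAGULATION: Tuple[str, ...] = (
    "d_dimer",
    "procalcitonin",
    "b_type_natriuretic_peptide",
    "alpha_hydroxybutyrate_dehydrogenase",
    "prealbumin",
    "primitive_cells",
    "plasma_prothrombin_time",
    "activated_partial_prothrombin_time",
    "fibrinogen",
)

PANEL_2_BLOOD_ROUTINE: Tuple[str, ...] = (
    "red_blood_cell_count",
    "hemoglobin",
    "white_blood_cell_count",
    "neutrophil_percentage",
    "neutrophil_count",
    "lymphocyte_percentage",
    "lymphocyte_count",
    "platelet_count",
    "monocyte_percentage",
    "monocyte_count",
)

PANEL_3_BIOCHEMISTRY: Tuple[str, ...] = (
    "sodium",
    "potassium",
    "chlorine",
    "calcium",
    "uric_acid",
    "glucose",
    "triglyceride",
    "gamma_glutamyl_transpeptidase",
    "albumin",
    "alanine_aminotransferase",
    "aspartate_aminotransferase",
    "alkaline_phosphatase",
    "lactate_dehydrogenase",
    "creatinine",
    "c_reactive_protein",
    "ferritin",
)

PANEL_4_CYTOKINES: Tuple[str, ...] = (
    "il_6",
    "il_10",
    "ifn_gamma",
    "tnf_alpha",
    "il_2",
    "il_8",
    "il_1_beta",
)

#: Panel combinations offered for prediction, in recommended order of use.
VALID_COMBOS: Tuple[str, ...] = ("1234", "123", "4", "23", "3", "2")


@dataclass(frozen=True)
class FactorSchema:
    """The ordered four-panel factor catalogue.

    Panels are keyed ``1..4``; the concatenation order of factor names is
    fixed (panel 1, then 2, 3, 4).
    """

    panels: Dict[int, Tuple[str, ...]] = field(
        default_factory=lambda: {
            1: PANEL_1_COAGULATION,
            2: PANEL_2_BLOOD_ROUTINE,
            3: PANEL_3_BIOCHEMISTRY,
            4: PANEL_4_CYTOKINES,
        }
    )

    def __post_init__(self) -> None:
        sizes = {k: len(v) for k, v in self.panels.items()}
        if sizes != {1: 9, 2: 10, 3: 16, 4: 7}:
            raise ValueError(f"panel sizes must be 9/10/16/7, got {sizes}")
        names = self.all_factors()
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique across panels")

    def all_factors(self) -> List[str]:
        """All 42 factor names in canonical concatenation order."""
        return [f for pid in (1, 2, 3, 4) for f in self.panels[pid]]

    def factors_for_combo(self, combo: str) -> List[str]:
        """Factor names for a panel combination, order preserved."""
        combo = validate_combo(combo)
        return [f for pid in (1, 2, 3, 4) if str(pid) in combo for f in self.panels[pid]]

    def panel_of(self, factor: str) -> int:
        for pid, names in self.panels.items():
            if factor in names:
                return pid
        raise KeyError(f"unknown factor: {factor!r}")

    def n_features(self, combo: str = "1234") -> int:
        return len(self.factors_for_combo(combo))

    def to_json(self) -> str:
        return json.dumps({str(k): list(v) for k, v in self.panels.items()}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FactorSchema":
        raw = json.loads(text)
        return cls(panels={int(k): tuple(v) for k, v in raw.items()})


def validate_combo(combo: str) -> str:
    """Normalise and validate a panel combination string."""
    combo = str(combo)
    if combo not in VALID_COMBOS:
        raise ValueError(f"unsupported panel combination {combo!r}; valid: {VALID_COMBOS}")
    return combo


DEFAULT_SCHEMA = FactorSchema()
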