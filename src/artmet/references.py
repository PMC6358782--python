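"""Reference-standard ions and fragment lists for the three authentic
compounds used to anchor the method: artemisinin (ART), deoxyartemisinin
(de-ART) and dihydroartemisinin (DHA).

``observed_ions`` holds the printed accurate masses of the three adduct
channels per compound; ``fragments`` the high-energy fragment series (unit
resolution, as published). The DHA [M+H]+ value is ~25 mDa below the
theoretical protonated C15H24O5 and is kept verbatim but flagged, so
consumers can exclude it from accuracy checks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import Formula, parse_formula

__all__ = ["ReferenceCompound", "REFERENCE_COMPOUNDS"]


@dataclass(frozen=True)
class ReferenceCompound:
    name: str
    formula: Formula
    #: printed observed m/z per adduct channel
    observed_ions: dict[str, float]
    #: high-energy fragment series (unit-resolution m/z)
    fragments: tuple[int, ...]
    #: adducts whose printed value is known-inconsistent with the formula
    flagged_ions: tuple[str, ...] = ()


REFERENCE_COMPOUNDS: dict[str, ReferenceCompound] = {
    "ART": ReferenceCompound(
        name="ART",
        formula=parse_formula("C15H22O5"),
        observed_ions={"M+H": 283.1537, "M+Na": 305.1354, "M+K": 321.1092},
        fragments=(265, 247, 229, 237, 219, 209, 205, 191),
    ),
    "de-ART": ReferenceCompound(
        name="de-ART",
        formula=parse_formula("C15H22O4"),
        observed_ions={"M+H": 267.1589, "M+Na": 289.1407, "M+K": 305.1142},
        fragments=(249, 231, 239, 221, 203),
    ),
    "DHA": ReferenceCompound(
        name="DHA",
        formula=parse_formula("C15H24O5"),
        observed_ions={"M+H": 285.1447, "M+Na": 307.1509, "M+K": 323.1251},
        fragments=(267, 249, 231, 239, 221, 203),
        flagged_ions=("M+H",),
    ),
}
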