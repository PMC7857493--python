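"""Reference computations on the canonical myeloperoxidase record.

Bundles the study-level facts the package recomputes from first
principles: mature sequon positions, chain masses, and the mass of the
prominent diprotomeric glycoproteoform (canonical light+heavy chains,
one heme b per protomer, the dominant glycan at each sequon, the
interprotomer disulfide bridge).
"""

from __future__ import annotations

from .glycans import UNOCCUPIED, glycan_mass, parse_shorthand
from .proteins import (
    HEME_B_AVG,
    ProteinRecord,
    chain_mass,
    disulfide_correction,
    load_mpo_record,
)

__all__ = [
    "PROMINENT_GLYCOFORMS",
    "mature_sequon_positions",
    "protomer_mass",
    "prominent_diprotomer_mass",
]

#: Dominant glycoform at each mature sequon: truncated paucimannosidic
#: species at Asn323/Asn483, oligomannosidic at Asn355/Asn391, and a
#: largely unoccupied Asn729.
PROMINENT_GLYCOFORMS: dict[int, str] = {
    323: "M2F",
    355: "M6",
    391: "M6",
    483: "M3F",
    729: UNOCCUPIED,
}


def mature_sequon_positions(record: ProteinRecord | None = None) -> list[int]:
    """Sequon positions retained in mature myeloperoxidase (precursor numbering)."""
    record = record or load_mpo_record()
    return record.mature_sequons()


def protomer_mass(
    record: ProteinRecord | None = None,
    glycoforms: dict[int, str] | None = None,
    heme_mass: float = HEME_B_AVG,
    scale: str = "average",
) -> float:
    """Mass of one alpha-beta protomer with one heme and the given glycans."""
    record = record or load_mpo_record()
    glycoforms = PROMINENT_GLYCOFORMS if glycoforms is None else glycoforms
    mass = (
        chain_mass(record, "light", scale)
        + chain_mass(record, "heavy", scale)
        + heme_mass
    )
    for code in glycoforms.values():
        if code == UNOCCUPIED:
            continue
        mass += glycan_mass(parse_shorthand(code).composition, "conjugated", scale)
    return mass


def prominent_diprotomer_mass(
    record: ProteinRecord | None = None,
    glycoforms: dict[int, str] | None = None,
    scale: str = "average",
) -> float:
    """Mass of the prominent diprotomeric glycoproteoform (Cys-Cys bridged)."""
    record = record or load_mpo_record()
    p = protomer_mass(record, glycoforms, scale=scale)
    return 2.0 * p + disulfide_correction(1, scale)
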