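"""Composition-level model of the N-glycans found on neutrophil myeloperoxidase.

Glycans are named by a compact shorthand in which ``M<k>`` denotes
oligomannosidic/paucimannosidic species (Man_k GlcNAc2), ``GlcNAc<k>``
denotes chitobiose core-type stubs left on the asparagine, and
``[F]A<n>[G<g>][S<s>]`` denotes (core-fucosylated) complex-type glycans
with *n* antennary GlcNAc, *g* galactoses and *s* sialic acids on a
trimannosylchitobiose core.  An optional trailing ``a``/``b`` marks
chromatographically resolved isomers; it is carried as a label and does
not alter the composition.

The model is deliberately composition-level: linkage detail is encoded
only as the terminal-feature flags needed downstream (terminal
beta-1,2-GlcNAc, terminal alpha-1,3-mannose, core fucose), which is
sufficient for classifying species, simulating endoglycosidase H
treatment, and computing truncation-pathway metrics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "UNOCCUPIED",
    "GlycanClass",
    "GlycanComposition",
    "GlycanStructure",
    "GlycanParseError",
    "load_monosaccharide_table",
    "parse_shorthand",
    "glycan_mass",
    "classify",
    "endoh_sensitive",
    "fut8_eligible",
]

#: Reserved profile key for the non-glycosylated peptide form.
UNOCCUPIED = "unoccupied"

WATER_MONO = 18.01056
WATER_AVG = 18.01528

RESIDUE_CLASSES = ("Hex", "HexNAc", "dHex", "NeuAc", "Phospho")


class GlycanClass:
    """Biosynthetic classes reachable from the shorthand grammar."""

    OLIGOMANNOSE = "oligomannose"
    PAUCIMANNOSE = "paucimannose"
    COMPLEX_HYBRID = "complex/hybrid"
    CHITOBIOSE_CORE = "chitobiose-core"

    ALL = (OLIGOMANNOSE, PAUCIMANNOSE, COMPLEX_HYBRID, CHITOBIOSE_CORE)


class GlycanParseError(ValueError):
    """Raised when a shorthand code does not match the grammar."""


def load_monosaccharide_table() -> Mapping[str, tuple[float, float]]:
    """Load the shipped monosaccharide residue-mass table.

    Returns an immutable mapping ``name -> (monoisotopic, average)`` in Da.
    """
    table: dict[str, tuple[float, float]] = {}
    text = resources.files("mpoglyco.data").joinpath("monosaccharides.tsv").read_text()
    for line in text.strip().splitlines()[1:]:
        name, mono, avg = line.split("\t")
        mono_f, avg_f = float(mono), float(avg)
        if not (0.0 < mono_f <= avg_f):
            raise ValueError(f"invalid residue masses for {name}: {mono} / {avg}")
        table[name] = (mono_f, avg_f)
    return MappingProxyType(table)


MONOSACCHARIDES = load_monosaccharide_table()


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of monosaccharide residue classes in one N-glycan."""

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neuac: int = 0
    phospho: int = 0

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "dhex", "neuac", "phospho"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} count")
        if self.dhex > max(self.hexnac, 0):
            raise ValueError("dHex exceeds HexNAc: core fucose requires a core GlcNAc")

    def as_dict(self) -> dict[str, int]:
        return {
            "Hex": self.hex,
            "HexNAc": self.hexnac,
            "dHex": self.dhex,
            "NeuAc": self.neuac,
            "Phospho": self.phospho,
        }

    @property
    def total_residues(self) -> int:
        return self.hex + self.hexnac + self.dhex + self.neuac


@dataclass(frozen=True)
class GlycanStructure:
    """A shorthand-coded glycan with composition, class and terminal flags."""

    code: str
    composition: GlycanComposition
    glycan_class: str
    isomer: str = ""
    has_b12_glcnac: bool = False
    has_a13_man: bool = False
    core_fucosylated: bool = False

    @property
    def canonical_code(self) -> str:
        """Regenerate the shorthand code from the composition (isomer dropped)."""
        c = self.composition
        if self.glycan_class == GlycanClass.CHITOBIOSE_CORE:
            return f"GlcNAc{c.hexnac}" + ("F" if c.dhex else "")
        if self.glycan_class == GlycanClass.COMPLEX_HYBRID:
            n = c.hexnac - 2
            code = ("F" if c.dhex else "") + f"A{n}"
            if c.hex > 3:
                code += f"G{c.hex - 3}"
            if c.neuac:
                code += f"S{c.neuac}"
            return code
        return f"M{c.hex}" + ("F" if c.dhex else "")


_M_RE = re.compile(r"^M(\d+)(F?)([ab]?)$")
_GLCNAC_RE = re.compile(r"^GlcNAc(\d+)(F?)([ab]?)$")
_COMPLEX_RE = re.compile(r"^(F?)A(\d+)(?:G(\d+))?(?:S(\d+))?([ab]?)$")


def parse_shorthand(code: str) -> GlycanStructure:
    """Parse a shorthand glycan code into a classified :class:`GlycanStructure`.

    >>> parse_shorthand("M5").glycan_class
    'oligomannose'
    >>> parse_shorthand("M2F").core_fucosylated
    True
    """
    if not isinstance(code, str) or not code.strip():
        raise GlycanParseError("empty glycan code")
    code = code.strip()
    if code == UNOCCUPIED:
        raise GlycanParseError(
            "'unoccupied' is a reserved profile key, not a glycan structure"
        )

    m = _M_RE.match(code)
    if m:
        k = int(m.group(1))
        if k == 0:
            raise GlycanParseError(f"zero mannose count in {code!r}")
        comp = GlycanComposition(hex=k, hexnac=2, dhex=1 if m.group(2) else 0)
        return _build(code, comp, isomer=m.group(3))

    m = _GLCNAC_RE.match(code)
    if m:
        k = int(m.group(1))
        if k == 0 or k > 2:
            raise GlycanParseError(f"chitobiose core GlcNAc count must be 1-2 in {code!r}")
        comp = GlycanComposition(hexnac=k, dhex=1 if m.group(2) else 0)
        return _build(code, comp, isomer=m.group(3))

    m = _COMPLEX_RE.match(code)
    if m:
        n = int(m.group(2))
        if n == 0:
            raise GlycanParseError(f"zero antennae in {code!r}")
        g = int(m.group(3) or 0)
        s = int(m.group(4) or 0)
        if g > n or s > n:
            raise GlycanParseError(f"more Gal/NeuAc than antennae in {code!r}")
        comp = GlycanComposition(
            hex=3 + g, hexnac=2 + n, dhex=1 if m.group(1) else 0, neuac=s
        )
        return _build(code, comp, isomer=m.group(5))

    raise GlycanParseError(f"unparseable glycan code: {code!r}")


def _build(code: str, comp: GlycanComposition, isomer: str = "") -> GlycanStructure:
    cls = classify(comp)
    # Terminal beta-1,2-GlcNAc is exposed only on agalactosylated,
    # asialo complex-type antennae (A<n>/FA<n> with no G/S extension).
    b12 = cls == GlycanClass.COMPLEX_HYBRID and comp.hex == 3 and comp.neuac == 0
    # Terminal alpha-1,3-arm mannose is present on Man3+ trimmed cores.
    a13 = comp.hexnac == 2 and comp.hex >= 3
    return GlycanStructure(
        code=code,
        composition=comp,
        glycan_class=cls,
        isomer=isomer,
        has_b12_glcnac=b12,
        has_a13_man=a13,
        core_fucosylated=comp.dhex >= 1,
    )


def classify(comp: GlycanComposition) -> str:
    """Assign the biosynthetic class of a composition.

    Rules (deterministic, total on the shorthand-reachable space):
    chitobiose-core for HexNAc <= 2 with no Hex; oligomannose for
    HexNAc2 Hex>=5 without fucose; paucimannose for HexNAc2 Hex1-4;
    complex/hybrid for HexNAc >= 3.
    """
    if comp.hexnac <= 2 and comp.hex == 0 and comp.hexnac >= 1:
        return GlycanClass.CHITOBIOSE_CORE
    if comp.hexnac == 2 and comp.hex >= 5 and comp.dhex == 0:
        return GlycanClass.OLIGOMANNOSE
    if comp.hexnac == 2 and 1 <= comp.hex <= 4:
        return GlycanClass.PAUCIMANNOSE
    if comp.hexnac >= 3:
        return GlycanClass.COMPLEX_HYBRID
    raise ValueError(f"unclassifiable composition: {comp.as_dict()}")


def glycan_mass(
    comp: GlycanComposition, form: str = "conjugated", scale: str = "monoisotopic"
) -> float:
    """Mass of a glycan composition in Da.

    ``form='free'`` is the released glycan (adds one water); ``'conjugated'``
    is the residue-mass delta the glycan contributes on an asparagine.
    """
    if form not in ("free", "conjugated"):
        raise ValueError(f"unknown form {form!r}")
    if scale not in ("monoisotopic", "average"):
        raise ValueError(f"unknown scale {scale!r}")
    idx = 0 if scale == "monoisotopic" else 1
    counts = comp.as_dict()
    mass = sum(MONOSACCHARIDES[name][idx] * n for name, n in counts.items())
    if form == "free" and comp.total_residues + comp.phospho > 0:
        mass += WATER_MONO if scale == "monoisotopic" else WATER_AVG
    return mass


def endoh_sensitive(g: GlycanStructure) -> bool:
    """True iff endoglycosidase H cleaves the glycan down to a GlcNAc stub.

    Endo H hydrolyses between the two core GlcNAc residues of
    oligomannosidic (and hybrid) glycans; processed, truncated and
    core-fucosylated species resist it.
    """
    return g.glycan_class == GlycanClass.OLIGOMANNOSE


def fut8_eligible(g: GlycanStructure) -> bool:
    """True iff the glycan passed through a FUT8-competent intermediate.

    FUT8 (core alpha-1,6-fucosyltransferase) cannot act on oligomannosidic
    substrates; every processed or truncated class is counted as having
    been a potential substrate.
    """
    return g.glycan_class != GlycanClass.OLIGOMANNOSE


def inventory_to_rows(codes: list[str]) -> list[dict]:
    """Tabulate an inventory of shorthand codes (for TSV export)."""
    rows = []
    for code in codes:
        g = parse_shorthand(code)
        row = {"code": code}
        row.update(g.composition.as_dict())
        row["class"] = g.glycan_class
        rows.append(row)
    return rows
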