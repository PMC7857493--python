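"""Sequence-level model of myeloperoxidase-like proteins.

Handles sequon detection on the precursor, chain extraction from an
annotation table (1-based inclusive ranges on UniProt precursor
numbering, signal peptide included), polypeptide masses, and the
non-glycan modification arithmetic (Met/Trp oxidation, Tyr
chlorination, heme, disulfides).

The canonical human myeloperoxidase precursor (UniProtKB P05164) ships
with the package together with its chain annotation.  The precursor
carries six N-glycosylation sequons; the one at Asn139 lies in the
propeptide and is removed during maturation, leaving the five sites of
the mature beta-chain (Asn323, Asn355, Asn391, Asn483, Asn729).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from Bio import SeqIO
from pyteomics import mass as pmass

__all__ = [
    "ProteinRecord",
    "PtmDelta",
    "find_sequons",
    "chain_mass",
    "apply_ptms",
    "load_mpo_record",
    "load_ptm_table",
    "disulfide_correction",
    "OXIDATION_MONO",
    "CHLORINATION_MONO",
    "HEME_B_MONO",
    "HEME_B_AVG",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

OXIDATION_MONO = 15.99491
CHLORINATION_MONO = 33.96103
HEME_B_MONO = 616.17730   # heme b, C34H32FeN4O4; covalent-link correction is a knob
HEME_B_AVG = 616.4873
DISULFIDE_MONO = -2.01565  # loss of two H per bridge
DISULFIDE_AVG = -2.01588


@dataclass(frozen=True)
class PtmDelta:
    """A named modification mass delta with its target residues."""

    name: str
    targets: str
    mono: float
    avg: float
    max_copies: int

    def delta(self, scale: str = "monoisotopic") -> float:
        return self.mono if scale == "monoisotopic" else self.avg


@dataclass
class ProteinRecord:
    """A precursor sequence with named chain ranges (1-based inclusive)."""

    accession: str
    sequence: str
    chains: dict[str, tuple[int, int]] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residues in {self.accession}: {sorted(bad)}")
        n = len(self.sequence)
        for name, (start, end) in self.chains.items():
            if not (1 <= start <= end <= n):
                raise ValueError(f"chain {name!r} range ({start},{end}) outside 1..{n}")

    def chain_sequence(self, chain: str) -> str:
        if chain == "full":
            return self.sequence
        if chain not in self.chains:
            raise KeyError(f"unknown chain {chain!r}; have {sorted(self.chains)}")
        start, end = self.chains[chain]
        return self.sequence[start - 1 : end]

    def mature_sequons(self, mature_chains: tuple[str, ...] = ("light", "heavy")) -> list[int]:
        """Sequon positions retained in the mature (processed) protein.

        Detected on the full precursor so positions stay in precursor
        numbering, then filtered to the annotated mature chain ranges.
        """
        ranges = [self.chains[c] for c in mature_chains if c in self.chains]
        return [
            p
            for p in find_sequons(self.sequence)
            if any(start <= p <= end for start, end in ranges)
        ]


def find_sequons(sequence: str) -> list[int]:
    """Return 1-based Asn positions of N-X-S/T sequons (X != Pro).

    A trailing Asn within the last two residues can never complete the
    motif and is not reported.
    """
    seq = sequence.upper()
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return [
        i + 1
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"
    ]


def chain_mass(record: ProteinRecord, chain: str, scale: str = "average") -> float:
    """Mass in Da of an annotated chain's unmodified polypeptide (+ water)."""
    seq = record.chain_sequence(chain)
    if scale == "monoisotopic":
        return pmass.calculate_mass(sequence=seq)
    if scale == "average":
        return pmass.calculate_mass(sequence=seq, average=True)
    raise ValueError(f"unknown scale {scale!r}")


def apply_ptms(
    base_mass: float,
    modifications: list[tuple[PtmDelta, int]],
    scale: str = "monoisotopic",
) -> float:
    """Add modification deltas to a base mass; order-independent."""
    total = base_mass
    for ptm, copies in modifications:
        if copies < 0 or copies > ptm.max_copies:
            raise ValueError(
                f"{ptm.name}: {copies} copies outside 0..{ptm.max_copies}"
            )
        total += copies * ptm.delta(scale)
    return total


def disulfide_correction(n_bridges: int, scale: str = "monoisotopic") -> float:
    """Mass correction for n disulfide bridges (two H lost per bridge)."""
    if n_bridges < 0:
        raise ValueError("negative bridge count")
    return n_bridges * (DISULFIDE_MONO if scale == "monoisotopic" else DISULFIDE_AVG)


def _read_chain_table(text: str) -> dict[str, tuple[int, int]]:
    chains: dict[str, tuple[int, int]] = {}
    for line in text.strip().splitlines()[1:]:
        name, start, end = line.split("\t")
        chains[name] = (int(start), int(end))
    return chains


def load_mpo_record() -> ProteinRecord:
    """Load the shipped canonical human myeloperoxidase precursor."""
    with resources.as_file(
        resources.files("mpoglyco.data").joinpath("P05164.fasta")
    ) as path:
        rec = next(SeqIO.parse(str(path), "fasta"))
    chains = _read_chain_table(
        resources.files("mpoglyco.data").joinpath("P05164_chains.tsv").read_text()
    )
    return ProteinRecord(
        accession="P05164",
        sequence=str(rec.seq),
        chains=chains,
        notes="alpha=light (165-278), beta=heavy (279-745); "
        "interprotomer Cys319-Cys319 bridge in the diprotomer",
    )


def load_ptm_table() -> dict[str, PtmDelta]:
    """Load the shipped modification table (oxidation, chlorination, heme)."""
    text = resources.files("mpoglyco.data").joinpath("ptm_deltas.tsv").read_text()
    table: dict[str, PtmDelta] = {}
    for line in text.strip().splitlines()[1:]:
        name, targets, mono, avg, max_copies = line.split("\t")
        table[name] = PtmDelta(name, targets, float(mono), float(avg), int(max_copies))
    return table
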