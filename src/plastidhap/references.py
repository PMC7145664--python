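"""Build doubled haplotype reference sequences from the three plastome regions.

Given the LSC, SSC and IR sequences, each structural haplotype's monomer
is the concatenation of the four oriented region slots; the reference is
the monomer duplicated head-to-tail so that reads spanning the
linearisation point of the circular genome still align contiguously.
Every reference carries a block map giving the exact half-open
coordinates of each of the eight region instances on the doubled
sequence, which the read classifier uses to test IR coverage and flank
depth.  Coordinates are 0-based half-open throughout, matching PAF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq

from .haplotypes import Orientation, Structure, enumerate_ir_constrained

__all__ = [
    "RegionSet",
    "Block",
    "HaplotypeRef",
    "apply_orientation",
    "build_references",
    "read_region_fasta",
    "write_reference_fasta",
    "split_plastome",
]

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
FASTA_WRAP = 80


def _validate_seq(seq: str, label: str) -> str:
    seq = seq.upper()
    for i, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise ValueError(
                f"{label}: invalid base {base!r} at position {i} "
                "(alphabet is ACGTN, case-insensitive)"
            )
    return seq


@dataclass(frozen=True)
class RegionSet:
    """The three region sequences of a quadripartite plastome."""

    lsc: str
    ssc: str
    ir: str

    def __post_init__(self) -> None:
        for label in ("lsc", "ssc", "ir"):
            seq = getattr(self, label)
            if not seq:
                raise ValueError(f"region {label.upper()} is empty")
            object.__setattr__(self, label, _validate_seq(seq, label.upper()))

    @property
    def genome_length(self) -> int:
        """Monomer length G = |LSC| + |SSC| + 2|IR|."""
        return len(self.lsc) + len(self.ssc) + 2 * len(self.ir)

    def region(self, role: str) -> str:
        return {"LSC": self.lsc, "SSC": self.ssc, "IR": self.ir}[role]


@dataclass(frozen=True)
class Block:
    """One region instance on a doubled reference (0-based half-open)."""

    role: str
    orientation: Orientation
    start: int
    end: int
    copy_index: int  # occurrence index of this role along the doubled sequence

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HaplotypeRef:
    """A named doubled reference sequence with its block coordinate map."""

    structure: Structure
    doubled_seq: str
    block_map: tuple[Block, ...] = field(repr=False)

    @property
    def name(self) -> str:
        return self.structure.name

    def ir_blocks(self) -> list[Block]:
        return [b for b in self.block_map if b.role == "IR"]

    def flanked_ir_blocks(self) -> list[Block]:
        """IR instances with both an LSC and an SSC neighbour in the map.

        On the doubled layout (LSC IR SSC IR) x 2 these are the first
        three IR instances; the final IR abuts the sequence end and
        cannot satisfy a flank requirement on its high-coordinate side.
        """
        irs = []
        for i, b in enumerate(self.block_map):
            if b.role == "IR" and 0 < i < len(self.block_map) - 1:
                irs.append(b)
        return irs


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def apply_orientation(seq: str, o: Orientation) -> str:
    """Transform a sequence: identity, reverse, complement or reverse-complement."""
    seq = _validate_seq(seq, "sequence")
    if o is Orientation.ID:
        return seq
    if o is Orientation.R:
        return seq[::-1]
    if o is Orientation.C:
        return seq.translate(_COMPLEMENT)
    return str(Seq(seq).reverse_complement())


def build_monomer(regions: RegionSet, s: Structure) -> str:
    """Concatenation of the four oriented region slots (one genome copy)."""
    from .haplotypes import ROLES

    return "".join(
        apply_orientation(regions.region(role), o)
        for role, o in zip(ROLES, s.orientations)
    )


def _make_block_map(regions: RegionSet, s: Structure) -> tuple[Block, ...]:
    from .haplotypes import ROLES

    blocks: list[Block] = []
    pos = 0
    counts: dict[str, int] = {}
    for _rep in range(2):
        for role, o in zip(ROLES, s.orientations):
            length = len(regions.region(role))
            idx = counts.get(role, 0)
            blocks.append(Block(role, o, pos, pos + length, idx))
            counts[role] = idx + 1
            pos += length
    return tuple(blocks)


def build_reference(regions: RegionSet, s: Structure) -> HaplotypeRef:
    monomer = build_monomer(regions, s)
    return HaplotypeRef(s, monomer + monomer, _make_block_map(regions, s))


def build_references(
    regions: RegionSet, structures: Sequence[Structure] | None = None
) -> list[HaplotypeRef]:
    """One doubled reference per structure (default: the 32 canonical
    IR-constrained structures)."""
    if structures is None:
        structures = enumerate_ir_constrained()
    names = [s.name for s in structures]
    if len(set(names)) != len(names):
        raise ValueError("structures must be unique")
    return [build_reference(regions, s) for s in structures]


def read_region_fasta(source: Union[str, Path, TextIO]) -> RegionSet:
    """Read a FASTA with records identified (case-insensitively) as LSC, SSC, IR."""
    records = {}
    for rec in SeqIO.parse(source, "fasta"):
        key = rec.id.upper()
        if key in records:
            raise ValueError(f"duplicate region id {rec.id!r} in region FASTA")
        records[key] = str(rec.seq)
    missing = {"LSC", "SSC", "IR"} - records.keys()
    if missing:
        raise ValueError(
            f"region FASTA must contain LSC, SSC and IR records; "
            f"missing {sorted(missing)}, found {sorted(records)}"
        )
    return RegionSet(lsc=records["LSC"], ssc=records["SSC"], ir=records["IR"])


def _wrap(seq: str, width: int = FASTA_WRAP) -> Iterable[str]:
    for i in range(0, len(seq), width):
        yield seq[i : i + width]


def write_region_fasta(regions: RegionSet, dest: Union[str, Path, TextIO]) -> None:
    _write_fasta(
        [("LSC", regions.lsc), ("SSC", regions.ssc), ("IR", regions.ir)], dest
    )


def write_reference_fasta(
    refs: Sequence[HaplotypeRef], dest: Union[str, Path, TextIO]
) -> None:
    """Write the references as a multi-FASTA keyed by structure name,
    consumable by any long-read mapper."""
    _write_fasta([(r.name, r.doubled_seq) for r in refs], dest)


def _write_fasta(
    items: Sequence[tuple[str, str]], dest: Union[str, Path, TextIO]
) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            _write_fasta(items, fh)
        return
    for name, seq in items:
        dest.write(f">{name}\n")
        for line in _wrap(seq):
            dest.write(line + "\n")


def split_plastome(
    genome: str,
    ira: tuple[int, int],
    irb: tuple[int, int],
) -> RegionSet:
    """Split a complete plastome (LSC-first) into regions, given the 0-based
    half-open coordinates of the two repeat copies.

    The genome must be linearised at the LSC start with IRa downstream of
    the LSC.  A warning is logged if the second repeat copy is not the
    exact reverse complement of the first (non-identical or in-line
    repeat annotations).
    """
    genome = _validate_seq(genome, "genome")
    (a0, a1), (b0, b1) = ira, irb
    if not (0 < a0 < a1 <= b0 < b1 <= len(genome)):
        raise ValueError("repeat coordinates must satisfy 0 < a0 < a1 <= b0 < b1 <= len(genome)")
    ir = genome[a0:a1]
    other = genome[b0:b1]
    if other != apply_orientation(ir, Orientation.RC):
        logger.warning(
            "second repeat copy is not the exact reverse complement of the first"
        )
    regions = RegionSet(
        lsc=genome[b1:] + genome[:a0],  # circular: tail past IRb wraps into the LSC
        ssc=genome[a1:b0],
        ir=ir,
    )
    return regions
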