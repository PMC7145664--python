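"""Orientation algebra and enumeration of plastome structural haplotypes.

Plant chloroplast genomes are circular and quadripartite: a large
single-copy region (LSC) and a small single-copy region (SSC) separated
by two copies of a large repeat (IR), in the conserved order
LSC-IRa-SSC-IRb.  A *structural haplotype* assigns each of the four
region slots one of four orientations (original, reversed, complemented,
reverse-complemented), giving 4**4 = 256 arrangements.  Because DNA is
double-stranded, a molecule and its opposite-strand reading are
indistinguishable, which merges the 256 arrangements into 128
identifiable structures.  Constraining the two repeat copies to be
mutually inverted (the typical plastome configuration, and the one a
single IR-spanning read can identify) leaves 32 canonical structures.

This module provides the orientation group, the structure type and its
string naming, strand equivalence, canonicalisation, the enumerations
above, and the A/B/C haplotype labelling used for reporting.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "Orientation",
    "Structure",
    "HaplotypeLabel",
    "compose",
    "enumerate_all",
    "strand_equivalent",
    "canonical",
    "enumerate_ir_constrained",
    "label_haplotype",
    "HAPLOTYPE_A_NAME",
    "HAPLOTYPE_B_NAME",
    "INLINE_DIAGNOSTIC_NAMES",
]


class Orientation(enum.IntEnum):
    """One of the four ways a region sequence can appear in a molecule.

    The codes form the Klein four-group under composition; with the
    integer encoding below, composition is bitwise XOR (reversal and
    complementation are independent involutions).
    """

    ID = 0  # original
    R = 1   # reversed
    C = 2   # complemented
    RC = 3  # reverse-complemented

    @property
    def suffix(self) -> str:
        return _SUFFIX[self]


_SUFFIX = {
    Orientation.ID: "",
    Orientation.R: "r",
    Orientation.C: "c",
    Orientation.RC: "rc",
}
_SUFFIX_TO_ORIENT = {v: k for k, v in _SUFFIX.items()}

#: fixed role order of the quadripartite structure
ROLES = ("LSC", "IR", "SSC", "IR")


def compose(a: Orientation, b: Orientation) -> Orientation:
    """Orientation equivalent to applying ``b`` then ``a`` (commutative)."""
    return Orientation(a ^ b)


@dataclass(frozen=True, order=True)
class Structure:
    """A structural haplotype: orientations for the LSC, IRa, SSC, IRb slots."""

    orientations: tuple[Orientation, Orientation, Orientation, Orientation]

    def __post_init__(self) -> None:
        if len(self.orientations) != 4:
            raise ValueError("a structure has exactly four region slots")

    @property
    def name(self) -> str:
        """Token name, e.g. ``LSC_IR_SSC_IRrc`` (suffixes r/c/rc per slot)."""
        return "_".join(
            role + o.suffix for role, o in zip(ROLES, self.orientations)
        )

    @classmethod
    def from_name(cls, name: str) -> "Structure":
        tokens = name.split("_")
        if len(tokens) != 4:
            raise ValueError(f"structure name must have 4 tokens: {name!r}")
        orients = []
        for token, role in zip(tokens, ROLES):
            if not token.startswith(role):
                raise ValueError(
                    f"token {token!r} does not match expected role {role}"
                )
            suffix = token[len(role):]
            if suffix not in _SUFFIX_TO_ORIENT:
                raise ValueError(f"unknown orientation suffix {suffix!r} in {token!r}")
            orients.append(_SUFFIX_TO_ORIENT[suffix])
        return cls(tuple(orients))

    @property
    def is_ir_constrained(self) -> bool:
        """True when the second repeat copy is the inversion of the first."""
        return self.orientations[3] == compose(Orientation.RC, self.orientations[1])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


#: canonical structure of haplotype A (published orientation, inverted repeats)
HAPLOTYPE_A_NAME = "LSC_IR_SSC_IRrc"
#: canonical structure of haplotype B (SSC flipped relative to A)
HAPLOTYPE_B_NAME = "LSC_IR_SSCrc_IRrc"
#: the two references whose IR-instance mapping pattern diagnoses in-line repeats
INLINE_DIAGNOSTIC_NAMES = ("LSC_IR_SSC_IRrc", "LSC_IRrc_SSC_IR")


class HaplotypeLabel(enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    OTHER = "OTHER"


def enumerate_all() -> list[Structure]:
    """All 256 orientation assignments, sorted lexicographically by name."""
    structures = [
        Structure(orients)
        for orients in itertools.product(Orientation, repeat=4)
    ]
    return sorted(structures, key=lambda s: s.name)


def strand_equivalent(s: Structure) -> Structure:
    """The structure seen when reading the same circular molecule from the
    opposite strand.

    Reading the complementary strand reverse-complements the whole
    molecule: the slot order reverses, every slot orientation composes
    with RC, and the molecule is rotated so the LSC slot comes first
    again.  The operation is an involution with no fixed points.
    """
    a, b, c, d = s.orientations
    rc = Orientation.RC
    return Structure((compose(rc, a), compose(rc, d), compose(rc, c), compose(rc, b)))


def canonical(s: Structure) -> Structure:
    """Representative of the strand-equivalence class {s, strand_equivalent(s)}:
    whichever has the lexicographically smaller name.  Idempotent."""
    t = strand_equivalent(s)
    return s if s.name <= t.name else t


@lru_cache(maxsize=1)
def enumerate_ir_constrained() -> tuple[Structure, ...]:
    """The 32 canonical structures with mutually inverted repeat copies.

    The 4*4*4 = 64 assignments satisfying orientation(IRb) =
    RC . orientation(IRa) collapse pairwise under strand equivalence.
    """
    seen: dict[str, Structure] = {}
    for a, b, c in itertools.product(Orientation, repeat=3):
        d = compose(Orientation.RC, b)
        rep = canonical(Structure((a, b, c, d)))
        seen[rep.name] = rep
    return tuple(sorted(seen.values(), key=lambda s: s.name))


def label_haplotype(s: Structure, inline_evidence: bool = False) -> HaplotypeLabel:
    """A/B/C/OTHER label for a canonical structure.

    Haplotype A is the arrangement with both single-copy regions in the
    published orientation and inverted repeats; haplotype B differs from
    A only in the orientation of the SSC; haplotype C denotes a genome
    whose repeat copies are in-line (same orientation) rather than
    inverted, inferred indirectly from the read-mapping pattern rather
    than from a dedicated reference.
    """
    rep = canonical(s)
    if rep.name == HAPLOTYPE_A_NAME:
        return HaplotypeLabel.A
    if rep.name == HAPLOTYPE_B_NAME:
        return HaplotypeLabel.B
    if inline_evidence:
        return HaplotypeLabel.C
    return HaplotypeLabel.OTHER
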