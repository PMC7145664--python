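"""Classify long-read alignments into structural-haplotype support.

A read supports a structural haplotype when its best alignment to the
doubled reference set completely covers one IR instance and extends at
least ``flank_min`` (default 1000 bp) into both adjacent single-copy
blocks — the junction context LSC|IR|SSC read through an entire repeat
copy is what distinguishes the 32 canonical structures from each other.
Such alignments are *valid calls*; each read contributes at most one.

The module also implements the indirect inference of in-line (tandem,
non-inverted) repeat genomes: reads from such a genome can only produce
valid calls at the 1st/3rd flanked IR instance of the LSC_IR_SSC_IRrc
reference and at the 2nd flanked IR instance of the LSC_IRrc_SSC_IR
reference; seeing exactly that disjoint pattern, and nothing else,
indicates in-line repeats even though no in-line reference is present.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from .haplotypes import INLINE_DIAGNOSTIC_NAMES
from .references import HaplotypeRef

__all__ = [
    "PafRecord",
    "ValidCall",
    "RejectionReason",
    "TallyTable",
    "InlineEvidence",
    "parse_paf",
    "select_alignment",
    "call_read",
    "classify_records",
    "tally",
    "detect_inline_repeats",
    "write_calls_tsv",
    "write_tally_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PafRecord:
    """One PAF alignment line (mandatory 12 columns plus the tp:A type tag)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int
    type_tag: str | None = None  # 'P' primary, 'S' secondary, 'I'/'i' inversion

    @property
    def is_primary(self) -> bool:
        return self.type_tag in (None, "P")

    @property
    def identity(self) -> float:
        return self.nmatch / self.alnlen if self.alnlen else 0.0


class RejectionReason(enum.Enum):
    NO_IR_COVERED = "NO_IR_COVERED"
    FLANK_TOO_SHORT = "FLANK_TOO_SHORT"
    IR_AT_EDGE = "IR_AT_EDGE"


@dataclass(frozen=True)
class ValidCall:
    """A read's unique assignment to one structure via full-IR + flank coverage."""

    qname: str
    structure: str
    ir_instance: int  # 1-based index among the fully flanked IR instances
    left_flank: int
    right_flank: int


def parse_paf(
    source: Union[str, Path, TextIO, Iterable[str]],
    known_targets: set[str] | None = None,
) -> tuple[list[PafRecord], int]:
    """Parse PAF lines into records.

    Malformed lines (too few columns, non-integer fields, inverted or
    out-of-range coordinates) are skipped with a logged warning; records
    whose target is not in ``known_targets`` (when given) are dropped
    likewise.  Returns ``(records, n_skipped)``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return parse_paf(fh, known_targets)

    records: list[PafRecord] = []
    skipped = 0
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        rec = _parse_fields(fields, lineno)
        if rec is None:
            skipped += 1
            continue
        if known_targets is not None and rec.tname not in known_targets:
            logger.warning(
                "PAF line %d: target %r not in reference set; dropped",
                lineno,
                rec.tname,
            )
            skipped += 1
            continue
        records.append(rec)
    return records, skipped


def _parse_fields(fields: list[str], lineno: int) -> PafRecord | None:
    if len(fields) < 12:
        logger.warning("PAF line %d: %d columns (<12); skipped", lineno, len(fields))
        return None
    try:
        qlen, qstart, qend = int(fields[1]), int(fields[2]), int(fields[3])
        tlen, tstart, tend = int(fields[6]), int(fields[7]), int(fields[8])
        nmatch, alnlen, mapq = int(fields[9]), int(fields[10]), int(fields[11])
    except ValueError:
        logger.warning("PAF line %d: non-integer mandatory field; skipped", lineno)
        return None
    strand = fields[4]
    ok = (
        strand in "+-"
        and 0 <= qstart < qend <= qlen
        and 0 <= tstart < tend <= tlen
        and 0 <= nmatch <= alnlen
    )
    if not ok:
        logger.warning("PAF line %d: invalid coordinates/strand; skipped", lineno)
        return None
    type_tag = None
    for tag in fields[12:]:
        if tag.startswith("tp:A:"):
            type_tag = tag[5:]
            break
    return PafRecord(
        qname=fields[0],
        qlen=qlen,
        qstart=qstart,
        qend=qend,
        strand=strand,
        tname=fields[5],
        tlen=tlen,
        tstart=tstart,
        tend=tend,
        nmatch=nmatch,
        alnlen=alnlen,
        mapq=mapq,
        type_tag=type_tag,
    )


def select_alignment(records: Sequence[PafRecord]) -> PafRecord | None:
    """Best-hit selection for one read, mirroring a mapper run with
    secondary alignments suppressed.

    Only primary records (tp:A:P, or untagged) are considered; among
    those the highest match count wins, ties broken by lexicographic
    target name.
    """
    primaries = [r for r in records if r.is_primary]
    if not primaries:
        return None
    return min(primaries, key=lambda r: (-r.nmatch, r.tname))


def call_read(
    rec: PafRecord,
    ref: HaplotypeRef,
    flank_min: int = 1000,
    ir_slack: int = 0,
) -> ValidCall | RejectionReason:
    """Apply the valid-read rule to one best-hit alignment.

    The alignment must contain a whole flanked IR block and reach at
    least ``flank_min`` bp beyond the block on both sides.  ``ir_slack``
    tolerates ragged alignment ends: the required span
    ``[block.start - flank_min, block.end + flank_min]`` may be missed
    by up to ``ir_slack`` bp at each end (at slack 0 this is exactly
    strict containment plus full flanks).  When several IR instances
    qualify — possible only for reads longer than one genome copy — the
    lowest-coordinate one is recorded, so each read yields a single call.
    """
    if rec.tname != ref.name:
        raise ValueError(f"alignment target {rec.tname!r} does not match reference {ref.name!r}")
    flanked = ref.flanked_ir_blocks()
    saw_short_flank = False
    for block in flanked:
        if rec.tstart <= block.start + ir_slack and rec.tend >= block.end - ir_slack:
            left_ok = rec.tstart <= block.start - flank_min + ir_slack
            right_ok = rec.tend >= block.end + flank_min - ir_slack
            if left_ok and right_ok:
                instance = flanked.index(block) + 1
                return ValidCall(
                    rec.qname,
                    ref.name,
                    instance,
                    block.start - rec.tstart,
                    rec.tend - block.end,
                )
            saw_short_flank = True
    if saw_short_flank:
        return RejectionReason.FLANK_TOO_SHORT
    # distinguish "covered only the unflankable edge IR" from "no IR at all"
    for block in ref.ir_blocks():
        if block not in flanked and rec.tstart <= block.start + ir_slack and rec.tend >= block.end - ir_slack:
            return RejectionReason.IR_AT_EDGE
    return RejectionReason.NO_IR_COVERED


def classify_records(
    records: Sequence[PafRecord],
    refs: Sequence[HaplotypeRef],
    flank_min: int = 1000,
    ir_slack: int = 0,
    min_identity: float = 0.0,
) -> tuple[list[ValidCall], Counter]:
    """Group alignments by read, pick the best hit, and apply the
    valid-read rule; returns the calls and a counter of rejection reasons.

    ``min_identity`` optionally discards best hits whose match fraction
    (nmatch/alnlen) falls below the threshold, to guard against reads
    from near-identical non-chloroplast plastid genomes.
    """
    by_name = {r.name: r for r in refs}
    grouped: dict[str, list[PafRecord]] = defaultdict(list)
    for rec in records:
        grouped[rec.qname].append(rec)

    calls: list[ValidCall] = []
    rejections: Counter = Counter()
    for qname in sorted(grouped):
        best = select_alignment(grouped[qname])
        if best is None:
            rejections["NO_PRIMARY"] += 1
            continue
        if best.identity < min_identity:
            rejections["LOW_IDENTITY"] += 1
            continue
        ref = by_name.get(best.tname)
        if ref is None:
            raise ValueError(f"alignment target {best.tname!r} not in reference set")
        result = call_read(best, ref, flank_min=flank_min, ir_slack=ir_slack)
        if isinstance(result, ValidCall):
            calls.append(result)
        else:
            rejections[result.value] += 1
    return calls, rejections


@dataclass
class TallyTable:
    """Valid-read support per structure, with per-IR-instance sub-counts."""

    counts: dict[str, int] = field(default_factory=dict)
    instance_counts: dict[tuple[str, int], int] = field(default_factory=dict)
    total_valid: int = 0


def tally(calls: Sequence[ValidCall]) -> TallyTable:
    """Aggregate valid calls; raises on a duplicate read name (at most one
    call per read is guaranteed upstream, so a duplicate indicates a bug)."""
    seen: set[str] = set()
    t = TallyTable()
    for call in calls:
        if call.qname in seen:
            raise ValueError(f"duplicate call for read {call.qname!r}")
        seen.add(call.qname)
        t.counts[call.structure] = t.counts.get(call.structure, 0) + 1
        key = (call.structure, call.ir_instance)
        t.instance_counts[key] = t.instance_counts.get(key, 0) + 1
        t.total_valid += 1
    return t


@dataclass(frozen=True)
class InlineEvidence:
    """Outcome of the in-line-repeat inference rule."""

    triggered: bool
    supporting_reads: int
    pattern: dict[tuple[str, int], int]


def detect_inline_repeats(t: TallyTable, min_reads: int = 5) -> InlineEvidence:
    """Infer a genome with in-line (same-orientation) repeat copies.

    Triggered iff all valid calls fall exactly in the diagnostic
    pattern — instances 1 and/or 3 of the first diagnostic reference and
    instance 2 of the second, with the complementary instances and every
    other structure empty — and the combined support exceeds
    ``min_reads``.
    """
    ref_a, ref_b = INLINE_DIAGNOSTIC_NAMES
    pattern = {
        k: v for k, v in t.instance_counts.items() if k[0] in (ref_a, ref_b)
    }
    supporting = sum(
        t.instance_counts.get(k, 0)
        for k in ((ref_a, 1), (ref_a, 3), (ref_b, 2))
    )
    other_structures = sum(
        v for k, v in t.counts.items() if k not in (ref_a, ref_b)
    )
    off_pattern = (
        t.instance_counts.get((ref_a, 2), 0)
        + t.instance_counts.get((ref_b, 1), 0)
        + t.instance_counts.get((ref_b, 3), 0)
    )
    triggered = (
        supporting > min_reads and other_structures == 0 and off_pattern == 0
    )
    return InlineEvidence(triggered, supporting, pattern)


def write_calls_tsv(calls: Sequence[ValidCall], dest: Union[str, Path, TextIO]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_calls_tsv(calls, fh)
        return
    dest.write("qname\tstructure\tir_instance\tleft_flank\tright_flank\n")
    for c in calls:
        dest.write(
            f"{c.qname}\t{c.structure}\t{c.ir_instance}\t{c.left_flank}\t{c.right_flank}\n"
        )


def read_calls_tsv(source: Union[str, Path, TextIO]) -> list[ValidCall]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_calls_tsv(fh)
    header = next(source, None)
    calls = []
    for line in source:
        if not line.strip():
            continue
        qname, structure, inst, left, right = line.rstrip("\n").split("\t")
        calls.append(ValidCall(qname, structure, int(inst), int(left), int(right)))
    return calls


def write_tally_tsv(t: TallyTable, dest: Union[str, Path, TextIO]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_tally_tsv(t, fh)
        return
    dest.write("structure\tir_instance\tcount\n")
    for (structure, inst), n in sorted(t.instance_counts.items()):
        dest.write(f"{structure}\t{inst}\t{n}\n")
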