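"""End-to-end pipeline: regions -> references -> classification -> report.

Ties the stages together for the common case: build the 32 doubled
references from a region FASTA, classify a best-hit PAF against them,
tally support, run the in-line-repeat inference, and quantify haplotype
frequencies with the equal-ratio test.  All outputs are deterministic
functions of the inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .classify import (
    InlineEvidence,
    TallyTable,
    classify_records,
    detect_inline_repeats,
    parse_paf,
    write_calls_tsv,
    write_tally_tsv,
)
from .references import build_references, read_region_fasta, write_reference_fasta
from .stats import QuantResult, quantify, structural_labeling, write_report_tsv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunOutputs", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    regions: Path
    alignments: Path
    outdir: Path
    flank_min: int = 1000
    ir_slack: int = 0
    min_identity: float = 0.0
    min_valid_reads: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank_min < 0 or self.ir_slack < 0 or self.min_identity < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class RunOutputs:
    tally: TallyTable
    inline: InlineEvidence
    result: QuantResult


def run_pipeline(cfg: RunConfig) -> RunOutputs:
    """Run the three-stage analysis and write refs.fasta, calls.tsv,
    tally.tsv, report.tsv and run.log under the output directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    regions = read_region_fasta(cfg.regions)
    refs = build_references(regions)
    write_reference_fasta(refs, outdir / "refs.fasta")

    records, skipped = parse_paf(cfg.alignments, known_targets={r.name for r in refs})
    calls, rejections = classify_records(
        records,
        refs,
        flank_min=cfg.flank_min,
        ir_slack=cfg.ir_slack,
        min_identity=cfg.min_identity,
    )
    write_calls_tsv(calls, outdir / "calls.tsv")
    t = tally_calls(calls)
    write_tally_tsv(t, outdir / "tally.tsv")

    inline = detect_inline_repeats(t, min_reads=cfg.min_valid_reads)
    result = quantify(t, structural_labeling(inline_evidence=inline.triggered))
    write_report_tsv({"sample": result}, outdir / "report.tsv")

    with open(outdir / "run.log", "w") as fh:
        fh.write(f"plastidhap {__version__}\n")
        fh.write(f"config: {cfg}\n")
        fh.write(f"paf_records: {len(records)}  skipped_lines: {skipped}\n")
        fh.write(f"valid_reads: {t.total_valid}  rejections: {dict(rejections)}\n")
        fh.write(f"inline_evidence: {inline.triggered} ({inline.supporting_reads} reads)\n")
    return RunOutputs(t, inline, result)


def tally_calls(calls):
    from .classify import tally

    return tally(calls)
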