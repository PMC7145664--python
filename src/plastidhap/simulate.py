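"""Synthetic plastomes, isomer mixtures, long reads, and truth alignments.

The generator emulates the data regime the method is designed for: a
circular quadripartite chloroplast genome present as a mixture of
structural isomers (typically haplotypes A and B near 1:1), sequenced
with reads long enough to span an entire repeat copy plus a kilobase of
each neighbouring single-copy region.  Reads are drawn from the doubled
circular template at a uniform start, a log-normal length and a uniform
strand, with optional uniform substitution/indel errors.

Because correctness must not depend on an external mapper, the module
can also emit *truth* alignments in PAF: for reads simulated from a
structure present in the reference set the placement is known by
construction; for other sources (e.g. in-line repeat genomes) error-free
reads are placed by exact substring search against every doubled
reference, which doubles as a minimal independent mapper in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, TextIO, Union

import numpy as np

from .haplotypes import (
    HAPLOTYPE_A_NAME,
    HAPLOTYPE_B_NAME,
    Orientation,
    Structure,
)
from .references import HaplotypeRef, RegionSet, apply_orientation, build_monomer

__all__ = [
    "SimConfig",
    "TruthRead",
    "SimResult",
    "make_regions",
    "make_genome",
    "simulate_reads",
    "simulate_dataset",
    "emit_truth_paf",
    "map_reads_exact",
    "write_reads_fasta",
    "write_truth_tsv",
    "resolve_mixture",
]

#: alias names accepted in mixture specifications
STRUCTURE_ALIASES = {
    "A": HAPLOTYPE_A_NAME,
    "B": HAPLOTYPE_B_NAME,
    # in-line (tandem) repeats with haplotype A's single-copy order
    "C": "LSC_IR_SSC_IR",
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults reflect a typical angiosperm plastome (LSC ~85 kb, SSC
    ~18 kb, IR ~25 kb, GC ~0.37) sequenced as an equal mixture of the
    two single-copy-orientation isomers with nanopore-scale read lengths
    (log-normal, median 15 kb).  Error rates default to zero; truth
    alignments then place every read exactly.
    """

    lsc_len: int = 85_000
    ssc_len: int = 18_000
    ir_len: int = 25_000
    gc: float = 0.37
    mixture: Mapping[str, float] = field(
        default_factory=lambda: {HAPLOTYPE_A_NAME: 0.5, HAPLOTYPE_B_NAME: 0.5}
    )
    n_reads: int = 2000
    read_median: int = 15_000
    read_sigma: float = 0.35
    read_min: int = 1000
    read_max: int = 60_000
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        mix = resolve_mixture(self.mixture)
        object.__setattr__(self, "mixture", mix)
        total = sum(mix.values())
        if any(w < 0 for w in mix.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        for rate in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= rate <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


def resolve_mixture(mixture: Mapping[str, float]) -> dict[str, float]:
    """Expand A/B/C aliases to structure names and validate the names."""
    out: dict[str, float] = {}
    for key, w in mixture.items():
        name = STRUCTURE_ALIASES.get(key, key)
        Structure.from_name(name)  # raises on a malformed name
        out[name] = out.get(name, 0.0) + float(w)
    return out


@dataclass(frozen=True)
class TruthRead:
    """Ground truth for one simulated read."""

    qname: str
    structure: str
    start: int      # circular start on the source monomer, in [0, G)
    length: int     # template span in bp (before errors)
    strand: str     # '+' forward, '-' reverse-complemented read
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0


@dataclass
class SimResult:
    config: SimConfig
    regions: RegionSet
    genomes: dict[str, str]
    reads: list[tuple[str, str]]
    truth: list[TruthRead]


_BASES = np.array(list("ACGT"))


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def make_regions(cfg: SimConfig, rng: np.random.Generator | None = None) -> RegionSet:
    """Random LSC/SSC/IR sequences at the configured GC; the IR string is
    guaranteed not to occur verbatim inside the single-copy regions
    (regenerated on the astronomically unlikely collision)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lsc = _random_seq(cfg.lsc_len, cfg.gc, rng)
    ssc = _random_seq(cfg.ssc_len, cfg.gc, rng)
    for _ in range(100):
        ir = _random_seq(cfg.ir_len, cfg.gc, rng)
        if ir not in lsc and ir not in ssc:
            return RegionSet(lsc=lsc, ssc=ssc, ir=ir)
    raise RuntimeError("could not draw an IR absent from the single-copy regions")


def make_genome(regions: RegionSet, s: Structure) -> str:
    """Monomer of the oriented regions, interpreted as a circular genome."""
    return build_monomer(regions, s)


def _draw_lengths(cfg: SimConfig, n: int, g: int, rng: np.random.Generator) -> np.ndarray:
    mu = math.log(cfg.read_median)
    hi = min(cfg.read_max, g)
    lo = min(cfg.read_min, hi)
    lengths = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, cfg.read_sigma, size=2 * (n - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        lengths[filled : filled + take] = ok[:take].astype(int)
        filled += take
    return lengths


def _apply_errors(
    seq: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, int, int, int]:
    if cfg.sub_rate == cfg.ins_rate == cfg.del_rate == 0:
        return seq, 0, 0, 0
    out: list[str] = []
    n_sub = n_ins = n_del = 0
    u = rng.random((len(seq), 3))
    for i, base in enumerate(seq):
        if u[i, 0] < cfg.del_rate:
            n_del += 1
            continue
        if u[i, 1] < cfg.sub_rate:
            choices = [b for b in "ACGT" if b != base]
            base = choices[rng.integers(3)]
            n_sub += 1
        out.append(base)
        if u[i, 2] < cfg.ins_rate:
            out.append("ACGT"[rng.integers(4)])
            n_ins += 1
    return "".join(out), n_sub, n_ins, n_del


def simulate_reads(
    cfg: SimConfig,
    genomes: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], list[TruthRead]]:
    """Draw reads from the circular genomes according to the mixture.

    Each read picks a source structure by mixture weight, a uniform
    circular start, a truncated log-normal length (capped at the genome
    length) and a uniform strand; errors are applied at the configured
    rates.  Returns ``(reads, truth)`` with one truth row per read.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    names = sorted(cfg.mixture)
    weights = np.array([cfg.mixture[n] for n in names])
    g = len(next(iter(genomes.values())))
    if any(len(seq) != g for seq in genomes.values()):
        raise ValueError("all source genomes must share one length")

    sources = rng.choice(len(names), size=cfg.n_reads, p=weights)
    lengths = _draw_lengths(cfg, cfg.n_reads, g, rng)
    starts = rng.integers(0, g, size=cfg.n_reads)
    strands = rng.choice(np.array(["+", "-"]), size=cfg.n_reads)

    reads: list[tuple[str, str]] = []
    truth: list[TruthRead] = []
    for i in range(cfg.n_reads):
        name = names[sources[i]]
        doubled = genomes[name] + genomes[name]
        start, length = int(starts[i]), int(lengths[i])
        template = doubled[start : start + length]
        if strands[i] == "-":
            template = apply_orientation(template, Orientation.RC)
        seq, n_sub, n_ins, n_del = _apply_errors(template, cfg, rng)
        qname = f"read_{i:06d}"
        reads.append((qname, seq))
        truth.append(
            TruthRead(qname, name, start, length, str(strands[i]), n_sub, n_ins, n_del)
        )
    return reads, truth


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Regions, source genomes, reads and truth for one configuration."""
    rng = np.random.default_rng(cfg.seed)
    regions = make_regions(cfg, rng)
    genomes = {
        name: make_genome(regions, Structure.from_name(name))
        for name in cfg.mixture
    }
    reads, truth = simulate_reads(cfg, genomes, rng)
    return SimResult(cfg, regions, genomes, reads, truth)


def _paf_line(
    qname: str,
    qlen: int,
    strand: str,
    tname: str,
    tlen: int,
    tstart: int,
    tend: int,
    nmatch: int,
    alnlen: int,
) -> str:
    return (
        f"{qname}\t{qlen}\t0\t{qlen}\t{strand}\t{tname}\t{tlen}\t"
        f"{tstart}\t{tend}\t{nmatch}\t{alnlen}\t60\ttp:A:P"
    )


def emit_truth_paf(
    truth: Sequence[TruthRead],
    refs: Sequence[HaplotypeRef],
    reads: Sequence[tuple[str, str]] | None = None,
) -> list[str]:
    """One primary PAF record per read giving its true placement.

    A read whose source structure is in the reference set is placed by
    coordinate arithmetic on that doubled reference (always representable
    because the reference is twice the genome and reads are at most one
    genome long).  A read from a structure absent from the set — the
    in-line repeat case — is placed by exact substring search over all
    references, which requires the read sequences and is only exact for
    error-free reads; reads with no exact placement are omitted, as a
    best-hit mapper may discard them.
    """
    by_name = {r.name: r for r in refs}
    seqs = dict(reads) if reads is not None else None
    lines: list[str] = []
    for row in truth:
        ref = by_name.get(row.structure)
        if ref is not None:
            qlen = row.length + row.n_ins - row.n_del
            nmatch = row.length - row.n_sub - row.n_del
            alnlen = row.length + row.n_ins
            lines.append(
                _paf_line(
                    row.qname,
                    qlen,
                    row.strand,
                    ref.name,
                    len(ref.doubled_seq),
                    row.start,
                    row.start + row.length,
                    nmatch,
                    alnlen,
                )
            )
            continue
        if seqs is None:
            raise ValueError(
                f"read {row.qname}: source {row.structure!r} is not in the "
                "reference set; pass the read sequences for exact placement"
            )
        if row.n_sub or row.n_ins or row.n_del:
            raise ValueError(
                "exact placement of out-of-reference reads requires error-free reads"
            )
        hit = _find_exact(seqs[row.qname], refs)
        if hit is not None:
            tname, strand, tstart, tlen = hit
            L = len(seqs[row.qname])
            lines.append(
                _paf_line(row.qname, L, strand, tname, tlen, tstart, tstart + L, L, L)
            )
    return lines


def _find_exact(
    seq: str, refs: Sequence[HaplotypeRef]
) -> tuple[str, str, int, int] | None:
    """First full-length exact placement over references sorted by name
    ('+' checked before '-'), mirroring the classifier's tie-break."""
    rc = apply_orientation(seq, Orientation.RC)
    for ref in sorted(refs, key=lambda r: r.name):
        idx = ref.doubled_seq.find(seq)
        if idx >= 0:
            return ref.name, "+", idx, len(ref.doubled_seq)
        idx = ref.doubled_seq.find(rc)
        if idx >= 0:
            return ref.name, "-", idx, len(ref.doubled_seq)
    return None


def map_reads_exact(
    reads: Sequence[tuple[str, str]], refs: Sequence[HaplotypeRef]
) -> list[str]:
    """Exact-substring 'mapper': a primary PAF record per read that occurs
    verbatim (either strand) in some doubled reference.  Only meaningful
    for error-free reads; serves as an independent check of the
    truth-based placement."""
    lines = []
    for qname, seq in reads:
        hit = _find_exact(seq, refs)
        if hit is not None:
            tname, strand, tstart, tlen = hit
            lines.append(
                _paf_line(qname, len(seq), strand, tname, tlen, tstart, tstart + len(seq), len(seq), len(seq))
            )
    return lines


def write_reads_fasta(
    reads: Sequence[tuple[str, str]], dest: Union[str, Path, TextIO]
) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_reads_fasta(reads, fh)
        return
    for qname, seq in reads:
        dest.write(f">{qname}\n{seq}\n")


def write_truth_tsv(truth: Sequence[TruthRead], dest: Union[str, Path, TextIO]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_truth_tsv(truth, fh)
        return
    dest.write("qname\tstructure\tstart\tlength\tstrand\tn_sub\tn_ins\tn_del\n")
    for r in truth:
        dest.write(
            f"{r.qname}\t{r.structure}\t{r.start}\t{r.length}\t{r.strand}\t"
            f"{r.n_sub}\t{r.n_ins}\t{r.n_del}\n"
        )


def write_truth_paf(lines: Sequence[str], dest: Union[str, Path, TextIO]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_truth_paf(lines, fh)
        return
    for line in lines:
        dest.write(line + "\n")
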