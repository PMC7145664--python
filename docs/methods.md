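# Methods

## Model

A quadripartite plastome is modelled as four ordered region slots —
LSC, IRa, SSC, IRb — each carrying one of four orientations: original
(ID), reversed (R), complemented (C), reverse-complemented (RC). The
orientations form the Klein four-group under composition (implemented as
XOR on a two-bit code: one bit for reversal, one for complementation).
A *structure* is an assignment of orientations to the four slots; there
are 4⁴ = 256.

**Strand equivalence.** A circular double-stranded molecule read from
its complementary strand reverse-complements the whole monomer: the slot
order reverses, every slot orientation composes with RC, and the
molecule is rotated so the LSC slot leads again. Algebraically,
`(a, b, c, d) → (RC∘a, RC∘d, RC∘c, RC∘b)`. This map is an involution
with no fixed points (RC∘x ≠ x for every x), so the 256 structures fall
into exactly 128 classes of size two. A plain per-base complement
without reversal is *not* used: it does not correspond to reading the
other strand of any physical molecule. The class representative
("canonical" structure) is the member with the lexicographically smaller
name; names are per-slot tokens (`LSC`/`IR`/`SSC` plus suffix
``/`r`/`c`/`rc`) joined by underscores, e.g. `LSC_IR_SSC_IRrc`.

**IR constraint.** Restricting to structures whose second repeat copy is
the reverse complement of the first (orientation(IRb) = RC ∘
orientation(IRa)) gives 4³ = 64 assignments that collapse to 32
canonical structures. This is the default reference set: a read needs
to span only one IR plus flanking sequence — rather than the entire SSC
and more — to identify one of these uniquely.

**Haplotype labels.** Haplotype A is the class of `LSC_IR_SSC_IRrc`
(single-copy regions in the orientation of the user-supplied regions,
repeats inverted); haplotype B is the class of `LSC_IR_SSCrc_IRrc`
(SSC flipped); haplotype C denotes in-line (same-orientation) repeat
copies and is assigned only on in-line evidence (below). Labels are
defined structurally relative to the input region file, not by gene
annotation. Orientations R and C alone are not physically realisable
arrangements of one molecule; they are retained in enumeration and as
reference decoys and would be reported as OTHER if ever called.

## Reference construction

Each reference is the monomer (oriented LSC · IRa · SSC · IRb)
duplicated and concatenated, so reads spanning the linearisation point
align contiguously; its length is exactly 2G where
G = |LSC| + |SSC| + 2|IR|. A block map records the eight region
instances with 0-based half-open coordinates (the PAF convention,
avoiding junction off-by-ones). Region FASTA records must be named
LSC/SSC/IR (case-insensitive) — explicit over inference. Reference
FASTA is written wrapped at 80 columns. A helper `split_plastome` cuts a
complete published genome into regions given the two repeat-copy
coordinate pairs; automatic IR discovery is out of scope.

## Read classification

Input is PAF from any best-hit long-read mapper (or the simulator's
truth PAF). Per read, only primary records are considered (tp:A:P or
untagged); the highest match count wins, ties broken by lexicographic
target name. Supplementary/secondary alignments are ignored — the
doubled reference exists precisely so junction-spanning reads align in
one piece.

A best hit becomes a **valid call** when it completely covers a *flanked*
IR instance (an IR with both an LSC and an SSC neighbour in the block
map — the first three of the four instances on the doubled layout) and
extends at least `flank_min` (default 1000 bp) into both neighbouring
blocks. Flank comparisons are inclusive (`≥ flank_min`). A read
qualifying at several instances (only possible when longer than one
genome copy) is counted once, at the lowest-coordinate instance.
Rejections are categorised NO_IR_COVERED, FLANK_TOO_SHORT, or IR_AT_EDGE
(only the unflankable final IR instance was covered).

`ir_slack` (default 0, i.e. strict) tolerates ragged alignment ends: the
required span `[block.start − flank_min, block.end + flank_min]` may be
missed by up to `ir_slack` bp at each end. The tolerance is applied to
the span rather than to IR containment alone because a contiguous
alignment ending *inside* the IR can never exhibit a flank — slack on
containment by itself could never change an outcome. An optional
`min_identity` filter (nmatch/alnlen) guards against reads from
near-identical non-chloroplast plastid genomes; it is off by default.

**In-line repeat inference.** No in-line reference is built. On the
doubled `LSC_IR_SSC_IRrc` reference the three flanked IR instances sit
in contexts LSC·IR·SSC, SSC·IRrc·LSC, LSC·IR·SSC; on `LSC_IRrc_SSC_IR`
they sit in LSC·IRrc·SSC, SSC·IR·LSC, LSC·IRrc·SSC. A genome with
in-line repeats (both copies in the LSC→SSC orientation) has exactly the
junction contexts LSC·IR·SSC and SSC·IR·LSC, so its valid reads can only
land on instances 1/3 of the first reference and instance 2 of the
second. The rule triggers when all calls fall in exactly that disjoint
pattern — the complementary instances of both diagnostic references and
every other structure receive zero calls — and combined support exceeds
the sufficiency threshold. Genuinely inverted-repeat genomes populate
all three instances of their own reference and therefore never trigger
it.

## Statistics

With k valid reads of haplotype A among n = A + B, the frequency is k/n
and the departure from 1:1 is tested with the two-sided exact binomial
test computed by the point-probability ("minlike") method: the p-value
sums Pr(X = j | n, ½) over all j with Pr(X = j) ≤ Pr(X = k)·(1 + 10⁻⁷);
the relative tolerance keeps floating-point noise from deciding whether
the mirror-image outcome is included. Across S samples, homogeneity of
the two haplotype counts is tested with the Pearson χ² statistic against
pooled expected proportions (df = S − 1, no continuity correction),
via `scipy.stats.chi2_contingency`.

Frequencies are reported only for samples with **more than five** valid
reads in total (A + B + OTHER ≥ 6); the flag is `sufficient`. Reports
print frequencies and p-values at 2 decimals with p-values floored at
2.2e−16 for display, alongside full-precision columns.

## Simulator

The generator emulates the regime the method targets: defaults are
LSC 85 kb, SSC 18 kb, IR 25 kb (a typical angiosperm plastome), GC 0.37,
a 1:1 A/B mixture, 2000 reads with log-normal lengths (median 15 kb,
σ = 0.35, truncated to [1, 60] kb and to the genome length), uniform
circular start and strand, and error-free bases (uniform
substitution/indel rates up to 20% are available). Regions are i.i.d.
bases at the target GC; the IR string is guaranteed absent from the
single-copy regions. A single seed governs all draws.

Truth alignments are emitted as PAF: reads from a structure in the
reference set are placed by coordinate arithmetic on its doubled
reference (always representable since references are 2G and reads ≤ G);
reads from structures outside the set (the in-line case) are placed by
exact substring search over all references — exact only for error-free
reads — with ties broken by lexicographic reference name, mirroring the
classifier's tie-break. The same exact search doubles as a minimal
independent mapper in the test suite; an external mapper is an optional
integration path and is never required for correctness.

What the simulator does **not** emulate: realistic nanopore error
profiles (homopolymer bias, quality strings), chimeric or adapter
artefacts, non-chloroplast contamination, copy-number variation along
the genome, or linear genome ends. Passing tests therefore demonstrate
the combinatorics, the classification rule and the statistics — not
robustness to platform-specific artefacts, for which the `min_identity`
and `ir_slack` knobs exist.

## Test problem sizes

End-to-end tests use a reduced plastome keeping realistic proportions —
LSC 9 kb, SSC 4 kb, IR 2.5 kb (G = 18 kb) — with 400–600 reads of
median length 7 kb (range 2–18 kb), which yields ≈ 180 valid reads per
dataset. Mixture-recovery checks use the exact Clopper–Pearson 95%
interval per replicate over 12 replicates, since any single 95% interval
misses the truth for 5% of seeds by design. The type-I-error check
compares the Monte-Carlo rejection rate of the equal-frequency test over
2000 replicates (n = 1000 reads each) to the test's exactly enumerated
size at α = 0.05, which is slightly below 0.05 because the binomial is
discrete.

## Known limitations

- A/B labels are relative to the supplied region orientations; if the
  region file encodes the less common isomer, A and B swap meaning.
- Reads shorter than |IR| + 2·flank_min can never be valid, so species
  with very long IRs require correspondingly long reads; highly reduced
  IRs (a few hundred bp) instead need only ~2.4 kb reads.
- If the SSC (or LSC) is shorter than `flank_min`, a nominal flank can
  spill beyond the neighbouring block; flanks are measured as alignment
  extent past the IR boundary, not capped at the neighbour's length.
- One call per read: reads longer than a full genome contribute no extra
  evidence beyond their lowest-coordinate junction.
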