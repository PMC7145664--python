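"""Haplotype frequency estimation and the associated hypothesis tests.

Flip-flop recombination between the two large inverted repeats is
expected to maintain the two single-copy-orientation isomers (haplotypes
A and B) at a 1:1 ratio.  Given valid-read counts, this module estimates
the haplotype A frequency, tests it against 1:1 with a two-sided exact
binomial test, tests frequency homogeneity across samples with a Pearson
chi-square test, and applies the sufficiency filter (more than five
valid reads) below which no frequency is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence, TextIO, Union

import numpy as np
from scipy import stats as sps

from .classify import TallyTable
from .haplotypes import HaplotypeLabel, Structure, label_haplotype

__all__ = [
    "QuantResult",
    "HomogeneityResult",
    "binom_test_exact",
    "quantify",
    "chi2_homogeneity",
    "structural_labeling",
    "format_pvalue",
    "MIN_VALID_READS",
    "P_DISPLAY_FLOOR",
]

#: a sample needs more than this many valid reads for frequencies to be reported
MIN_VALID_READS = 5

#: display floor for p-values (smaller values are shown as "<2.2e-16")
P_DISPLAY_FLOOR = 2.2e-16

# relative tolerance when comparing point probabilities in the two-sided sum;
# guards against floating-point noise deciding whether the mirror-image
# outcome is included
_REL_TOL = 1e-7


def binom_test_exact(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial test by the point-probability method.

    The p-value sums Pr(X = j | n, p0) over every outcome j whose point
    probability does not exceed that of the observed k (within a small
    relative tolerance).  For p0 = 0.5 the result is symmetric in
    k <-> n - k.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} out of range [0, {n}]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    mask = pmf <= pmf[k] * (1.0 + _REL_TOL)
    if mask.all():
        return 1.0
    return min(float(pmf[mask].sum()), 1.0)


@dataclass(frozen=True)
class QuantResult:
    """Haplotype counts, frequency and equal-ratio test for one sample."""

    count_a: int
    count_b: int
    other_counts: Mapping[str, int] = field(default_factory=dict)
    frequency: float | None = None  # count_a / (count_a + count_b)
    p_binomial: float | None = None
    sufficient: bool = False

    @property
    def total_valid(self) -> int:
        return self.count_a + self.count_b + sum(self.other_counts.values())


Labeling = Union[Mapping[str, HaplotypeLabel], Callable[[str], HaplotypeLabel]]


def structural_labeling(inline_evidence: bool = False) -> Callable[[str], HaplotypeLabel]:
    """Default labeling: A/B by structure relative to the input regions."""

    def _label(name: str) -> HaplotypeLabel:
        return label_haplotype(Structure.from_name(name), inline_evidence)

    return _label


def quantify(t: TallyTable, labeling: Labeling | None = None) -> QuantResult:
    """Split tallied counts into haplotypes A/B/other and test A:B against 1:1.

    The frequency (proportion of haplotype A among A + B) and its exact
    binomial p-value are defined only when A + B > 0.  The sufficiency
    flag requires more than :data:`MIN_VALID_READS` valid reads in total;
    an insufficient sample keeps its counts but callers should not
    interpret its frequency.
    """
    if labeling is None:
        labeling = structural_labeling()
    label_of = labeling if callable(labeling) else lambda name: labeling[name]

    count_a = count_b = 0
    other: dict[str, int] = {}
    for name, n in t.counts.items():
        lab = label_of(name)
        if lab is HaplotypeLabel.A:
            count_a += n
        elif lab is HaplotypeLabel.B:
            count_b += n
        else:
            other[name] = other.get(name, 0) + n

    frequency = p = None
    if count_a + count_b > 0:
        frequency = count_a / (count_a + count_b)
        p = binom_test_exact(count_a, count_a + count_b)
    sufficient = (count_a + count_b + sum(other.values())) > MIN_VALID_READS
    return QuantResult(count_a, count_b, other, frequency, p, sufficient)


@dataclass(frozen=True)
class HomogeneityResult:
    """Pearson chi-square test of equal haplotype proportions across samples."""

    chi2: float
    df: int
    p: float


def chi2_homogeneity(table: Sequence[Sequence[int]]) -> HomogeneityResult:
    """Chi-square test on an S x 2 table of per-sample haplotype counts.

    Expected counts come from the pooled proportions; df = S - 1.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need an S x 2 count table with S >= 2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("every sample must have at least one counted read")
    res = sps.chi2_contingency(arr, correction=False)
    return HomogeneityResult(chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


def format_pvalue(p: float | None) -> str:
    """Display form: 2 decimals, floored at 2.2e-16 for vanishing values."""
    if p is None:
        return "NA"
    if p < P_DISPLAY_FLOOR:
        return f"<{P_DISPLAY_FLOOR:.1e}"
    return f"{p:.2f}" if p >= 0.005 else f"{p:.2e}"


def write_report_tsv(
    results: Mapping[str, QuantResult],
    dest: Union[str, Path, TextIO],
    homogeneity: HomogeneityResult | None = None,
) -> None:
    """Per-sample report with display-rounded and full-precision columns."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_report_tsv(results, fh, homogeneity)
        return
    dest.write(
        "sample\tcount_A\tcount_B\tother\tfrequency\tp_binomial\t"
        "frequency_full\tp_binomial_full\tsufficient\n"
    )
    for sample, r in results.items():
        freq = "NA" if r.frequency is None else f"{r.frequency:.2f}"
        freq_full = "NA" if r.frequency is None else repr(r.frequency)
        p_full = "NA" if r.p_binomial is None else repr(r.p_binomial)
        dest.write(
            f"{sample}\t{r.count_a}\t{r.count_b}\t{sum(r.other_counts.values())}\t"
            f"{freq}\t{format_pvalue(r.p_binomial)}\t{freq_full}\t{p_full}\t"
            f"{r.sufficient}\n"
        )
    if homogeneity is not None:
        dest.write(
            f"#chi2_homogeneity\tchi2={homogeneity.chi2!r}\tdf={homogeneity.df}\t"
            f"p={format_pvalue(homogeneity.p)}\tp_full={homogeneity.p!r}\n"
        )
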