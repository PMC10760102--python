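"""Core value objects shared across the pipeline.

All genomic coordinates are 0-based half-open (BED convention); the single
conversion point for 1-based inclusive inputs is the minimal-GTF reader in
:mod:`wtct.io`. Peak significance is carried as -log10 of the adjusted
p-value throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end <= start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class Peak:
    """A region with a differential-enrichment significance.

    ``neglog_padj`` is -log10 of the adjusted p-value; regions should have
    passed the upstream FDR < 0.1 filter (neglog_padj > 1) before scoring,
    which the pipeline enforces when loading.
    """

    interval: GenomicInterval
    name: str
    neglog_padj: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.neglog_padj) and self.neglog_padj >= 0):
            raise ValueError(
                f"peak {self.name!r}: neglog_padj must be finite and >= 0, "
                f"got {self.neglog_padj}"
            )


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene with its strand-aware TSS anchor.

    The TSS is ``start`` on the plus strand and ``end - 1`` on the minus
    strand (half-open coordinates); unknown strand "." is treated as plus.
    """

    gene_id: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass(frozen=True, slots=True)
class DEGRecord:
    """Per-gene differential-expression (or -enrichment) result."""

    gene_id: str
    log_fc: float
    log_pv: float
    padj: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_fc):
            raise ValueError(f"{self.gene_id}: non-finite log_fc")
        if not (math.isfinite(self.log_pv) and self.log_pv >= 0):
            raise ValueError(f"{self.gene_id}: log_pv must be >= 0")
        if not (0.0 <= self.padj <= 1.0):
            raise ValueError(
                f"{self.gene_id}: padj outside [0,1]: {self.padj}"
            )


@dataclass(frozen=True, slots=True)
class StateSegment:
    """One segment of a chromatin-state segmentation (e.g. ChromHMM)."""

    interval: GenomicInterval
    state: str


@dataclass(frozen=True, slots=True)
class NESRecord:
    """A normalized enrichment score for one gene-set term."""

    term: str
    nes: float
    background: str = ""


@dataclass(frozen=True, slots=True)
class PeakGeneLink:
    """A peak assigned to a gene: midpoint-to-TSS distance within the window."""

    gene_id: str
    peak_name: str
    distance: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("negative distance")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"weight outside (0,1]: {self.weight}")


@dataclass(frozen=True, slots=True)
class OverlapTest:
    """2x2 genome-bin contingency of two peak sets with its chi-squared test."""

    both: int
    a_only: int
    b_only: int
    neither: int
    chi2: float
    p: float

    @property
    def total(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither


@dataclass(frozen=True, slots=True)
class WtCTScore:
    """Per-gene weighted cistrome-transcriptome score in one background."""

    gene_id: str
    score: float
    background: str = ""
    mode: str = "weighted"

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"{self.gene_id}: negative score")


@dataclass(frozen=True, slots=True)
class ComparisonResult:
    """Two-sided rank-sum comparison of score distributions."""

    background_a: str
    background_b: str
    n_a: int
    n_b: int
    statistic: float
    p: float
    direction: int  # sign of median(a) - median(b)


@dataclass(frozen=True, slots=True)
class ConcordanceCall:
    """Cooperative/antagonistic/unclassified label for one gene."""

    gene_id: str
    sign_a: str | None
    sign_b: str | None
    label: str  # cooperative | antagonistic | unclassified


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """Upper-tail hypergeometric over-representation of one annotated set."""

    set_name: str
    k: int  # overlap of members with the annotated set
    n: int  # number of members drawn
    K: int  # annotated-set size in the universe
    N: int  # universe size
    p: float
    q: float


@dataclass(frozen=True, slots=True)
class PartialCorrResult:
    """Mean marginal vs partial correlation of a regulator with its targets."""

    coregulator: str
    r_mean: float
    r_partial_mean: float
    delta: float
    per_gene: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass(frozen=True, slots=True)
class JaccardBootResult:
    """Top-k Jaccard similarity of two ranked lists with a permutation p."""

    k: int
    jaccard: float
    n_boot: int
    p: float


@dataclass(frozen=True, slots=True)
class IntersectResult:
    """Per-set shared/unique peak counts under the >=1 bp overlap rule."""

    shared_a: int
    unique_a: int
    shared_b: int
    unique_b: int
    pairs: tuple[tuple[str, str], ...]
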