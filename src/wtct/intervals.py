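"""Interval overlap primitives and overlap statistics.

Shared binding between two cistromes is defined by at least 1 bp in common
between peaks; overlap significance is a 2x2 chi-squared on fixed genome
bins; peak-to-gene assignment links every peak whose midpoint lies within
a symmetric window (default 100 kb, inclusive) of a gene's TSS.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .models import (
    GenomicInterval,
    IntersectResult,
    OverlapTest,
    Peak,
    PeakGeneLink,
    StateSegment,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000
DEFAULT_BIN_SIZE = 1_000


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least 1 bp (strand ignored)."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def _by_chrom(peaks: Iterable[Peak]) -> dict[str, list[Peak]]:
    grouped: dict[str, list[Peak]] = defaultdict(list)
    for p in peaks:
        grouped[p.interval.chrom].append(p)
    return grouped


def intersect_sets(
    a: Sequence[Peak], b: Sequence[Peak]
) -> IntersectResult:
    """Shared/unique peak counts of two sets under the >=1 bp rule.

    A peak is shared if it overlaps at least one peak of the other set, so
    the two shared counts need not be equal. The full overlapping pair
    list is returned in (chrom, start) order of set A.
    """
    b_chrom = _by_chrom(b)
    shared_a: set[str] = set()
    shared_b: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for pa in sorted(a, key=lambda p: (p.interval.chrom, p.interval.start)):
        others = b_chrom.get(pa.interval.chrom)
        if not others:
            continue
        starts = np.fromiter((o.interval.start for o in others), dtype=np.int64)
        ends = np.fromiter((o.interval.end for o in others), dtype=np.int64)
        hit = (starts < pa.interval.end) & (ends > pa.interval.start)
        for idx in np.flatnonzero(hit):
            pb = others[idx]
            shared_a.add(pa.name)
            shared_b.add(pb.name)
            pairs.append((pa.name, pb.name))
    return IntersectResult(
        shared_a=len(shared_a),
        unique_a=len(list(a)) - len(shared_a),
        shared_b=len(shared_b),
        unique_b=len(list(b)) - len(shared_b),
        pairs=tuple(pairs),
    )


def _bin_coverage(
    peaks: Iterable[Peak],
    offsets: Mapping[str, int],
    sizes: Mapping[str, int],
    bin_size: int,
    total_bins: int,
) -> np.ndarray:
    cov = np.zeros(total_bins, dtype=bool)
    for p in peaks:
        chrom = p.interval.chrom
        if chrom not in sizes:
            raise ValueError(f"peak {p.name!r} on {chrom!r} not in universe")
        if p.interval.end > sizes[chrom]:
            raise ValueError(
                f"peak {p.name!r} extends beyond {chrom} "
                f"({p.interval.end} > {sizes[chrom]})"
            )
        lo = offsets[chrom] + p.interval.start // bin_size
        hi = offsets[chrom] + (p.interval.end - 1) // bin_size + 1
        cov[lo:hi] = True
    return cov


def overlap_chi2(
    a: Iterable[Peak],
    b: Iterable[Peak],
    universe: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> OverlapTest:
    """Chi-squared association of two peak sets on fixed genome bins.

    The genome is tiled into ``bin_size`` bins; each bin is labelled
    covered/uncovered (>=1 bp) by each set and the 2x2 table is tested
    with a 1-df chi-squared without continuity correction. A zero marginal
    yields p = 1 with a warning.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    offsets: dict[str, int] = {}
    total = 0
    for chrom, size in universe.items():
        offsets[chrom] = total
        total += -(-size // bin_size)
    cov_a = _bin_coverage(a, offsets, universe, bin_size, total)
    cov_b = _bin_coverage(b, offsets, universe, bin_size, total)
    both = int(np.count_nonzero(cov_a & cov_b))
    a_only = int(np.count_nonzero(cov_a & ~cov_b))
    b_only = int(np.count_nonzero(~cov_a & cov_b))
    neither = total - both - a_only - b_only
    row_a, row_b = both + a_only, b_only + neither
    col_a, col_b = both + b_only, a_only + neither
    if 0 in (row_a, row_b, col_a, col_b):
        logger.warning("overlap_chi2: zero marginal, reporting p = 1")
        return OverlapTest(both, a_only, b_only, neither, 0.0, 1.0)
    det = both * neither - a_only * b_only
    chi2 = total * det * det / (row_a * row_b * col_a * col_b)
    p = float(stats.chi2.sf(chi2, df=1))
    return OverlapTest(both, a_only, b_only, neither, float(chi2), p)


def annotate_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Iterable,
    window: int = DEFAULT_WINDOW,
) -> list[PeakGeneLink]:
    """Link every peak to every gene with |midpoint - TSS| <= window.

    The boundary is inclusive; a peak may link to several genes and a gene
    to several peaks. Weights are left at 1 (set during scoring).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    chrom_mids: dict[str, np.ndarray] = {}
    chrom_names: dict[str, list[str]] = {}
    for chrom, group in _by_chrom(peaks).items():
        group = sorted(group, key=lambda p: p.interval.midpoint)
        chrom_mids[chrom] = np.array(
            [p.interval.midpoint for p in group], dtype=float
        )
        chrom_names[chrom] = [p.name for p in group]
    links: list[PeakGeneLink] = []
    for gene in genes:
        mids = chrom_mids.get(gene.interval.chrom)
        if mids is None:
            continue
        tss = gene.tss
        lo = int(np.searchsorted(mids, tss - window, side="left"))
        hi = int(np.searchsorted(mids, tss + window, side="right"))
        names = chrom_names[gene.interval.chrom]
        links.extend(
            PeakGeneLink(gene.gene_id, names[i], abs(mids[i] - tss))
            for i in range(lo, hi)
        )
    return links


def stratify_by_states(
    peaks: Iterable[Peak],
    segments: Sequence[StateSegment],
) -> dict[str, list[Peak]]:
    """Assign peaks to every chromatin state they overlap by >=1 bp.

    Peaks overlapping no segment are collected under ``"unassigned"``.
    Overlapping segments within the segmentation are an error.
    """
    seg_chrom: dict[str, list[StateSegment]] = defaultdict(list)
    for s in segments:
        seg_chrom[s.interval.chrom].append(s)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, group in seg_chrom.items():
        group.sort(key=lambda s: s.interval.start)
        for prev, nxt in zip(group, group[1:]):
            if nxt.interval.start < prev.interval.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"[{prev.interval.start},{prev.interval.end}) and "
                    f"[{nxt.interval.start},{nxt.interval.end})"
                )
        seg_chrom[chrom] = group
        starts[chrom] = np.array([s.interval.start for s in group], dtype=np.int64)
        ends[chrom] = np.array([s.interval.end for s in group], dtype=np.int64)
    out: dict[str, list[Peak]] = defaultdict(list)
    for p in peaks:
        chrom = p.interval.chrom
        assigned = False
        if chrom in seg_chrom:
            # segments are disjoint and sorted, so ends are sorted too
            lo = int(np.searchsorted(ends[chrom], p.interval.start, side="right"))
            hi = int(np.searchsorted(starts[chrom], p.interval.end, side="left"))
            for i in range(lo, hi):
                out[seg_chrom[chrom][i].state].append(p)
                assigned = True
        if not assigned:
            out["unassigned"].append(p)
    return dict(out)
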