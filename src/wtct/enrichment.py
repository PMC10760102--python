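"""DE filtering, hypergeometric set over-representation and delta-NES.

Over-representation of an annotated class (e.g. coactivators inside a
protein-complex membership list) is tested one-sided with the upper-tail
hypergeometric p = P(X >= k); BH adjustment is applied across the sets
tested in one call. Delta-NES subtracts a reference background's
normalized enrichment score from a variant's, per gene-set term.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .models import DEGRecord, EnrichmentResult, NESRecord
from .scoring import bh_adjust

logger = logging.getLogger(__name__)

# (log_pv_min, abs_fc_min) presets for the two assay families
DE_PRESETS: dict[str, tuple[float, float]] = {
    "rna": (1.0, 0.37),
    "proteomics": (1.3, 0.37),
}


def filter_de(
    records: Iterable[DEGRecord],
    log_pv_min: float = 1.0,
    abs_fc_min: float = 0.37,
) -> list[DEGRecord]:
    """Keep records with log_pv > log_pv_min and |log_fc| > abs_fc_min."""
    if log_pv_min < 0 or abs_fc_min < 0:
        raise ValueError("thresholds must be >= 0")
    return [
        r for r in records
        if r.log_pv > log_pv_min and abs(r.log_fc) > abs_fc_min
    ]


def hypergeom_test(
    members: Iterable[str],
    annotated_set: Iterable[str],
    universe: Iterable[str],
    set_name: str = "set",
) -> EnrichmentResult:
    """Upper-tail hypergeometric p for one annotated set.

    ``members`` must be a subset of the universe; annotated elements
    outside the universe are dropped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    members = set(members)
    stray = members - universe
    if stray:
        raise ValueError(
            f"{len(stray)} member(s) outside the universe, e.g. "
            f"{sorted(stray)[:3]}"
        )
    annotated = set(annotated_set)
    dropped = annotated - universe
    if dropped:
        logger.warning(
            "%s: dropped %d annotated element(s) outside the universe",
            set_name, len(dropped),
        )
        annotated &= universe
    N, K, n = len(universe), len(annotated), len(members)
    k = len(members & annotated)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
    return EnrichmentResult(set_name, k, n, K, N, min(p, 1.0), min(p, 1.0))


def hypergeom_enrichment(
    members: Iterable[str],
    annotated_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Test several annotated sets; q is BH-adjusted across this call."""
    universe = set(universe)
    members = set(members)
    raw = [
        hypergeom_test(members, annotated, universe, set_name=name)
        for name, annotated in annotated_sets.items()
    ]
    qs = bh_adjust([r.p for r in raw])
    return [
        EnrichmentResult(r.set_name, r.k, r.n, r.K, r.N, r.p, q)
        for r, q in zip(raw, qs)
    ]


@dataclass(frozen=True, slots=True)
class DeltaNESRow:
    term: str
    nes_variant: float
    nes_reference: float
    delta: float


@dataclass(frozen=True, slots=True)
class DeltaNESTable:
    """Per-term NES difference; one-sided terms are listed, not imputed."""

    rows: tuple[DeltaNESRow, ...]
    variant_only: tuple[str, ...]
    reference_only: tuple[str, ...]


def delta_nes(
    nes_variant: Sequence[NESRecord],
    nes_reference: Sequence[NESRecord],
) -> DeltaNESTable:
    """NES(variant) - NES(reference) for terms present in both tables."""
    var = _index_terms(nes_variant, "variant")
    ref = _index_terms(nes_reference, "reference")
    shared = [t for t in var if t in ref]
    rows = tuple(
        DeltaNESRow(t, var[t], ref[t], var[t] - ref[t]) for t in shared
    )
    return DeltaNESTable(
        rows=rows,
        variant_only=tuple(t for t in var if t not in ref),
        reference_only=tuple(t for t in ref if t not in var),
    )


def _index_terms(records: Sequence[NESRecord], label: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for rec in records:
        if rec.term in out:
            raise ValueError(f"{label}: duplicate term {rec.term!r}")
        out[rec.term] = rec.nes
    return out
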