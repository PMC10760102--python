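"""Cooperative vs antagonistic gene classification across two contrasts.

A gene significant in both contrasts is cooperative when its direction of
change is the same in both and antagonistic when opposite; everything
else — absent, non-significant, or a significant record with log_fc = 0 —
is unclassified. Significance uses the DEG filter (strict logPV and |FC|
thresholds, default logPV > 1 and |FC| > 0.37).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import stats

from .models import ConcordanceCall, DEGRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class SigRule:
    """Strict-inequality significance thresholds for a DE record."""

    log_pv_min: float = 1.0
    abs_fc_min: float = 0.37

    def __post_init__(self) -> None:
        if self.log_pv_min < 0 or self.abs_fc_min < 0:
            raise ValueError("thresholds must be >= 0")

    def passes(self, rec: DEGRecord | None) -> bool:
        return (
            rec is not None
            and rec.log_pv > self.log_pv_min
            and abs(rec.log_fc) > self.abs_fc_min
        )


def _sign(rec: DEGRecord | None) -> str | None:
    if rec is None or rec.log_fc == 0:
        return None
    return "+" if rec.log_fc > 0 else "-"


def classify_gene(
    rec_a: DEGRecord | None,
    rec_b: DEGRecord | None,
    sig_rule: SigRule = SigRule(),
) -> ConcordanceCall:
    """Label one gene from its (possibly absent) records in two contrasts."""
    if rec_a is None and rec_b is None:
        raise ValueError("gene absent from both contrasts")
    if rec_a is not None and rec_b is not None and rec_a.gene_id != rec_b.gene_id:
        raise ValueError(
            f"mismatched genes: {rec_a.gene_id!r} vs {rec_b.gene_id!r}"
        )
    gene_id = rec_a.gene_id if rec_a is not None else rec_b.gene_id
    sign_a, sign_b = _sign(rec_a), _sign(rec_b)
    if sig_rule.passes(rec_a) and sig_rule.passes(rec_b):
        if sign_a is None or sign_b is None:
            # |log_fc| > abs_fc_min > 0 rules this out unless abs_fc_min == 0
            logger.info("%s: significant with log_fc = 0, unclassified", gene_id)
            label = "unclassified"
        else:
            label = "cooperative" if sign_a == sign_b else "antagonistic"
    else:
        label = "unclassified"
    return ConcordanceCall(gene_id, sign_a, sign_b, label)


@dataclass(frozen=True, slots=True)
class ConcordanceSummary:
    """Counts over the union of genes present in either contrast."""

    n_cooperative: int
    n_antagonistic: int
    n_unclassified: int
    n_union: int
    n_both_significant: int
    frac_antagonistic_shared: float  # over both-significant genes
    frac_antagonistic_union: float  # over the whole union
    calls: tuple[ConcordanceCall, ...] = field(default_factory=tuple)


def concordance_summary(
    contrast_a: Iterable[DEGRecord],
    contrast_b: Iterable[DEGRecord],
    sig_rule: SigRule = SigRule(),
) -> ConcordanceSummary:
    """Classify every gene in the union of two contrasts and tally labels.

    Counts always satisfy cooperative + antagonistic + unclassified =
    |union|. The antagonistic fraction is reported both over
    both-significant genes and over the union.
    """
    map_a = _index(contrast_a, "contrast_a")
    map_b = _index(contrast_b, "contrast_b")
    union = sorted(set(map_a) | set(map_b))
    if not union:
        raise ValueError("empty union of contrasts")
    calls = tuple(
        classify_gene(map_a.get(g), map_b.get(g), sig_rule) for g in union
    )
    n_coop = sum(c.label == "cooperative" for c in calls)
    n_ant = sum(c.label == "antagonistic" for c in calls)
    n_unc = len(calls) - n_coop - n_ant
    n_both = sum(
        sig_rule.passes(map_a.get(g)) and sig_rule.passes(map_b.get(g))
        for g in union
    )
    return ConcordanceSummary(
        n_cooperative=n_coop,
        n_antagonistic=n_ant,
        n_unclassified=n_unc,
        n_union=len(union),
        n_both_significant=n_both,
        frac_antagonistic_shared=n_ant / n_both if n_both else 0.0,
        frac_antagonistic_union=n_ant / len(union),
        calls=calls,
    )


def _index(records: Iterable[DEGRecord], label: str) -> Mapping[str, DEGRecord]:
    out: dict[str, DEGRecord] = {}
    for rec in records:
        if rec.gene_id in out:
            raise ValueError(f"{label}: duplicate gene {rec.gene_id!r}")
        out[rec.gene_id] = rec
    return out


def compare_antagonism(
    summary_a: ConcordanceSummary, summary_b: ConcordanceSummary
) -> tuple[float, float]:
    """Two-proportion chi-squared on antagonistic fractions (shared genes).

    Returns (chi2, p); a degenerate table yields p = 1 with a warning.
    """
    k1, n1 = summary_a.n_antagonistic, summary_a.n_both_significant
    k2, n2 = summary_b.n_antagonistic, summary_b.n_both_significant
    if n1 == 0 or n2 == 0:
        raise ValueError("no both-significant genes in one summary")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
        logger.warning("compare_antagonism: degenerate table, p = 1")
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
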