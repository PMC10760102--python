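"""Delta partial correlation and bootstrap Jaccard similarity.

``delta_corr`` measures how much of a regulator-target correlation is
routed through a coregulator: for each target gene it computes the Pearson
correlation r(regulator, gene) and the first-order partial correlation
r(regulator, gene | coregulator), averages both over the target set, and
reports delta = mean(r) - mean(r_partial). A positive delta means the
coregulator accounts for part of the regulator-target relationship.

``ranked_jaccard_boot`` compares the top-k sets of two ranked gene lists
with the Jaccard index and calibrates it against a permutation null of
one list's ranking (the add-one estimator keeps p > 0).
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import JaccardBootResult, PartialCorrResult


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-d and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate vector (zero variance)")
    return float(np.corrcoef(x, y)[0, 1])


def partial_corr_from_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation from the three pairwise r values."""
    if abs(r_xz) >= 1 or abs(r_yz) >= 1:
        raise ValueError("collinear with conditioning variable")
    return (r_xy - r_xz * r_yz) / math.sqrt(
        (1.0 - r_xz**2) * (1.0 - r_yz**2)
    )


def partial_corr(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> float:
    """Pearson correlation of x and y after removing z (first order)."""
    return partial_corr_from_r(pearson(x, y), pearson(x, z), pearson(y, z))


def delta_corr(
    expr: pd.DataFrame,
    regulator: str,
    target_set: Sequence[str],
    coregulator: str,
    method: str = "pearson",
) -> PartialCorrResult:
    """Mean correlation vs mean partial correlation over a target set.

    ``expr`` is a samples x genes matrix; ``method`` may be ``pearson``
    or ``spearman`` (rank-transform first, then the same algebra).
    """
    if len(target_set) == 0:
        raise ValueError("empty target set")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method!r}")
    missing = [c for c in [regulator, coregulator, *target_set]
               if c not in expr.columns]
    if missing:
        raise ValueError(f"columns not in matrix: {missing[:5]}")
    if len(expr) < 3:
        raise ValueError("need at least 3 samples")

    def col(name: str) -> np.ndarray:
        v = expr[name].to_numpy(dtype=float)
        return stats.rankdata(v) if method == "spearman" else v

    reg = col(regulator)
    coreg = col(coregulator)
    r_rc = pearson(reg, coreg)
    per_gene: dict[str, tuple[float, float]] = {}
    for gene in target_set:
        g = col(gene)
        r = pearson(reg, g)
        rp = partial_corr_from_r(r, r_rc, pearson(g, coreg))
        per_gene[gene] = (r, rp)
    r_mean = float(np.mean([v[0] for v in per_gene.values()]))
    rp_mean = float(np.mean([v[1] for v in per_gene.values()]))
    return PartialCorrResult(
        coregulator=coregulator,
        r_mean=r_mean,
        r_partial_mean=rp_mean,
        delta=r_mean - rp_mean,
        per_gene=per_gene,
    )


def topk_jaccard(list_a: Sequence[str], list_b: Sequence[str], k: int) -> float:
    """Jaccard index of the top-k sets of two ranked lists."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(len(list_a), len(list_b)):
        raise ValueError("k exceeds a list length")
    top_a, top_b = set(list_a[:k]), set(list_b[:k])
    return len(top_a & top_b) / len(top_a | top_b)


def ranked_jaccard_boot(
    list_a: Sequence[str],
    list_b: Sequence[str],
    k: int,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> JaccardBootResult:
    """Top-k Jaccard with a permutation-null p-value.

    The null permutes list_b's ranking ``n_boot`` times (seeded) and
    recomputes the top-k Jaccard; p = (1 + #{J_null >= J_obs}) /
    (n_boot + 1).
    """
    for name, lst in (("list_a", list_a), ("list_b", list_b)):
        if len(set(lst)) != len(lst):
            raise ValueError(f"{name} contains duplicate ids")
    j_obs = topk_jaccard(list_a, list_b, k)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    top_a = set(list_a[:k])
    member = np.fromiter((x in top_a for x in list_b), dtype=bool,
                         count=len(list_b))
    n = len(list_b)
    exceed = 0
    for _ in range(n_boot):
        inter = int(member[rng.choice(n, size=k, replace=False)].sum())
        j_null = inter / (2 * k - inter)
        if j_null >= j_obs:
            exceed += 1
    return JaccardBootResult(
        k=k,
        jaccard=j_obs,
        n_boot=n_boot,
        p=(1 + exceed) / (n_boot + 1),
    )
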