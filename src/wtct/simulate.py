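"""Seeded synthetic data with planted, recoverable effects.

Every generator is a pure function of :class:`SimConfig`: one global seed,
with a fixed per-generator substream derived from it, so composite
pipelines are reproducible byte-for-byte. The generators plant the exact
structure the downstream statistics look for:

* peaks whose placement is coupled to the TSSs of a designated target-gene
  subset whose |logFC| is boosted (wt-C-T power / type-I surface);
* paired DE contrasts with an exact planted antagonism fraction;
* an expression matrix following a latent-factor model whose marginal and
  partial correlations have closed forms;
* two ranked lists with an exact planted top-k overlap.

Noise laws are deliberately simple and stated: Gaussian expression noise,
shifted-exponential peak significance (1 + Exp(1) on the -log10 scale, so
every peak passes FDR < 0.1), uniform placement. Truth labels accompany
every dataset.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .models import DEGRecord, GeneModel, GenomicInterval, Peak, StateSegment

WINDOW = 100_000

# substream tags, fixed forever so adding a generator never shifts streams
_S_GENOME, _S_PEAKS, _S_CONTRASTS, _S_EXPR, _S_RANKS, _S_STATES = range(1, 7)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixture.

    Defaults are the conditions exercised throughout the test surface:
    two 10 Mb chromosomes, 300 genes, 600 peaks with 90% coupling and a
    mean |logFC| bonus of 1.0 for coupled genes, a 30% antagonism fraction,
    latent-factor loadings of 0.5 and a 50% planted top-k overlap.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 10_000_000
    n_genes: int = 300
    n_peaks: int = 600
    coupling: float = 0.9
    effect_fc: float = 1.0
    frac_antagonistic: float = 0.3
    confounder_loading: float = 0.5
    loading_a: float = 0.5  # latent factor -> regulator
    loading_b: float = 0.5  # regulator -> target
    loading_c: float = 0.5  # latent factor -> target
    n_samples: int = 1000
    n_expr_targets: int = 20
    top_k_overlap: float = 0.5
    frac_target_genes: float = 0.2
    gene_len: int = 2_000
    peak_len: int = 400

    def __post_init__(self) -> None:
        for name in ("coupling", "frac_antagonistic", "top_k_overlap",
                     "frac_target_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        for name in ("n_chrom", "chrom_len", "n_peaks", "n_samples",
                     "n_expr_targets", "gene_len", "peak_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.effect_fc < 0:
            raise ValueError("effect_fc must be >= 0")
        if self.chrom_len <= 2 * WINDOW:
            raise ValueError(
                f"chrom_len must exceed twice the {WINDOW} bp window"
            )


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def _chrom_names(cfg: SimConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(cfg.n_chrom)]


def chrom_sizes(cfg: SimConfig) -> dict[str, int]:
    return {c: cfg.chrom_len for c in _chrom_names(cfg)}


def make_genome_and_genes(
    cfg: SimConfig,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Uniformly placed genes with unique TSSs, round-robin over chromosomes."""
    rng = _rng(cfg, _S_GENOME)
    sizes = chrom_sizes(cfg)
    names = _chrom_names(cfg)
    per_chrom = [cfg.n_genes // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_genes % cfg.n_chrom):
        per_chrom[i] += 1
    capacity = cfg.chrom_len - cfg.gene_len
    if max(per_chrom, default=0) > capacity:
        raise ValueError("n_genes exceeds placeable capacity")
    genes: list[GeneModel] = []
    idx = 0
    for chrom, count in zip(names, per_chrom):
        tss_seen: set[int] = set()
        placed = 0
        while placed < count:
            start = int(rng.integers(0, capacity))
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else start + cfg.gene_len - 1
            if tss in tss_seen:
                continue
            tss_seen.add(tss)
            idx += 1
            genes.append(
                GeneModel(
                    f"G{idx:05d}",
                    GenomicInterval(chrom, start, start + cfg.gene_len, strand),
                )
            )
            placed += 1
    return genes, sizes


def make_coupled_peaks_and_de(
    genes: list[GeneModel], cfg: SimConfig
) -> tuple[list[Peak], list[DEGRecord], dict[str, list[str]]]:
    """Peaks coupled to a target-gene subset, plus a matched DE table.

    A fraction ``coupling`` of peaks is placed with its midpoint within
    the 100 kb window of a randomly chosen designated target gene; the
    rest are uniform. Target genes that received at least one coupled
    peak get an exponential |logFC| bonus with mean ``effect_fc``, so
    ``coupling = 0`` is an exact null. Peak -log10(adjusted p) is
    1 + Exp(1), i.e. every peak passes FDR < 0.1.
    """
    if not genes:
        raise ValueError("gene catalog is empty")
    rng = _rng(cfg, _S_PEAKS)
    n = len(genes)
    n_targets = int(round(cfg.frac_target_genes * n))
    target_idx = np.sort(rng.choice(n, size=n_targets, replace=False))
    target_ids = [genes[i].gene_id for i in target_idx]

    n_coupled = int(round(cfg.coupling * cfg.n_peaks))
    half = cfg.peak_len // 2
    peaks: list[Peak] = []
    coupled_idx: set[int] = set()
    nlp = 1.0 + rng.exponential(1.0, size=cfg.n_peaks)
    chroms = _chrom_names(cfg)
    for i in range(cfg.n_peaks):
        if i < n_coupled and n_targets > 0:
            gi = int(target_idx[rng.integers(n_targets)])
            coupled_idx.add(gi)
            gene = genes[gi]
            mid = gene.tss + rng.uniform(-WINDOW, WINDOW)
            mid = float(np.clip(mid, half, cfg.chrom_len - half))
            chrom = gene.interval.chrom
            start = int(round(mid)) - half
        else:
            chrom = chroms[int(rng.integers(cfg.n_chrom))]
            start = int(rng.integers(0, cfg.chrom_len - cfg.peak_len))
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, start + cfg.peak_len),
                f"pk{i + 1:05d}",
                float(nlp[i]),
                "sim",
            )
        )

    coupled_ids = {genes[i].gene_id for i in coupled_idx}
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    mag = np.abs(rng.normal(0.0, 0.5, size=n))
    bonus = rng.exponential(cfg.effect_fc, size=n) if cfg.effect_fc > 0 else (
        np.zeros(n)
    )
    log_pv = 1.05 + rng.exponential(1.0, size=n)
    degs: list[DEGRecord] = []
    for i, gene in enumerate(genes):
        m = mag[i] + (bonus[i] if gene.gene_id in coupled_ids else 0.0)
        degs.append(
            DEGRecord(
                gene.gene_id,
                float(sign[i] * m),
                float(log_pv[i]),
                float(min(1.0, 10.0 ** -log_pv[i])),
            )
        )
    truth = {
        "target_genes": target_ids,
        "coupled_genes": sorted(coupled_ids),
    }
    return peaks, degs, truth


def make_paired_contrasts(
    genes: list[GeneModel], cfg: SimConfig, n_shared: int | None = None
) -> tuple[list[DEGRecord], list[DEGRecord], dict[str, list[str]]]:
    """Two DE contrasts with an exact planted antagonism fraction.

    Exactly round(frac_antagonistic * n_shared) of the genes significant
    in both contrasts flip sign between them; the remaining genes are
    split between significant-in-one-only (absent from the other) and
    present-but-non-significant in both.
    """
    if not genes:
        raise ValueError("gene catalog is empty")
    rng = _rng(cfg, _S_CONTRASTS)
    n = len(genes)
    if n_shared is None:
        n_shared = (2 * n) // 3
    if n_shared > n:
        raise ValueError("n_shared exceeds the gene catalog")
    perm = rng.permutation(n)
    shared = perm[:n_shared]
    rest = perm[n_shared:]
    third = len(rest) // 3
    a_only, b_only, neither = rest[:third], rest[third:2 * third], rest[2 * third:]

    n_ant = int(round(cfg.frac_antagonistic * n_shared))
    ant = set(shared[:n_ant].tolist())

    def sig_record(gid: str, sign: float) -> DEGRecord:
        mag = 0.38 + rng.exponential(0.5)
        lpv = 1.05 + rng.exponential(1.0)
        return DEGRecord(gid, float(sign * mag), float(lpv),
                         float(min(1.0, 10.0 ** -lpv)))

    def dull_record(gid: str) -> DEGRecord:
        return DEGRecord(gid, float(rng.uniform(-0.2, 0.2)),
                         float(rng.uniform(0.0, 0.8)), 1.0)

    contrast_a: list[DEGRecord] = []
    contrast_b: list[DEGRecord] = []
    truth_ant: list[str] = []
    truth_coop: list[str] = []
    for i in shared:
        gid = genes[int(i)].gene_id
        sign_a = -1.0 if rng.random() < 0.5 else 1.0
        contrast_a.append(sig_record(gid, sign_a))
        if int(i) in ant:
            contrast_b.append(sig_record(gid, -sign_a))
            truth_ant.append(gid)
        else:
            contrast_b.append(sig_record(gid, sign_a))
            truth_coop.append(gid)
    for i in a_only:
        contrast_a.append(sig_record(genes[int(i)].gene_id,
                                     -1.0 if rng.random() < 0.5 else 1.0))
    for i in b_only:
        contrast_b.append(sig_record(genes[int(i)].gene_id,
                                     -1.0 if rng.random() < 0.5 else 1.0))
    for i in neither:
        gid = genes[int(i)].gene_id
        contrast_a.append(dull_record(gid))
        contrast_b.append(dull_record(gid))
    truth = {"antagonistic": sorted(truth_ant), "cooperative": sorted(truth_coop)}
    return contrast_a, contrast_b, truth


def analytic_delta_corr(cfg: SimConfig) -> tuple[float, float, float]:
    """Closed-form (r, r_partial, delta) of the latent-factor model.

    With F, noises ~ N(0,1) i.i.d., C = lam*F + e, R = a*F + e and
    T = b*R + c*F + e the covariances follow from the linear structure.
    """
    a, b, c, lam = (cfg.loading_a, cfg.loading_b, cfg.loading_c,
                    cfg.confounder_loading)
    var_r = a * a + 1.0
    var_c = lam * lam + 1.0
    var_t = b * b * var_r + c * c + 2.0 * a * b * c + 1.0
    cov_rt = b * var_r + a * c
    cov_rc = a * lam
    cov_ct = lam * (a * b + c)
    r_rt = cov_rt / np.sqrt(var_r * var_t)
    r_rc = cov_rc / np.sqrt(var_r * var_c)
    r_ct = cov_ct / np.sqrt(var_c * var_t)
    rp = (r_rt - r_rc * r_ct) / np.sqrt((1 - r_rc**2) * (1 - r_ct**2))
    return float(r_rt), float(rp), float(r_rt - rp)


def make_expression_matrix(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Samples x genes matrix from the latent-factor model.

    Columns: REG (regulator), COREG (coregulator), T0001..T{n} (targets).
    The truth dict carries the loadings and the analytic correlations.
    """
    rng = _rng(cfg, _S_EXPR)
    n, m = cfg.n_samples, cfg.n_expr_targets
    a, b, c, lam = (cfg.loading_a, cfg.loading_b, cfg.loading_c,
                    cfg.confounder_loading)
    factor = rng.standard_normal(n)
    coreg = lam * factor + rng.standard_normal(n)
    reg = a * factor + rng.standard_normal(n)
    targets = (
        b * reg[:, None] + c * factor[:, None] + rng.standard_normal((n, m))
    )
    cols = {"REG": reg, "COREG": coreg}
    for j in range(m):
        cols[f"T{j + 1:04d}"] = targets[:, j]
    df = pd.DataFrame(cols, index=[f"S{i + 1:05d}" for i in range(n)])
    df.index.name = "sample"
    r, rp, delta = analytic_delta_corr(cfg)
    truth = {
        "loading_a": a, "loading_b": b, "loading_c": c,
        "confounder_loading": lam,
        "analytic_r": r, "analytic_r_partial": rp, "analytic_delta": delta,
    }
    return df, truth


def make_ranked_lists(
    cfg: SimConfig, n_items: int = 1000, k: int = 100
) -> tuple[list[str], list[str], dict[str, float]]:
    """Two ranked id lists whose top-k sets share an exact planted overlap."""
    if not 0 < k <= n_items:
        raise ValueError("k must lie in (0, n_items]")
    rng = _rng(cfg, _S_RANKS)
    ids = np.array([f"L{i:05d}" for i in range(n_items)])
    list_a = ids[rng.permutation(n_items)]
    top_a = list_a[:k]
    rest_a = list_a[k:]
    n_overlap = int(round(cfg.top_k_overlap * k))
    from_top = top_a[rng.choice(k, size=n_overlap, replace=False)]
    from_rest = rest_a[rng.choice(len(rest_a), size=k - n_overlap,
                                  replace=False)]
    top_b = np.concatenate([from_top, from_rest])
    top_b = top_b[rng.permutation(k)]
    tail_pool = ids[~np.isin(ids, top_b)]
    tail_b = tail_pool[rng.permutation(len(tail_pool))]
    list_b = np.concatenate([top_b, tail_b])
    truth = {
        "k": float(k),
        "planted_overlap": float(n_overlap),
        "expected_jaccard": n_overlap / (2 * k - n_overlap),
    }
    return list_a.tolist(), list_b.tolist(), truth


STATE_LABELS = ("Active Enhancer", "Promoter", "Quiescent", "Heterochromatin")


def make_state_segmentation(cfg: SimConfig) -> list[StateSegment]:
    """A contiguous, non-overlapping chromatin-state tiling per chromosome."""
    rng = _rng(cfg, _S_STATES)
    segments: list[StateSegment] = []
    for chrom in _chrom_names(cfg):
        pos = 0
        while pos < cfg.chrom_len:
            length = int(rng.integers(20_000, 100_000))
            end = min(pos + length, cfg.chrom_len)
            state = STATE_LABELS[int(rng.integers(len(STATE_LABELS)))]
            segments.append(
                StateSegment(GenomicInterval(chrom, pos, end), state)
            )
            pos = end
    return segments


def write_fixture(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a self-contained fixture directory plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, sizes = make_genome_and_genes(cfg)
    peaks, degs, truth_peaks = make_coupled_peaks_and_de(genes, cfg)
    de_a, de_b, truth_pairs = make_paired_contrasts(genes, cfg)
    expr, truth_expr = make_expression_matrix(cfg)
    list_a, list_b, truth_ranks = make_ranked_lists(cfg)
    states = make_state_segmentation(cfg)

    paths = {
        "genes": outdir / "genes.bed",
        "peaks": outdir / "peaks.tsv",
        "de": outdir / "de.tsv",
        "de_a": outdir / "de_a.tsv",
        "de_b": outdir / "de_b.tsv",
        "matrix": outdir / "expression.tsv",
        "list_a": outdir / "list_a.txt",
        "list_b": outdir / "list_b.txt",
        "states": outdir / "states.bed",
        "chrom_sizes": outdir / "chrom_sizes.tsv",
        "truth": outdir / "truth.json",
    }
    wio.write_genes(genes, paths["genes"])
    wio.write_peaks(peaks, paths["peaks"])
    wio.write_de_table(degs, paths["de"])
    wio.write_de_table(de_a, paths["de_a"])
    wio.write_de_table(de_b, paths["de_b"])
    wio.write_expression_matrix(expr, paths["matrix"])
    wio.write_id_list(list_a, paths["list_a"])
    wio.write_id_list(list_b, paths["list_b"])
    wio.write_segments(states, paths["states"])
    wio.write_chrom_sizes(sizes, paths["chrom_sizes"])
    truth = {
        "config": asdict(cfg),
        "coupled_peaks_and_de": truth_peaks,
        "paired_contrasts": truth_pairs,
        "expression": truth_expr,
        "ranked_lists": truth_ranks,
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
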