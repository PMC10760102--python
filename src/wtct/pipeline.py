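"""Stage orchestration over a file manifest.

Stages run in dependency order (filter -> annotate -> score -> compare;
overlap, concordance, enrichment and association are independent). Every
output table starts with two comment lines carrying the config hash and
seed, and re-running with identical inputs and config is byte-identical.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import assoc, concordance, enrichment, intervals, io as wio, scoring
from .config import AnalysisConfig

logger = logging.getLogger(__name__)

STAGE_INPUTS: dict[str, tuple[str, ...]] = {
    "annotate": ("peaks", "genes"),
    "wtct": ("peaks", "genes", "de"),
    "compare": ("peaks", "genes", "de", "peaks_b"),
    "overlap": ("peaks", "peaks_b", "chrom_sizes"),
    "concord": ("de_a", "de_b"),
    "enrich": ("members", "sets"),
    "assoc": ("matrix", "regulator", "targets", "coregulators"),
    "jaccard": ("list_a", "list_b"),
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _write(df: pd.DataFrame, path: Path, config: AnalysisConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config.config_hash()}\n")
        fh.write(f"# seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _load_peaks(manifest, key, config):
    peaks = wio.read_peaks(manifest[key], format="tsv")
    cutoff = -math.log10(config.region_fdr_max)
    kept = [p for p in peaks if p.neglog_padj > cutoff]
    if len(kept) < len(peaks):
        logger.info(
            "%s: %d/%d region(s) pass FDR < %g",
            key, len(kept), len(peaks), config.region_fdr_max,
        )
    return kept


def run_pipeline(
    config: AnalysisConfig,
    manifest: Mapping[str, str],
    outdir: str | Path,
    stages: list[str] | None = None,
) -> dict[str, Path]:
    """Run the requested stages (default: all whose inputs are present)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = [
            s for s, needs in STAGE_INPUTS.items()
            if all(k in manifest for k in needs)
        ]
    log_lines: list[str] = []
    handler = _ListHandler(log_lines)
    root = logging.getLogger("wtct")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}
    try:
        for stage in stages:
            if stage not in STAGE_INPUTS:
                raise PipelineError(f"{stage}: unknown stage")
            missing = [k for k in STAGE_INPUTS[stage] if k not in manifest]
            if missing:
                raise PipelineError(
                    f"{stage}: missing required input(s) {missing}"
                )
            try:
                outputs[stage] = _RUNNERS[stage](config, manifest, outdir)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{stage}: {exc}") from exc
            logger.info("stage %s done -> %s", stage, outputs[stage].name)
    finally:
        root.removeHandler(handler)
    logpath = outdir / "run.log"
    with open(logpath, "w", encoding="utf-8") as fh:
        fh.write(f"config_hash={config.config_hash()} seed={config.seed}\n")
        fh.write(
            f"thresholds: window={config.window} mode={config.wtct_mode} "
            f"de={config.sig_thresholds} region_fdr_max={config.region_fdr_max} "
            f"bin_size={config.bin_size} n_boot={config.n_boot}\n"
        )
        fh.writelines(line + "\n" for line in log_lines)
    outputs["log"] = logpath
    return outputs


class _ListHandler(logging.Handler):
    def __init__(self, sink: list[str]) -> None:
        super().__init__()
        self.sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append(f"{record.levelname} {record.name}: {record.getMessage()}")


def _genes(manifest):
    return wio.read_genes(manifest["genes"], format="bed6")


def _stage_annotate(config, manifest, outdir) -> Path:
    peaks = _load_peaks(manifest, "peaks", config)
    links = intervals.annotate_peaks_to_genes(
        peaks, _genes(manifest), window=config.window
    )
    df = pd.DataFrame(
        [(l.gene_id, l.peak_name, l.distance) for l in links],
        columns=["gene_id", "peak_name", "distance"],
    )
    path = outdir / "links.tsv"
    _write(df, path, config)
    return path


def _score_table(config, manifest, peaks_key, de_key, background):
    peaks = _load_peaks(manifest, peaks_key, config)
    degs = wio.read_de_table(manifest[de_key])
    state_filter = None
    if config.state is not None:
        if "states" not in manifest:
            raise PipelineError("wtct: state filter set but no 'states' input")
        state_filter = (config.state, wio.read_segments(manifest["states"]))
    return scoring.wtct_table(
        peaks, _genes(manifest), degs, window=config.window,
        mode=config.wtct_mode, state_filter=state_filter,
        background=background,
    )


def _stage_wtct(config, manifest, outdir) -> Path:
    scores = _score_table(config, manifest, "peaks", "de", "a")
    df = pd.DataFrame(
        [(s.gene_id, repr(s.score), s.background, s.mode) for s in scores],
        columns=["gene_id", "score", "background", "mode"],
    )
    path = outdir / "wtct.tsv"
    _write(df, path, config)
    return path


def _stage_compare(config, manifest, outdir) -> Path:
    scores_a = _score_table(config, manifest, "peaks", "de", "a")
    de_b = "de_b" if "de_b" in manifest else "de"
    scores_b = _score_table(config, manifest, "peaks_b", de_b, "b")
    res = scoring.compare_wtct(scores_a, scores_b)
    df = pd.DataFrame(
        [(res.background_a, res.background_b, res.n_a, res.n_b,
          repr(res.statistic), repr(res.p), res.direction)],
        columns=["background_a", "background_b", "n_a", "n_b", "statistic",
                 "p", "direction"],
    )
    path = outdir / "comparison.tsv"
    _write(df, path, config)
    return path


def _stage_overlap(config, manifest, outdir) -> Path:
    peaks_a = wio.read_peaks(manifest["peaks"], format="tsv")
    peaks_b = wio.read_peaks(manifest["peaks_b"], format="tsv")
    sizes = wio.read_chrom_sizes(manifest["chrom_sizes"])
    test = intervals.overlap_chi2(peaks_a, peaks_b, sizes,
                                  bin_size=config.bin_size)
    inter = intervals.intersect_sets(peaks_a, peaks_b)
    df = pd.DataFrame(
        [(test.both, test.a_only, test.b_only, test.neither,
          repr(test.chi2), repr(test.p), inter.shared_a, inter.unique_a,
          inter.shared_b, inter.unique_b)],
        columns=["bins_both", "bins_a_only", "bins_b_only", "bins_neither",
                 "chi2", "p", "shared_a", "unique_a", "shared_b", "unique_b"],
    )
    path = outdir / "overlap.tsv"
    _write(df, path, config)
    return path


def _stage_concord(config, manifest, outdir) -> Path:
    lo, hi = config.sig_thresholds
    rule = concordance.SigRule(lo, hi)
    summary = concordance.concordance_summary(
        wio.read_de_table(manifest["de_a"]),
        wio.read_de_table(manifest["de_b"]),
        rule,
    )
    df = pd.DataFrame(
        [(c.gene_id, c.sign_a or ".", c.sign_b or ".", c.label)
         for c in summary.calls],
        columns=["gene_id", "sign_a", "sign_b", "label"],
    )
    path = outdir / "concordance.tsv"
    _write(df, path, config)
    sdf = pd.DataFrame(
        [(summary.n_cooperative, summary.n_antagonistic,
          summary.n_unclassified, summary.n_union,
          summary.n_both_significant,
          repr(summary.frac_antagonistic_shared),
          repr(summary.frac_antagonistic_union))],
        columns=["cooperative", "antagonistic", "unclassified", "union",
                 "both_significant", "frac_antagonistic_shared",
                 "frac_antagonistic_union"],
    )
    _write(sdf, outdir / "concordance_summary.tsv", config)
    return path


def _stage_enrich(config, manifest, outdir) -> Path:
    members = wio.read_id_list(manifest["members"])
    sets = wio.read_gmt(manifest["sets"])
    if "universe" in manifest:
        universe = set(wio.read_id_list(manifest["universe"]))
    else:
        universe = set(members).union(*sets.values())
        logger.info("enrich: universe defaulted to members + sets union "
                    "(%d ids)", len(universe))
    results = enrichment.hypergeom_enrichment(members, sets, universe)
    df = pd.DataFrame(
        [(r.set_name, r.k, r.n, r.K, r.N, repr(r.p), repr(r.q))
         for r in results],
        columns=["set_name", "k", "n", "K", "N", "p", "q"],
    )
    path = outdir / "enrichment.tsv"
    _write(df, path, config)
    return path


def _stage_assoc(config, manifest, outdir) -> Path:
    expr = wio.read_expression_matrix(manifest["matrix"])
    targets = wio.read_id_list(manifest["targets"])
    coregs = wio.read_id_list(manifest["coregulators"])
    rows = []
    for coreg in coregs:
        res = assoc.delta_corr(expr, manifest["regulator"], targets, coreg)
        rows.append(
            (coreg, repr(res.r_mean), repr(res.r_partial_mean),
             repr(res.delta))
        )
    df = pd.DataFrame(
        rows, columns=["coregulator", "r_mean", "r_partial_mean", "delta"]
    )
    path = outdir / "delta_corr.tsv"
    _write(df, path, config)
    return path


def _stage_jaccard(config, manifest, outdir) -> Path:
    res = assoc.ranked_jaccard_boot(
        wio.read_id_list(manifest["list_a"]),
        wio.read_id_list(manifest["list_b"]),
        k=config.jaccard_k,
        n_boot=config.n_boot,
        seed=config.seed,
    )
    df = pd.DataFrame(
        [(res.k, repr(res.jaccard), res.n_boot, repr(res.p))],
        columns=["k", "jaccard", "n_boot", "p"],
    )
    path = outdir / "jaccard.tsv"
    _write(df, path, config)
    return path


_RUNNERS = {
    "annotate": _stage_annotate,
    "wtct": _stage_wtct,
    "compare": _stage_compare,
    "overlap": _stage_overlap,
    "concord": _stage_concord,
    "enrich": _stage_enrich,
    "assoc": _stage_assoc,
    "jaccard": _stage_jaccard,
}
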