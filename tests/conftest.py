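"""Shared fixtures and deterministic hypothesis settings."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wtct import DEGRecord, GeneModel, GenomicInterval, Peak

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def make_peak(chrom="chr1", start=0, end=100, name="pk1", nlp=2.0, source=""):
    return Peak(GenomicInterval(chrom, start, end), name, nlp, source)


def make_gene(gene_id="G1", chrom="chr1", start=1000, end=5000, strand="+"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def three_genes():
    return [
        make_gene("G1", "chr1", 50_000, 52_000, "+"),
        make_gene("G2", "chr1", 400_000, 402_000, "-"),
        make_gene("G3", "chr2", 50_000, 52_000, "+"),
    ]


@pytest.fixture
def simple_degs():
    return [
        DEGRecord("G1", 0.5, 2.0, 0.01),
        DEGRecord("G2", -1.0, 3.0, 0.001),
        DEGRecord("G3", 2.0, 1.5, 0.03),
    ]


def random_peaks(rng, n, chroms=("chr1", "chr2"), chrom_len=1_000_000,
                 max_len=5_000, prefix="pk", dyadic=False):
    """Random peak set; dyadic=True draws significances on a 1/4 grid."""
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - max_len))
        length = int(rng.integers(1, max_len))
        if dyadic:
            nlp = float(rng.integers(1, 33)) / 4.0
        else:
            nlp = float(rng.exponential(2.0))
        peaks.append(
            Peak(GenomicInterval(chrom, start, start + length),
                 f"{prefix}{i}", nlp)
        )
    return peaks


def random_genes(rng, n, chroms=("chr1", "chr2"), chrom_len=1_000_000,
                 gene_len=2_000):
    genes = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - gene_len))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"G{i}",
                      GenomicInterval(chrom, start, start + gene_len, strand))
        )
    return genes


def random_degs(rng, genes, dyadic=False):
    degs = []
    for g in genes:
        if dyadic:
            lfc = float(rng.integers(-16, 17)) / 8.0
        else:
            lfc = float(rng.normal(0, 1))
        degs.append(DEGRecord(g.gene_id, lfc, float(rng.uniform(0, 5)),
                              float(rng.uniform(0, 1))))
    return degs
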