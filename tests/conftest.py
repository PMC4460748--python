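import numpy as np
import pytest

from biomodules.annotation import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    build_index,
)


def make_gene(gene_id, chrom, start, end, strand="+", biotype="coding", exon_breaks=None):
    """One-transcript gene; exon_breaks is a list of (start, end) pairs."""
    span = GenomicInterval(chrom, start, end, strand)
    exons = (
        [GenomicInterval(chrom, s, e, strand) for s, e in exon_breaks]
        if exon_breaks
        else [GenomicInterval(chrom, start, end, strand)]
    )
    tx = TranscriptModel(transcript_id=f"{gene_id}.t1", span=span, exons=exons)
    return GeneModel(
        gene_id=gene_id, gene_name=gene_id.lower(), biotype=biotype, span=span, transcripts=[tx]
    )


@pytest.fixture
def toy_genes():
    """Three genes on chr1: GA 1000-5000 (+, 2 exons), GB 100000-120000 (-),
    GC on chr2."""
    ga = make_gene("GA", "chr1", 1000, 5000, "+", exon_breaks=[(1000, 2000), (4000, 5000)])
    gb = make_gene("GB", "chr1", 100_000, 120_000, "-", biotype="noncoding")
    gc = make_gene("GC", "chr2", 500, 900, "+")
    return AnnotationSet([ga, gb, gc])


@pytest.fixture
def toy_index(toy_genes):
    return build_index(toy_genes)


@pytest.fixture(scope="session")
def synthetic_genome():
    from biomodules.synthetic import simulate_genome

    return simulate_genome(n_genes=500, n_chroms=3, seed=20240901)


@pytest.fixture(scope="session")
def synthetic_index(synthetic_genome):
    return build_index(synthetic_genome)


def random_interval(rng, chrom_extents):
    chrom = list(chrom_extents)[int(rng.integers(0, len(chrom_extents)))]
    extent = chrom_extents[chrom]
    start = int(rng.integers(1, extent))
    length = int(rng.integers(1, 5000))
    return GenomicInterval(chrom, start, start + length - 1)


def chrom_extents_of(annset):
    out = {}
    for gene in annset:
        out[gene.span.chrom] = max(out.get(gene.span.chrom, 1), gene.span.end + 200_000)
    return out
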