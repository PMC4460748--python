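"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design the pipeline targets: a genome
annotation with coding and non-coding genes, two ChIP-seq peak sets with
controlled co-occupancy near chosen target genes, and a microarray-like
log2 expression matrix containing a planted biomodule — genes that are
simultaneously correlated with a seed gene and shifted between case and
control groups — with optional additive (and multiplicative) batch
effects.  Every generator is a pure function of its parameters and seed,
and ground truth is returned alongside the data so each pipeline stage can
be scored against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    write_gff3,
)
from .enrichment import GeneSet, GeneSetCollection, write_gmt
from .errors import DataError
from .expression import ExpressionMatrix, write_matrix, write_sample_sheet
from .peaks import Peak, PeakSet, write_bed

# Defaults mirror the study conditions the pipeline is meant for: ~31% of
# linked genes coding, 28 cases vs 24 controls, a 40-gene module at
# correlation 0.7 and a 2-fold (1 log2 unit) case shift.
DEFAULT_CODING_FRACTION = 0.31
DEFAULT_N_CASE = 28
DEFAULT_N_CONTROL = 24
DEFAULT_MODULE_SIZE = 40
DEFAULT_RHO = 0.7
DEFAULT_LOG2_EFFECT = 1.0
DEFAULT_SIGMA = 1.0


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated dataset."""

    params: dict = field(default_factory=dict)
    target_genes: list = field(default_factory=list)
    module_genes: list = field(default_factory=list)
    seed_gene: str | None = None
    batch_shifts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(
    n_genes: int = 500,
    n_chroms: int = 3,
    mean_gene_len: int = 20_000,
    mean_gap: int = 30_000,
    coding_fraction: float = DEFAULT_CODING_FRACTION,
    seed: int = 0,
    chrom_length: int | None = None,
) -> AnnotationSet:
    """Generate a toy genome of non-overlapping genes.

    Genes are laid out left to right per chromosome with exponential gaps;
    each gene carries 1-3 transcripts (the first spanning the gene) with
    1-8 non-overlapping exons.  ``coding_fraction`` of genes are flagged
    coding (independent Bernoulli draws).  With ``chrom_length`` set, a
    layout that does not fit raises :class:`DataError`.
    """
    if n_genes < 1 or n_chroms < 1 or mean_gene_len < 50 or mean_gap < 1:
        raise ValueError("invalid genome parameters")
    if not 0 <= coding_fraction <= 1:
        raise ValueError("coding_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = []
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    gene_no = 0
    for ci, count in enumerate(per_chrom, start=1):
        chrom = f"chr{ci}"
        pos = 1
        for _ in range(count):
            gap = int(rng.exponential(mean_gap)) + 1
            length = max(200, int(rng.exponential(mean_gene_len)))
            start = pos + gap
            end = start + length - 1
            if chrom_length is not None and end > chrom_length:
                raise DataError(
                    f"genes do not fit on {chrom}: need > {end} bp, have {chrom_length}"
                )
            gene_no += 1
            gid = f"SYNG{gene_no:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            span = GenomicInterval(chrom, start, end, strand)
            n_tx = int(rng.integers(1, 4))
            transcripts = []
            for t in range(1, n_tx + 1):
                if t == 1:
                    t_start, t_end = start, end
                else:
                    t_start = int(rng.integers(start, start + max(1, length // 3)))
                    t_end = int(rng.integers(t_start + max(1, length // 3), end + 1))
                t_span = GenomicInterval(chrom, t_start, t_end, strand)
                exons = _split_exons(rng, t_span)
                transcripts.append(
                    TranscriptModel(transcript_id=f"{gid}.t{t}", span=t_span, exons=exons)
                )
            transcripts.sort(key=lambda t: (t.span.start, t.transcript_id))
            biotype = "coding" if rng.random() < coding_fraction else "noncoding"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    gene_name=f"Syn{gene_no}",
                    biotype=biotype,
                    span=span,
                    transcripts=transcripts,
                )
            )
            pos = end
    return AnnotationSet(genes)


def _split_exons(rng, span: GenomicInterval) -> list[GenomicInterval]:
    """Partition a transcript span into 1-8 exons separated by introns."""
    length = span.length
    k_max = min(8, max(1, length // 100))
    k = int(rng.integers(1, k_max + 1))
    if k == 1:
        return [GenomicInterval(span.chrom, span.start, span.end, span.strand)]
    # 2(k-1) interior boundaries; enforce alternation with >= 1 bp segments
    cuts = np.sort(rng.choice(np.arange(1, length - 1), size=2 * (k - 1), replace=False))
    bounds = [span.start] + [span.start + int(c) for c in cuts] + [span.end]
    exons = []
    for i in range(k):
        e_start = bounds[2 * i] + (1 if i > 0 else 0)
        e_end = bounds[2 * i + 1]
        if i == k - 1:
            e_end = span.end
        if e_end < e_start:
            e_end = e_start
        exons.append(GenomicInterval(span.chrom, e_start, e_end, span.strand))
    # first exon starts at span.start, last ends at span.end by construction
    return exons


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    genome: AnnotationSet,
    target_genes: set,
    n_background_peaks: int = 20,
    radius: int = 150_000,
    co_occupancy_rate: float = 0.2,
    seed: int = 0,
    peak_width: int = 600,
    placement_sd: int = 20_000,
) -> tuple[PeakSet, PeakSet]:
    """Two marks' peak sets with planted co-occupancy at target genes.

    Each target gene gets overlapping peaks in both marks, centred near its
    TSS (Gaussian offset, sd ``placement_sd``, truncated well inside
    ``radius``).  ``n_background_peaks`` additional peaks per mark are
    placed uniformly over the chromosome extents; each background pair
    co-occurs (overlaps between marks) with probability
    ``co_occupancy_rate``, otherwise the second mark's peak is placed
    independently.
    """
    target_genes = set(target_genes)
    missing = target_genes - set(genome.gene_ids)
    if missing:
        raise DataError(f"target genes not in genome: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    extents: dict[str, int] = {}
    for gene in genome:
        extents[gene.span.chrom] = max(extents.get(gene.span.chrom, 1), gene.span.end + radius)

    half = peak_width // 2
    mark1: list[Peak] = []
    mark2: list[Peak] = []

    for gid in sorted(target_genes):
        gene = genome[gid]
        tss = gene.transcripts[0].tss
        limit = max(1, radius // 2 - peak_width)
        offset = int(np.clip(rng.normal(0, placement_sd), -limit, limit))
        center = max(half + 1, tss + offset)
        iv1 = GenomicInterval(gene.span.chrom, center - half, center + half)
        jitter = int(rng.integers(-half // 2, half // 2 + 1))
        c2 = max(half + 1, center + jitter)
        iv2 = GenomicInterval(gene.span.chrom, c2 - half, c2 + half)
        mark1.append(Peak(interval=iv1, name=f"target:{gid}"))
        mark2.append(Peak(interval=iv2, name=f"target:{gid}"))

    chroms = sorted(extents)
    for i in range(n_background_peaks):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        c1 = int(rng.integers(half + 1, extents[chrom]))
        mark1.append(Peak(interval=GenomicInterval(chrom, c1 - half, c1 + half), name=f"bg1_{i}"))
        if rng.random() < co_occupancy_rate:
            c2 = c1 + int(rng.integers(-half // 2, half // 2 + 1))
            c2 = max(half + 1, c2)
            mark2.append(
                Peak(interval=GenomicInterval(chrom, c2 - half, c2 + half), name=f"bg2_{i}")
            )
        else:
            chrom2 = chroms[int(rng.integers(0, len(chroms)))]
            c2 = int(rng.integers(half + 1, extents[chrom2]))
            mark2.append(
                Peak(interval=GenomicInterval(chrom2, c2 - half, c2 + half), name=f"bg2_{i}")
            )
    return PeakSet(mark1, label="mark1"), PeakSet(mark2, label="mark2")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    n_genes: int = 2000,
    n_case: int = DEFAULT_N_CASE,
    n_control: int = DEFAULT_N_CONTROL,
    module_size: int = DEFAULT_MODULE_SIZE,
    rho: float = DEFAULT_RHO,
    log2_effect: float = DEFAULT_LOG2_EFFECT,
    sigma: float = DEFAULT_SIGMA,
    batch_design: dict | None = None,
    rng_seed: int = 0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Microarray-like log2 matrix with a planted seed-anchored module.

    The seed gene's sample profile is unit-variance biological signal plus
    ``log2_effect`` in cases.  The other module genes share the seed's
    biological signal at correlation ``rho`` (noise sd ``sigma``) and carry
    the same case shift; non-module genes are independent noise.
    ``batch_design`` is ``{"n_batches": int, "shifts": [...], "scales":
    [...]}``; samples are assigned to batches round-robin within each group
    so batch and phenotype stay unconfounded.
    """
    if not 0 <= rho < 1:
        raise DataError("rho must satisfy 0 <= rho < 1")
    if module_size < 1 or module_size > n_genes:
        raise ValueError("module_size must be in [1, n_genes]")
    rng = np.random.default_rng(rng_seed)
    n = n_case + n_control
    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    module_genes = gene_ids[:module_size]
    seed_gene = module_genes[0]
    sample_ids = [f"case{i:03d}" for i in range(1, n_case + 1)] + [
        f"ctrl{i:03d}" for i in range(1, n_control + 1)
    ]
    case = np.concatenate([np.ones(n_case), np.zeros(n_control)])

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    z = rng.normal(0.0, 1.0, size=n)  # shared biological signal of the seed
    values = np.empty((n_genes, n), dtype=float)
    noise = rng.normal(0.0, 1.0, size=(n_genes, n))
    module_set = set(module_genes)
    for i, g in enumerate(gene_ids):
        if g == seed_gene:
            values[i] = z + log2_effect * case
        elif g in module_set:
            values[i] = rho * z + np.sqrt(1 - rho**2) * sigma * noise[i] + log2_effect * case
        else:
            values[i] = sigma * noise[i]
    values += baseline[:, None]

    phenotype = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=sample_ids, name="group"
    )
    batch_shifts: dict[str, float] = {}
    if batch_design:
        n_batches = int(batch_design.get("n_batches", 2))
        shifts = list(batch_design.get("shifts", [0.0] * n_batches))
        scales = list(batch_design.get("scales", [1.0] * n_batches))
        if len(shifts) != n_batches or len(scales) != n_batches:
            raise DataError("batch_design shifts/scales must match n_batches")
        assign = np.empty(n, dtype=int)
        assign[:n_case] = np.arange(n_case) % n_batches
        assign[n_case:] = np.arange(n_control) % n_batches
        centered = values - baseline[:, None]
        for b in range(n_batches):
            cols = assign == b
            centered[:, cols] = centered[:, cols] * scales[b] + shifts[b]
            batch_shifts[f"batch{b + 1}"] = float(shifts[b])
        values = centered + baseline[:, None]
        batch = pd.Series([f"batch{b + 1}" for b in assign], index=sample_ids, name="batch")
    else:
        batch = pd.Series(["batch1"] * n, index=sample_ids, name="batch")

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        phenotype=phenotype,
        batch=batch,
    )
    truth = SyntheticTruth(
        params=dict(
            n_genes=n_genes,
            n_case=n_case,
            n_control=n_control,
            module_size=module_size,
            rho=rho,
            log2_effect=log2_effect,
            sigma=sigma,
            rng_seed=rng_seed,
            batch_design=batch_design,
        ),
        module_genes=list(module_genes),
        seed_gene=seed_gene,
        batch_shifts=batch_shifts,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Full fixture directory
# ---------------------------------------------------------------------------

def simulate_fixture(
    outdir: str | Path,
    seed: int = 0,
    n_genes_genome: int = 200,
    n_chroms: int = 4,
    mean_gene_len: int = 15_000,
    mean_gap: int = 2_000_000,
    n_targets: int = 50,
    n_background_peaks: int = 20,
    co_occupancy_rate: float = 1.0,
    radius: int = 150_000,
    n_genes_expr: int = 2000,
    n_distractor_sets: int = 20,
    **expr_kwargs,
) -> SyntheticTruth:
    """Emit a complete fixture directory with ground truth.

    Writes genome.gff3, mark1.bed, mark2.bed, expr.tsv, samples.tsv,
    sets.gmt and truth.json.  The GMT contains one set matching the planted
    expression module plus random distractor sets.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    genome = simulate_genome(
        n_genes=n_genes_genome,
        n_chroms=n_chroms,
        mean_gene_len=mean_gene_len,
        mean_gap=mean_gap,
        coding_fraction=DEFAULT_CODING_FRACTION,
        seed=seed,
    )
    all_ids = genome.gene_ids
    targets = sorted(rng.choice(all_ids, size=min(n_targets, len(all_ids)), replace=False))
    mark1, mark2 = simulate_peaks(
        genome,
        set(targets),
        n_background_peaks=n_background_peaks,
        radius=radius,
        co_occupancy_rate=co_occupancy_rate,
        seed=seed + 1,
    )
    matrix, truth = simulate_expression(n_genes=n_genes_expr, rng_seed=seed + 2, **expr_kwargs)

    write_gff3(genome, outdir / "genome.gff3")
    write_bed(mark1, outdir / "mark1.bed")
    write_bed(mark2, outdir / "mark2.bed")
    write_matrix(matrix.values, outdir / "expr.tsv")
    write_sample_sheet(matrix.phenotype, matrix.batch, outdir / "samples.tsv")

    planted = GeneSet(
        name="PLANTED_MODULE_UP",
        description="synthetic: the planted seed-correlated, case-up module",
        members=frozenset(truth.module_genes),
    )
    distractors = []
    expr_ids = matrix.gene_ids
    for i in range(1, n_distractor_sets + 1):
        size = int(rng.integers(20, 200))
        members = frozenset(rng.choice(expr_ids, size=size, replace=False))
        distractors.append(
            GeneSet(name=f"RANDOM_SET_{i:02d}", description="synthetic distractor", members=members)
        )
    write_gmt(GeneSetCollection([planted, *distractors]), outdir / "sets.gmt")

    truth.target_genes = list(targets)
    truth.params.update(
        genome=dict(
            n_genes=n_genes_genome,
            n_chroms=n_chroms,
            mean_gene_len=mean_gene_len,
            mean_gap=mean_gap,
            seed=seed,
        ),
        peaks=dict(
            n_targets=len(targets),
            n_background_peaks=n_background_peaks,
            co_occupancy_rate=co_occupancy_rate,
            radius=radius,
            seed=seed + 1,
        ),
    )
    truth.to_json(outdir / "truth.json")
    return truth
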