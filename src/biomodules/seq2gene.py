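"""The seq2gene region-to-gene linking strategy.

Each co-enriched genomic region is classified against the annotation index
and linked to candidate target genes on *both* sides within a search radius
(default 150 kb), regardless of gene orientation — the rationale being that
distal regulatory elements act over long ranges and independently of the
target's strand, and that several elements may converge on one gene, so
linking only the nearest gene would be too conservative.

Per (region, gene) pair a single link is emitted with the highest-priority
category: exonic > promoter > intronic > intergenic.  The promoter window is
±``promoter_halfwidth`` around each transcript TSS (default ±2 kb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .annotation import AnnotationIndex, GenomicInterval, signed_span_distance
from .errors import ValidationError
from .peaks import PeakSet

CATEGORIES = ("exonic", "promoter", "intronic", "intergenic")

DEFAULT_RADIUS = 150_000
DEFAULT_PROMOTER_HALFWIDTH = 2_000


@dataclass(frozen=True)
class RegionGeneLink:
    region: GenomicInterval
    gene_id: str
    category: str  # exonic | promoter | intronic | intergenic
    signed_distance: int  # span-to-span; 0 when region overlaps the gene span
    gene_biotype: str


@dataclass
class Seq2GeneResult:
    links: list[RegionGeneLink]
    n_regions: int
    n_linked_regions: int
    category_counts: dict[str, int]
    fraction_linked: float
    coding_fraction: float  # fraction of distinct linked genes that are coding

    def summary(self) -> dict:
        return dict(
            n_regions=self.n_regions,
            n_linked_regions=self.n_linked_regions,
            fraction_linked=self.fraction_linked,
            coding_fraction=self.coding_fraction,
            category_counts=dict(self.category_counts),
            n_links=len(self.links),
            n_target_genes=len(target_genes(self)),
        )


def classify_region(
    region: GenomicInterval,
    index: AnnotationIndex,
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    radius: int = DEFAULT_RADIUS,
    nearest_only: bool = False,
) -> list[RegionGeneLink]:
    """Link one region to every candidate gene within ``radius``.

    For each gene the most specific relation wins: overlap with any exon is
    exonic; else overlap with any transcript's TSS +/- promoter_halfwidth is
    promoter; else overlap with the gene span is intronic; genes up to
    ``radius`` bp away on either side are intergenic links.  With
    ``nearest_only`` set, intergenic links keep only the nearest gene on
    each side of the region.
    """
    if promoter_halfwidth < 0 or radius < 0:
        raise ValueError("promoter_halfwidth and radius must be >= 0")
    # the promoter window can stick out beyond the gene span, so the
    # candidate search radius must cover it as well
    search = max(radius, promoter_halfwidth)
    links: list[RegionGeneLink] = []
    for gene_id, dist in index.query_radius(region, search):
        gene = index.genes[gene_id]
        category = None
        if dist == 0:
            for tx in gene.transcripts:
                if any(region.overlaps(e) for e in tx.exons):
                    category = "exonic"
                    break
        if category is None and _touches_promoter(region, gene, promoter_halfwidth):
            category = "promoter"
        if category is None and dist == 0:
            category = "intronic"
        if category is None:
            if abs(dist) > radius:
                continue
            category = "intergenic"
        links.append(
            RegionGeneLink(
                region=region,
                gene_id=gene_id,
                category=category,
                signed_distance=dist,
                gene_biotype=gene.biotype,
            )
        )
    if nearest_only:
        links = _keep_nearest_intergenic(links)
    return links


def _touches_promoter(region: GenomicInterval, gene, halfwidth: int) -> bool:
    for tx in gene.transcripts:
        lo = max(1, tx.tss - halfwidth)
        hi = tx.tss + halfwidth
        if region.start <= hi and region.end >= lo:
            return True
    return False


def _keep_nearest_intergenic(links: list[RegionGeneLink]) -> list[RegionGeneLink]:
    inter = [l for l in links if l.category == "intergenic"]
    keep = [l for l in links if l.category != "intergenic"]
    left = [l for l in inter if l.signed_distance < 0]
    right = [l for l in inter if l.signed_distance > 0]
    if left:
        keep.append(max(left, key=lambda l: l.signed_distance))
    if right:
        keep.append(min(right, key=lambda l: l.signed_distance))
    keep.sort(key=lambda l: (l.signed_distance, l.gene_id))
    return keep


def seq2gene(
    regions: PeakSet | Iterable[GenomicInterval],
    index: AnnotationIndex,
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    radius: int = DEFAULT_RADIUS,
    coding_only: bool = False,
    nearest_only: bool = False,
) -> Seq2GeneResult:
    """Run region classification over a whole peak set.

    Summary fractions (fraction of regions with at least one link; fraction
    of distinct linked genes that are coding) are computed over *all* links;
    ``coding_only`` then filters the reported links to coding genes.
    """
    if isinstance(regions, PeakSet):
        intervals = regions.intervals()
    else:
        intervals = list(regions)
    if not intervals:
        raise ValidationError("seq2gene needs at least one region")

    all_links: list[RegionGeneLink] = []
    n_linked = 0
    for region in intervals:
        links = classify_region(
            region,
            index,
            promoter_halfwidth=promoter_halfwidth,
            radius=radius,
            nearest_only=nearest_only,
        )
        if links:
            n_linked += 1
        all_links.extend(links)

    linked_genes = {l.gene_id for l in all_links}
    n_coding = sum(1 for g in linked_genes if index.genes[g].coding)
    result_links = (
        [l for l in all_links if l.gene_biotype == "coding"] if coding_only else all_links
    )
    counts = {c: 0 for c in CATEGORIES}
    for l in result_links:
        counts[l.category] += 1
    return Seq2GeneResult(
        links=result_links,
        n_regions=len(intervals),
        n_linked_regions=n_linked,
        category_counts=counts,
        fraction_linked=n_linked / len(intervals),
        coding_fraction=(n_coding / len(linked_genes)) if linked_genes else 0.0,
    )


def target_genes(result: Seq2GeneResult) -> set[str]:
    """Deduplicated candidate target genes of a seq2gene run."""
    return {l.gene_id for l in result.links}


def links_table(result: Seq2GeneResult, index: AnnotationIndex):
    """Links as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    rows = [
        dict(
            chrom=l.region.chrom,
            start=l.region.start,
            end=l.region.end,
            gene_id=l.gene_id,
            gene_name=index.genes[l.gene_id].gene_name,
            category=l.category,
            distance=l.signed_distance,
            biotype=l.gene_biotype,
        )
        for l in result.links
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gene_id", "gene_name", "category", "distance", "biotype"],
    )
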