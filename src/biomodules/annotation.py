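"""Gene models and a bisection-searchable annotation index.

Gene annotation (genes, transcripts, exons) is read from GFF3 or GTF and
held in a simple object model using 1-based inclusive coordinates, the GFF
convention.  For fast region queries the features are flattened into
per-chromosome arrays sorted by start position; lookups use binary search
(``numpy.searchsorted``) over the starts plus a running maximum of the ends,
so that a query returns exactly what a linear scan over all features would.
The flattened exon and transcript tables can also be written out as TSV
("exon.table" / "transcript.table") keyed by feature id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np

from .errors import FormatError, ValidationError

Strand = Literal["+", "-", "."]

_CODING_SYNONYMS = {"protein_coding", "coding", "mrna", "protein-coding"}


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if self.start < 1:
            raise ValidationError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"interval end ({self.end}) before start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Closed-interval intersection: at least one shared base pair."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and self.end >= other.start
        )


@dataclass
class TranscriptModel:
    transcript_id: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.span.chrom:
                raise ValidationError(
                    f"exon of {self.transcript_id} on {exon.chrom}, "
                    f"transcript on {self.span.chrom}"
                )
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValidationError(
                    f"exon {exon.start}-{exon.end} outside transcript "
                    f"{self.transcript_id} span {self.span.start}-{self.span.end}"
                )
            if prev_end is not None and exon.start <= prev_end:
                raise ValidationError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
            prev_end = exon.end

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site ('.' treated as '+')."""
        return self.span.end if self.span.strand == "-" else self.span.start


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    biotype: str  # "coding" | "noncoding"
    span: GenomicInterval
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biotype not in ("coding", "noncoding"):
            raise ValidationError(f"biotype must be coding/noncoding, got {self.biotype!r}")
        for tx in self.transcripts:
            if tx.span.start < self.span.start or tx.span.end > self.span.end:
                raise ValidationError(
                    f"transcript {tx.transcript_id} outside gene {self.gene_id} span"
                )

    @property
    def coding(self) -> bool:
        return self.biotype == "coding"


class AnnotationSet:
    """An ordered collection of gene models keyed by gene_id."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for gene in genes:
            if gene.gene_id in self._genes:
                raise ValidationError(f"duplicate gene_id {gene.gene_id!r}")
            self._genes[gene.gene_id] = gene

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def counts(self) -> tuple[int, int, int]:
        """(n_genes, n_transcripts, n_exons)."""
        n_tx = sum(len(g.transcripts) for g in self)
        n_ex = sum(len(t.exons) for g in self for t in g.transcripts)
        return len(self), n_tx, n_ex

    def validate(self) -> None:
        for gene in self:
            if not gene.transcripts:
                raise ValidationError(f"gene {gene.gene_id} has no transcripts")
            for tx in gene.transcripts:
                if not tx.exons:
                    raise ValidationError(
                        f"transcript {tx.transcript_id} has no exons"
                    )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _norm_biotype(raw: str | None) -> str:
    if raw is None:
        return "coding"
    return "coding" if raw.lower() in _CODING_SYNONYMS else "noncoding"


def _attr(feature, *keys: str) -> str | None:
    for key in keys:
        if key in feature.attributes:
            vals = feature.attributes[key]
            if vals:
                return vals[0]
    return None


def load_gene_models(path: str | Path, fmt: str | None = None) -> AnnotationSet:
    """Parse a GFF3 or GTF file into an :class:`AnnotationSet`.

    Parameters
    ----------
    path
        Annotation file. Comment (``#``) and blank lines are skipped.
    fmt
        ``"gff3"`` or ``"gtf"``; ``None`` guesses from the file suffix.

    Feature types recognised: ``gene``, ``transcript``/``mRNA`` (or any type
    carrying a transcript_id with a gene Parent), ``exon``.  Attribute keys
    accepted: GFF3 ``ID``/``Parent`` plus ``gene_id``/``transcript_id``;
    biotype from ``gene_biotype``/``biotype``/``gene_type``
    (``protein_coding`` and ``coding`` map to coding, all else noncoding);
    display name from ``gene_name``/``Name``.
    """
    from gffutils.feature import feature_from_line

    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf",) else "gff3"
    if fmt not in ("gff3", "gtf"):
        raise ValueError(f"fmt must be gff3 or gtf, got {fmt!r}")

    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises several types
                raise FormatError(f"{path.name}:{lineno}: unparsable {fmt} line ({exc})")
            ftype = feat.featuretype.lower()
            iv_kwargs = dict(
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else ".",
            )
            if ftype == "gene":
                gid = _attr(feat, "gene_id", "ID") or feat.id
                genes[gid] = dict(
                    iv=iv_kwargs,
                    name=_attr(feat, "gene_name", "Name") or gid,
                    biotype=_norm_biotype(
                        _attr(feat, "gene_biotype", "biotype", "gene_type")
                    ),
                )
            elif ftype in ("transcript", "mrna"):
                tid = _attr(feat, "transcript_id", "ID") or feat.id
                parent = _attr(feat, "Parent", "gene_id")
                if parent is None:
                    raise FormatError(
                        f"{path.name}:{lineno}: transcript {tid} has no gene parent"
                    )
                rec = transcripts.setdefault(tid, dict(iv=None, gene=parent, exons=[]))
                rec["iv"] = iv_kwargs
                rec["gene"] = parent
            elif ftype == "exon":
                tid = _attr(feat, "Parent", "transcript_id")
                if tid is None:
                    raise FormatError(f"{path.name}:{lineno}: exon has no transcript parent")
                transcripts.setdefault(tid, dict(iv=None, gene=_attr(feat, "gene_id"), exons=[]))
                transcripts[tid]["exons"].append((iv_kwargs, lineno))

    # Assemble models; infer missing spans from exon extents (bare GTFs).
    gene_tx: dict[str, list[TranscriptModel]] = {g: [] for g in genes}
    for tid, rec in transcripts.items():
        exon_ivs = []
        for iv_kwargs, lineno in rec["exons"]:
            exon_ivs.append(GenomicInterval(**iv_kwargs))
        if rec["iv"] is None:
            if not exon_ivs:
                raise ValidationError(f"transcript {tid} has no span and no exons")
            rec["iv"] = dict(
                chrom=exon_ivs[0].chrom,
                start=min(e.start for e in exon_ivs),
                end=max(e.end for e in exon_ivs),
                strand=exon_ivs[0].strand,
            )
        span = GenomicInterval(**rec["iv"])
        if not exon_ivs:
            raise ValidationError(f"transcript {tid} has no exons")
        tx = TranscriptModel(transcript_id=tid, span=span, exons=exon_ivs)
        gid = rec["gene"]
        if gid not in genes:
            # gene record missing (bare GTF): synthesise from transcript
            genes[gid] = dict(iv=dict(rec["iv"]), name=gid, biotype="coding")
            gene_tx[gid] = []
        gene_tx.setdefault(gid, []).append(tx)

    models = []
    for gid, rec in genes.items():
        txs = gene_tx.get(gid, [])
        if not txs:
            raise ValidationError(f"gene {gid} has no transcripts")
        span = GenomicInterval(**rec["iv"])
        lo = min(t.span.start for t in txs)
        hi = max(t.span.end for t in txs)
        if lo < span.start or hi > span.end:
            span = GenomicInterval(span.chrom, min(lo, span.start), max(hi, span.end), span.strand)
        models.append(
            GeneModel(
                gene_id=gid,
                gene_name=rec["name"],
                biotype=rec["biotype"],
                span=span,
                transcripts=sorted(txs, key=lambda t: (t.span.start, t.transcript_id)),
            )
        )
    models.sort(key=lambda g: (g.span.chrom, g.span.start, g.gene_id))
    annset = AnnotationSet(models)
    annset.validate()
    return annset


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------

class _FeatureTable:
    """Per-chromosome arrays sorted by (start, id), with a running max end."""

    def __init__(self, rows: list[tuple[str, int, int, str]]):
        # rows: (chrom, start, end, feature_id) plus optional payload handled
        # by the caller through parallel dicts.
        self.by_chrom: dict[str, dict[str, np.ndarray]] = {}
        from collections import defaultdict

        grouped: dict[str, list] = defaultdict(list)
        for row in rows:
            grouped[row[0]].append(row)
        for chrom, items in grouped.items():
            items.sort(key=lambda r: (r[1], r[3]))
            starts = np.array([r[1] for r in items], dtype=np.int64)
            ends = np.array([r[2] for r in items], dtype=np.int64)
            ids = np.array([r[3] for r in items], dtype=object)
            self.by_chrom[chrom] = dict(
                starts=starts,
                ends=ends,
                ids=ids,
                cummax_ends=np.maximum.accumulate(ends),
            )

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices (into this chrom's arrays) of features overlapping [start, end]."""
        tab = self.by_chrom.get(chrom)
        if tab is None:
            return np.empty(0, dtype=np.int64)
        hi = int(np.searchsorted(tab["starts"], end, side="right"))
        lo = int(np.searchsorted(tab["cummax_ends"], start, side="left"))
        if lo >= hi:
            return np.empty(0, dtype=np.int64)
        sel = np.nonzero(tab["ends"][lo:hi] >= start)[0] + lo
        return sel

    def ids_overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        tab = self.by_chrom.get(chrom)
        idx = self.overlapping(chrom, start, end)
        if tab is None or idx.size == 0:
            return []
        return list(tab["ids"][idx])


class AnnotationIndex:
    """Bisection-searchable index over gene, transcript, and exon intervals.

    Built once from an :class:`AnnotationSet`; supports overlap queries at
    gene/transcript/exon level and radius queries over gene spans.  Query
    results are ordered by (start, feature id) and match a linear scan.
    """

    def __init__(self, annset: AnnotationSet):
        if len(annset) == 0:
            raise ValidationError("cannot index an empty annotation set")
        annset.validate()
        self.annset = annset
        self.genes: dict[str, GeneModel] = {g.gene_id: g for g in annset}

        gene_rows, tx_rows, exon_rows = [], [], []
        # parallel payloads for exons: owning gene and transcript
        self.exon_gene: dict[str, str] = {}
        self.exon_transcript: dict[str, str] = {}
        self.transcript_gene: dict[str, str] = {}
        for gene in annset:
            s = gene.span
            gene_rows.append((s.chrom, s.start, s.end, gene.gene_id))
            for tx in gene.transcripts:
                tx_rows.append((tx.span.chrom, tx.span.start, tx.span.end, tx.transcript_id))
                self.transcript_gene[tx.transcript_id] = gene.gene_id
                for i, exon in enumerate(tx.exons, start=1):
                    eid = f"{tx.transcript_id}:exon{i}"
                    exon_rows.append((exon.chrom, exon.start, exon.end, eid))
                    self.exon_gene[eid] = gene.gene_id
                    self.exon_transcript[eid] = tx.transcript_id
        self._tables = {
            "gene": _FeatureTable(gene_rows),
            "transcript": _FeatureTable(tx_rows),
            "exon": _FeatureTable(exon_rows),
        }

    def query_overlaps(
        self, region: GenomicInterval, level: str = "gene"
    ) -> list[str]:
        """Feature ids at ``level`` overlapping ``region`` (closed intervals)."""
        if level not in self._tables:
            raise ValueError(f"level must be gene/transcript/exon, got {level!r}")
        return self._tables[level].ids_overlapping(region.chrom, region.start, region.end)

    def query_radius(
        self, region: GenomicInterval, radius: int, tss_distance: bool = False
    ) -> list[tuple[str, int]]:
        """Genes within ``radius`` bp of ``region``, with signed distances.

        Distance is 0 for span overlap, negative for genes upstream of the
        region and positive downstream, on the reference strand, measured
        span-to-span (or region-to-TSS when ``tss_distance`` is set).  Gene
        strand plays no role.
        """
        if radius < 0:
            raise ValueError("radius must be >= 0")
        tab = self._tables["gene"].by_chrom.get(region.chrom)
        if tab is None:
            return []
        idx = self._tables["gene"].overlapping(
            region.chrom, max(1, region.start - radius), region.end + radius
        )
        out: list[tuple[str, int]] = []
        for i in idx:
            gid = tab["ids"][i]
            gene = self.genes[gid]
            if tss_distance:
                dist = self._tss_dist(gene, region)
            else:
                dist = signed_span_distance(region, gene.span)
            if abs(dist) <= radius:
                out.append((gid, dist))
        return out

    @staticmethod
    def _tss_dist(gene: GeneModel, region: GenomicInterval) -> int:
        # distance from the region to the nearest transcript TSS
        best = None
        for tx in gene.transcripts:
            t = tx.tss
            if region.start <= t <= region.end:
                return 0
            d = t - region.end if t > region.end else t - region.start
            if best is None or abs(d) < abs(best):
                best = d
        assert best is not None
        return best


def signed_span_distance(region: GenomicInterval, span: GenomicInterval) -> int:
    """Span-to-span gap, signed: 0 on overlap, <0 left of region, >0 right."""
    if span.chrom != region.chrom:
        raise ValueError("distance undefined across chromosomes")
    if span.start <= region.end and span.end >= region.start:
        return 0
    if span.end < region.start:
        return span.end - region.start
    return span.start - region.end


def build_index(annset: AnnotationSet) -> AnnotationIndex:
    """Build the bisection-searchable :class:`AnnotationIndex`."""
    return AnnotationIndex(annset)


# ---------------------------------------------------------------------------
# Flat-table output
# ---------------------------------------------------------------------------

def write_feature_tables(index: AnnotationIndex, outdir: str | Path) -> dict[str, Path]:
    """Write exon.table and transcript.table TSVs keyed by feature id."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tx_rows, exon_rows = [], []
    for gene in index.annset:
        for tx in gene.transcripts:
            tx_rows.append(
                dict(
                    transcript_id=tx.transcript_id,
                    chrom=tx.span.chrom,
                    start=tx.span.start,
                    end=tx.span.end,
                    strand=tx.span.strand,
                    tss=tx.tss,
                    gene_id=gene.gene_id,
                    biotype=gene.biotype,
                )
            )
            for i, exon in enumerate(tx.exons, start=1):
                exon_rows.append(
                    dict(
                        exon_id=f"{tx.transcript_id}:exon{i}",
                        chrom=exon.chrom,
                        start=exon.start,
                        end=exon.end,
                        strand=exon.strand,
                        transcript_id=tx.transcript_id,
                        gene_id=gene.gene_id,
                    )
                )
    paths = {
        "transcript.table": outdir / "transcript.table",
        "exon.table": outdir / "exon.table",
    }
    pd.DataFrame(tx_rows).to_csv(paths["transcript.table"], sep="\t", index=False)
    pd.DataFrame(exon_rows).to_csv(paths["exon.table"], sep="\t", index=False)
    return paths


def write_gff3(annset: AnnotationSet, path: str | Path) -> Path:
    """Write an AnnotationSet as GFF3 (round-trips through load_gene_models)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(annset, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
            s = gene.span
            biotype = "protein_coding" if gene.coding else "lincRNA"
            fh.write(
                f"{s.chrom}\tbiomodules\tgene\t{s.start}\t{s.end}\t.\t{s.strand}\t.\t"
                f"ID={gene.gene_id};gene_id={gene.gene_id};gene_name={gene.gene_name};"
                f"gene_biotype={biotype}\n"
            )
            for tx in gene.transcripts:
                t = tx.span
                fh.write(
                    f"{t.chrom}\tbiomodules\ttranscript\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={gene.gene_id};"
                    f"transcript_id={tx.transcript_id}\n"
                )
                for i, exon in enumerate(tx.exons, start=1):
                    fh.write(
                        f"{exon.chrom}\tbiomodules\texon\t{exon.start}\t{exon.end}\t.\t"
                        f"{exon.strand}\t.\tID={tx.transcript_id}:exon{i};"
                        f"Parent={tx.transcript_id}\n"
                    )
    return path
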