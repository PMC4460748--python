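"""ChIP-seq peak sets: BED/narrowPeak IO and segment set algebra.

Peaks are stored 1-based inclusive internally (BED input is 0-based
half-open and converted on read; BED output converts back).  The central
operation is :func:`intersect_peaksets`, which computes the genomic
*segment* intersection of two marks — every output base pair is enriched in
both marks — the regions that feed region-to-gene annotation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .annotation import GenomicInterval
from .errors import FormatError, ValidationError

_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float | None = None
    name: str | None = None


class PeakSet:
    """One mark's enriched regions, sorted by (chrom, start, end)."""

    def __init__(self, peaks: Iterable[Peak], label: str = ""):
        self.label = label
        self.peaks: list[Peak] = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def total_bp(self) -> int:
        """Base pairs covered after merging overlapping peaks."""
        return sum(iv.length for iv in merge_intervals(self.intervals()))

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for p in self.peaks:
            out.setdefault(p.interval.chrom, []).append(p.interval)
        return out


def read_peaks(path: str | Path, dialect: str = "bed3", label: str | None = None) -> PeakSet:
    """Read a BED3/BED6/narrowPeak file into a :class:`PeakSet`.

    BED coordinates (0-based half-open) are converted to 1-based inclusive:
    ``chr1 99 200`` becomes chr1:100-200.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"dialect must be one of {sorted(_DIALECT_COLUMNS)}")
    want = _DIALECT_COLUMNS[dialect]
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != want:
                raise FormatError(
                    f"{path.name}:{lineno}: expected {want} columns for "
                    f"{dialect}, got {len(fields)}"
                )
            try:
                chrom, bed_start, bed_end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: bad coordinates ({exc})")
            if bed_end <= bed_start:
                raise ValidationError(
                    f"{path.name}:{lineno}: zero-length or inverted peak"
                )
            name = score = strand = None
            if want >= 6:
                name = fields[3] or None
                score = float(fields[4]) if fields[4] not in (".", "") else None
                strand = fields[5] if fields[5] in ("+", "-") else "."
            if dialect == "narrowPeak":
                # column 7 (signalValue) is the quantitative score of record
                score = float(fields[6]) if fields[6] not in (".", "") else score
            iv = GenomicInterval(chrom, bed_start + 1, bed_end, strand or ".")
            peaks.append(Peak(interval=iv, score=score, name=name))
    return PeakSet(peaks, label=label or path.stem)


def write_bed(peakset: PeakSet, path: str | Path) -> Path:
    """Write peaks as BED (0-based half-open), 3 or 6 columns as available."""
    path = Path(path)
    with open(path, "w") as fh:
        for p in peakset:
            iv = p.interval
            row = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if p.name is not None or p.score is not None:
                row += [p.name or ".", f"{p.score:g}" if p.score is not None else ".", iv.strand]
            fh.write("\t".join(row) + "\n")
    return path


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + 1:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def intersect_peaksets(a: PeakSet, b: PeakSet, label: str | None = None) -> PeakSet:
    """Genomic segment intersection of two peak sets.

    Each set is merged first; the output contains every maximal segment
    covered by both sets (book-ended output segments are merged).  This is
    the "common enriched regions" operation for two chromatin marks.
    """
    a_merged = {iv.chrom: [] for iv in merge_intervals(a.intervals())}
    for iv in merge_intervals(a.intervals()):
        a_merged[iv.chrom].append(iv)
    b_merged: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(b.intervals()):
        b_merged.setdefault(iv.chrom, []).append(iv)

    segments: list[GenomicInterval] = []
    for chrom, ivs_a in a_merged.items():
        ivs_b = b_merged.get(chrom)
        if not ivs_b:
            continue
        i = j = 0
        while i < len(ivs_a) and j < len(ivs_b):
            lo = max(ivs_a[i].start, ivs_b[j].start)
            hi = min(ivs_a[i].end, ivs_b[j].end)
            if lo <= hi:
                segments.append(GenomicInterval(chrom, lo, hi))
            if ivs_a[i].end < ivs_b[j].end:
                i += 1
            else:
                j += 1
    segments = merge_intervals(segments)
    out_label = label or f"{a.label}&{b.label}".strip("&")
    return PeakSet([Peak(interval=iv) for iv in segments], label=out_label)


def intersect_touching(a: PeakSet, b: PeakSet, label: str | None = None) -> PeakSet:
    """Alternative mode: peaks of ``a`` that touch any peak of ``b``."""
    b_merged: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(b.intervals()):
        b_merged.setdefault(iv.chrom, []).append(iv)
    kept = []
    for p in a:
        for iv in b_merged.get(p.interval.chrom, []):
            if iv.start > p.interval.end:
                break
            if p.interval.overlaps(iv):
                kept.append(p)
                break
    return PeakSet(kept, label=label or f"{a.label}~{b.label}")


def gene_target_difference(
    targets_a: set[str], targets_b: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Partition two target-gene sets into (a_only, b_only, shared)."""
    targets_a, targets_b = set(targets_a), set(targets_b)
    return targets_a - targets_b, targets_b - targets_a, targets_a & targets_b
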