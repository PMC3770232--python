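"""Genomic primitives: intervals, genes, annotations, and flat-file IO.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention —
throughout the package. GFF3 input (1-based, inclusive) is converted on read.
The TSS of a ``+`` strand gene is ``interval.start``; for a ``-`` strand gene it
is ``interval.end - 1``, the last covered base. Distances across chromosomes are
an explicit ``math.inf`` sentinel, never a large finite number.
"""
from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "Interval",
    "Gene",
    "BindingSite",
    "GenomeAnnotation",
    "ArrayDesign",
    "IntervalIndex",
    "gap",
    "point_gap",
    "signed_tss_distance",
    "merge_intervals",
    "intersect_bp",
    "read_bed",
    "read_bed_intervals",
    "write_bed",
    "read_chrom_lengths",
    "write_chrom_lengths",
    "read_gene_table",
    "write_gene_table",
    "read_gff3_genes",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded, the default).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint base, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def gap(a: Interval, b: Interval) -> float:
    """Bases strictly between two intervals; 0 if they overlap or abut.

    Different chromosomes return ``math.inf``.
    """
    if a.chrom != b.chrom:
        return math.inf
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def point_gap(iv: Interval, pos: int) -> int:
    """Distance from a point to the nearest edge of an interval (0 inside)."""
    return max(0, max(iv.start, pos) - min(iv.end, pos))


@dataclass(frozen=True)
class Gene:
    """A gene with a stranded body interval; the TSS follows from the strand."""

    id: str
    interval: Interval

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("gene id must be non-empty")
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.id}: strand must be '+' or '-', got {self.interval.strand!r}"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site: 5'-most covered base of the gene body."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class BindingSite:
    """A called peak: an unstranded interval with an id and optional score."""

    interval: Interval
    id: str
    score: Optional[float] = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def width(self) -> int:
        return self.interval.width


def signed_tss_distance(site: Union[BindingSite, Interval], gene: Gene) -> int:
    """Signed distance from a site to a gene's TSS.

    0 when the site covers the TSS (``start <= tss < end``); otherwise the
    coordinate gap between the TSS point and the nearest site edge, negative
    when the site lies on the gene's upstream (5') side, positive downstream.
    Raises on different chromosomes — callers must filter.
    """
    iv = site.interval if isinstance(site, BindingSite) else site
    if iv.chrom != gene.interval.chrom:
        raise ValueError("site and gene are on different chromosomes")
    tss = gene.tss
    if iv.start <= tss < iv.end:
        return 0
    mag = max(0, max(iv.start, tss) - min(iv.end, tss))
    site_is_left = tss >= iv.end
    upstream = site_is_left if gene.strand == "+" else not site_is_left
    return -mag if upstream else mag


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or abutting intervals into a sorted disjoint set.

    Strand is dropped (merged intervals are unstranded).
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end)
        else:
            merged.append(Interval(iv.chrom, iv.start, iv.end))
    return merged


def intersect_bp(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    """Total overlapping bases between two merged (disjoint, sorted) sets."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        x, y = a[i], b[j]
        if x.chrom == y.chrom:
            lo = max(x.start, y.start)
            hi = min(x.end, y.end)
            if hi > lo:
                total += hi - lo
            if (x.chrom, x.end) <= (y.chrom, y.end):
                i += 1
            else:
                j += 1
        elif (x.chrom, x.end) < (y.chrom, y.end):
            i += 1
        else:
            j += 1
    return total


class IntervalIndex:
    """Merged per-chromosome interval set with bisect-based point and gap queries."""

    def __init__(self, intervals: Iterable[Interval]):
        self.merged = merge_intervals(intervals)
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for iv in self.merged:
            self._starts.setdefault(iv.chrom, []).append(iv.start)
            self._ends.setdefault(iv.chrom, []).append(iv.end)

    @property
    def total_bp(self) -> int:
        return sum(iv.width for iv in self.merged)

    def contains_point(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[chrom][i]

    def overlaps_any(self, iv: Interval) -> bool:
        """True iff the interval shares >=1 base with an indexed interval."""
        starts = self._starts.get(iv.chrom)
        if not starts:
            return False
        i = bisect_left(starts, iv.end) - 1  # rightmost interval starting before iv.end
        return i >= 0 and self._ends[iv.chrom][i] > iv.start

    def min_gap(self, iv: Interval) -> float:
        """Gap to the nearest indexed interval; inf if none on the chromosome."""
        starts = self._starts.get(iv.chrom)
        if not starts:
            return math.inf
        ends = self._ends[iv.chrom]
        i = bisect_left(starts, iv.start)
        best = math.inf
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(starts):
                g = max(0, max(starts[j], iv.start) - min(ends[j], iv.end))
                best = min(best, g)
        return best


class GenomeAnnotation:
    """Chromosome lengths, genes, and the merged transcribed-region set.

    ``transcribed_regions`` defaults to the merged union of gene bodies; an
    externally supplied region set may be given instead.
    """

    def __init__(
        self,
        chrom_lengths: dict[str, int],
        genes: Sequence[Gene],
        transcribed_regions: Optional[Sequence[Interval]] = None,
    ):
        self.chrom_lengths = dict(chrom_lengths)
        self.genes = list(genes)
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValueError(f"duplicate gene id: {g.id}")
            seen.add(g.id)
            length = self.chrom_lengths.get(g.interval.chrom)
            if length is None:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.interval.chrom}")
            if g.interval.end > length:
                raise ValueError(
                    f"gene {g.id}: interval [{g.interval.start},{g.interval.end}) "
                    f"exceeds {g.interval.chrom} length {length}"
                )
        if transcribed_regions is None:
            transcribed_regions = [g.interval for g in self.genes]
        self.transcribed_regions = merge_intervals(transcribed_regions)
        self._by_id = {g.id: g for g in self.genes}
        # per-chromosome genes sorted by (tss, id) for nearest-TSS bisection
        self._tss_sorted: dict[str, list[Gene]] = {}
        for g in sorted(self.genes, key=lambda g: (g.interval.chrom, g.tss, g.id)):
            self._tss_sorted.setdefault(g.interval.chrom, []).append(g)
        self._tss_values = {
            chrom: [g.tss for g in gs] for chrom, gs in self._tss_sorted.items()
        }
        self._transcribed_index: Optional[IntervalIndex] = None

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def chrom_intervals(self) -> list[Interval]:
        return [Interval(c, 0, n) for c, n in sorted(self.chrom_lengths.items())]

    def genes_on(self, chrom: str) -> list[Gene]:
        """Genes on one chromosome, sorted by (tss, id)."""
        return self._tss_sorted.get(chrom, [])

    def tss_positions(self, chrom: str) -> list[int]:
        """TSS coordinates aligned with :meth:`genes_on`."""
        return self._tss_values.get(chrom, [])

    def transcribed_index(self) -> IntervalIndex:
        if self._transcribed_index is None:
            self._transcribed_index = IntervalIndex(self.transcribed_regions)
        return self._transcribed_index


class ArrayDesign:
    """Probe-covered genomic space of a tiling/promoter array."""

    def __init__(self, covered_regions: Iterable[Interval]):
        self.covered_regions = merge_intervals(covered_regions)
        if not self.covered_regions:
            raise ValueError("array design has no covered regions")

    @property
    def total_bp(self) -> int:
        return sum(iv.width for iv in self.covered_regions)

    def transcribed_fraction(self, annotation: GenomeAnnotation) -> float:
        """Proportion of covered bases inside the annotation's transcribed regions."""
        return intersect_bp(self.covered_regions, annotation.transcribed_regions) / self.total_bp


# ---------------------------------------------------------------------------
# Flat-file IO.  BED is parsed by hand because the contract requires
# line-numbered errors for malformed coordinates; everything is plain TSV.
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: Union[str, Path]) -> list[BindingSite]:
    """Read a 3-6 column BED file into binding sites, preserving file order.

    Column 4 becomes the id when present, otherwise ids are auto-assigned
    ``site_1 ...``; column 5 becomes the score when numeric. Malformed lines
    (non-integer coordinates, start >= end) raise ``ValueError`` naming the
    line number.
    """
    path = Path(path)
    sites: list[BindingSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            try:
                iv = Interval(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else f"site_{len(sites) + 1}"
            score = None
            if len(cols) > 4 and cols[4] not in ("", "."):
                try:
                    score = float(cols[4])
                except ValueError:
                    score = None
            sites.append(BindingSite(iv, name, score))
    return sites


def read_bed_intervals(path: Union[str, Path]) -> list[Interval]:
    return [s.interval for s in read_bed(path)]


def write_bed(sites: Iterable[Union[BindingSite, Interval]], path: Union[str, Path]) -> None:
    """Write sites or intervals as BED; coordinates round-trip bit-exactly."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites, start=1):
            if isinstance(s, BindingSite):
                iv, name, score = s.interval, s.id, s.score
            else:
                iv, name, score = s, f"site_{i}", None
            fields = [iv.chrom, str(iv.start), str(iv.end), name]
            if score is not None:
                fields.append(f"{score:g}")
            fh.write("\t".join(fields) + "\n")


def read_chrom_lengths(path: Union[str, Path]) -> dict[str, int]:
    """Read a two-column chrom/length TSV (header line optional)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                lengths[cols[0]] = int(cols[1])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: non-integer length") from None
    return lengths


def write_chrom_lengths(lengths: dict[str, int], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom in sorted(lengths):
            fh.write(f"{chrom}\t{lengths[chrom]}\n")


def read_gene_table(
    path: Union[str, Path],
    chrom_lengths: Union[str, Path, dict[str, int]],
) -> GenomeAnnotation:
    """Read a gene TSV with header columns chrom,start,end,strand,id.

    ``chrom_lengths`` is a sidecar TSV path or a mapping. Duplicate gene ids
    and strands outside {+,-} are errors.
    """
    if not isinstance(chrom_lengths, dict):
        chrom_lengths = read_chrom_lengths(chrom_lengths)
    path = Path(path)
    genes: list[Gene] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            idx = {name: header.index(name) for name in ("chrom", "start", "end", "strand", "id")}
        except ValueError as exc:
            raise ValueError(
                f"{path}: header must contain chrom,start,end,strand,id (got {header})"
            ) from exc
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            strand = cols[idx["strand"]]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            try:
                start, end = int(cols[idx["start"]]), int(cols[idx["end"]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            genes.append(Gene(cols[idx["id"]], Interval(cols[idx["chrom"]], start, end, strand)))
    return GenomeAnnotation(chrom_lengths, genes)


def write_gene_table(annotation: GenomeAnnotation, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tid\n")
        for g in sorted(annotation.genes, key=lambda g: (g.interval.chrom, g.interval.start, g.id)):
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{g.id}\n")


def _gff3_attr(attrs: str, keys: tuple[str, ...] = ("ID", "gene_id", "Name")) -> Optional[str]:
    for part in attrs.rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() in keys:
                return v.strip()
    return None


def read_gff3_genes(
    path: Union[str, Path],
    chrom_lengths: Union[str, Path, dict[str, int]],
    feature_type: str = "gene",
) -> GenomeAnnotation:
    """Read gene features from GFF3 (1-based inclusive, converted on read)."""
    if not isinstance(chrom_lengths, dict):
        chrom_lengths = read_chrom_lengths(chrom_lengths)
    path = Path(path)
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if cols[2] != feature_type:
                continue
            strand = cols[6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            gene_id = _gff3_attr(cols[8]) or f"gene_{len(genes) + 1}"
            genes.append(Gene(gene_id, Interval(cols[0], start1 - 1, end1, strand)))
    return GenomeAnnotation(chrom_lengths, genes)
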