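"""Promoter-array capture prediction and cross-platform target overlap.

A promoter array tiles a strand-oriented window around each gene's TSS
(``[TSS - upstream, TSS + downstream]`` in gene coordinates, inclusive at both
ends after orientation). A binding site is "captured" when it overlaps any
gene's window — a probe at a neighbouring gene's promoter still detects the
fragment. Gene-level capture asks whether at least one of a gene's assigned
(nearest-TSS) sites is captured.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import BindingSite, Gene, GenomeAnnotation, Interval, IntervalIndex
from .tss import nearest_tss

__all__ = [
    "PromoterWindow",
    "PLATFORM_WINDOWS",
    "gene_window",
    "site_captured",
    "CaptureResult",
    "capture_fractions",
    "OverlapResult",
    "target_overlap",
]


@dataclass(frozen=True)
class PromoterWindow:
    """A platform's promoter window, in bp upstream/downstream of the TSS."""

    platform: str
    upstream_bp: int
    downstream_bp: int

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be >= 0")
        if self.upstream_bp + self.downstream_bp == 0:
            raise ValueError("window must have positive extent")


#: Default promoter-array windows of the three common commercial platforms.
PLATFORM_WINDOWS: dict[str, PromoterWindow] = {
    "Nimblegen": PromoterWindow("Nimblegen", 3500, 750),
    "Agilent": PromoterWindow("Agilent", 5500, 2500),
    "Affymetrix": PromoterWindow("Affymetrix", 7500, 2450),
}


def gene_window(gene: Gene, window: PromoterWindow) -> Interval:
    """Genomic half-open interval of a gene's oriented promoter window.

    Bounds are inclusive at both ends after strand orientation, so the
    half-open interval ends one past the inclusive genomic bound.
    """
    tss = gene.tss
    if gene.strand == "+":
        lo = tss - window.upstream_bp
        hi = tss + window.downstream_bp
    else:
        lo = tss - window.downstream_bp
        hi = tss + window.upstream_bp
    return Interval(gene.interval.chrom, max(0, lo), hi + 1)


def _window_index(annotation: GenomeAnnotation, window: PromoterWindow) -> IntervalIndex:
    return IntervalIndex(gene_window(g, window) for g in annotation.genes)


def site_captured(
    site: BindingSite, annotation: GenomeAnnotation, window: PromoterWindow
) -> bool:
    """True iff the site overlaps at least one gene's promoter window."""
    index = _window_index(annotation, window)
    return index.overlaps_any(site.interval)


@dataclass
class CaptureResult:
    platform: str
    n_sites: int
    n_captured_sites: int
    site_fraction: float
    n_genes: int  # genes with >=1 assigned site
    n_captured_genes: int
    gene_fraction: float


def capture_fractions(
    sites: Sequence[BindingSite],
    annotation: GenomeAnnotation,
    window: PromoterWindow,
) -> CaptureResult:
    """Fractions of sites and of target genes captured by a promoter window.

    ``site_fraction`` = captured sites / all sites. ``gene_fraction`` counts a
    gene as captured when any of its assigned sites overlaps any window; the
    denominator is genes with >=1 assigned site.
    """
    if not sites:
        raise ValueError("capture_fractions undefined for an empty site list")
    index = _window_index(annotation, window)
    n_captured = 0
    gene_sites: dict[str, bool] = {}
    for site in sites:
        captured = index.overlaps_any(site.interval)
        if captured:
            n_captured += 1
        hit = nearest_tss(site, annotation)
        if hit is not None:
            gene_sites[hit.gene_id] = gene_sites.get(hit.gene_id, False) or captured
    n_genes = len(gene_sites)
    n_captured_genes = sum(gene_sites.values())
    return CaptureResult(
        platform=window.platform,
        n_sites=len(sites),
        n_captured_sites=n_captured,
        site_fraction=n_captured / len(sites),
        n_genes=n_genes,
        n_captured_genes=n_captured_genes,
        gene_fraction=n_captured_genes / n_genes if n_genes else float("nan"),
    )


@dataclass
class OverlapResult:
    n_a: int
    n_intersection: int
    fraction: float


def target_overlap(list_a: Sequence[str], list_b: Sequence[str]) -> OverlapResult:
    """Fraction of gene list A found in list B (|A n B| / |A|)."""
    a, b = set(list_a), set(list_b)
    if len(a) != len(list_a) or len(b) != len(list_b):
        raise ValueError("gene lists must contain unique ids")
    if not a:
        raise ValueError("target_overlap undefined for an empty list A")
    inter = len(a & b)
    return OverlapResult(n_a=len(a), n_intersection=inter, fraction=inter / len(a))
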