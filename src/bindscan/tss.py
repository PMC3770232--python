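"""Nearest-TSS assignment, signed distance histograms, and random null site sets.

Each binding site is assigned to the gene whose TSS minimises the absolute
signed distance (ties: overlap first, then lexicographically smallest gene id).
Distances are binned into a symmetric histogram — an "overlap" bin for sites
covering a TSS, half-open ``(0, 4k], (4k, 8k] ...`` bins on each side, and a
``>max`` bin per side — mirroring the standard view of peak sets around TSSs.
"""
from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    ArrayDesign,
    BindingSite,
    Gene,
    GenomeAnnotation,
    Interval,
    signed_tss_distance,
)

__all__ = [
    "NearestTSS",
    "nearest_tss",
    "DistanceHistogram",
    "distance_histogram",
    "random_site_set",
    "gene_distance_map",
    "gene_site_counts",
]


@dataclass(frozen=True)
class NearestTSS:
    gene_id: str
    distance: int  # signed bp; 0 = site overlaps the TSS


def nearest_tss(site: BindingSite, annotation: GenomeAnnotation) -> Optional[NearestTSS]:
    """Assign a site to the gene with the closest TSS.

    Returns ``None`` (no-assignment marker) when the site's chromosome has no
    genes. Ties on |distance| prefer overlap, then the smallest gene id.
    """
    iv = site.interval
    genes = annotation.genes_on(iv.chrom)
    if not genes:
        return None
    tss = annotation.tss_positions(iv.chrom)
    i1 = bisect_left(tss, iv.start)
    i2 = bisect_left(tss, iv.end)
    if i1 < i2:  # >=1 TSS inside the site: overlap, distance 0
        best = min(genes[i1:i2], key=lambda g: g.id)
        return NearestTSS(best.id, 0)
    mags = []
    if i1 > 0:
        mags.append(iv.start - tss[i1 - 1])
    if i1 < len(tss):
        mags.append(tss[i1] - iv.end)
    m = min(mags)
    # all genes attaining the minimum magnitude, on either side
    candidates: list[Gene] = []
    for value in {iv.start - m, iv.end + m}:
        lo = bisect_left(tss, value)
        hi = bisect_right(tss, value)
        candidates.extend(genes[lo:hi])
    best = min(candidates, key=lambda g: g.id)
    return NearestTSS(best.id, signed_tss_distance(site, best))


def _fmt_bp(x: int) -> str:
    if x == 0:
        return "0"
    return f"{x // 1000}k" if x % 1000 == 0 else f"{x}"


@dataclass
class DistanceHistogram:
    """Counts of sites per signed-distance bin around the nearest TSS."""

    bin_width: int
    max_distance: int
    counts: dict[str, int]
    n_total: int
    n_unassigned: int = 0

    @property
    def labels(self) -> list[str]:
        return list(self.counts)

    def percentages(self) -> dict[str, float]:
        if self.n_total == 0:
            raise ValueError("percentage view undefined: histogram has zero sites")
        return {k: 100.0 * v / self.n_total for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin": self.labels, "count": list(self.counts.values())})
        if self.n_total > 0:
            df["percent"] = 100.0 * df["count"] / self.n_total
        else:
            df["percent"] = float("nan")
        return df


def _bin_labels(bin_width: int, max_distance: int) -> list[str]:
    nbins = max_distance // bin_width
    labels = [f"upstream >{_fmt_bp(max_distance)}"]
    for k in range(nbins, 0, -1):
        labels.append(f"upstream ({_fmt_bp((k - 1) * bin_width)},{_fmt_bp(k * bin_width)}]")
    labels.append("overlap")
    for k in range(1, nbins + 1):
        labels.append(f"downstream ({_fmt_bp((k - 1) * bin_width)},{_fmt_bp(k * bin_width)}]")
    labels.append(f"downstream >{_fmt_bp(max_distance)}")
    return labels


def bin_label(distance: int, bin_width: int = 4000, max_distance: int = 40000) -> str:
    """Histogram bin for one signed distance (0 -> "overlap").

    A magnitude d with ``0 < d <= bin_width`` falls in the first bin: bins are
    half-open on the near side, closed on the far side.
    """
    if distance == 0:
        return "overlap"
    side = "upstream" if distance < 0 else "downstream"
    m = abs(distance)
    if m > max_distance:
        return f"{side} >{_fmt_bp(max_distance)}"
    k = -(-m // bin_width)  # ceil
    return f"{side} ({_fmt_bp((k - 1) * bin_width)},{_fmt_bp(k * bin_width)}]"


def distance_histogram(
    sites: Sequence[BindingSite],
    annotation: GenomeAnnotation,
    bin_width: int = 4000,
    max_distance: int = 40000,
) -> DistanceHistogram:
    """Histogram of nearest-TSS signed distances for a site set.

    Sites on chromosomes without genes are excluded from the binned counts and
    reported in ``n_unassigned``; counts partition the assigned sites.
    """
    if max_distance % bin_width != 0:
        raise ValueError("max_distance must be a multiple of bin_width")
    counts = {label: 0 for label in _bin_labels(bin_width, max_distance)}
    n_assigned = 0
    n_unassigned = 0
    for site in sites:
        hit = nearest_tss(site, annotation)
        if hit is None:
            n_unassigned += 1
            continue
        counts[bin_label(hit.distance, bin_width, max_distance)] += 1
        n_assigned += 1
    return DistanceHistogram(bin_width, max_distance, counts, n_assigned, n_unassigned)


def random_site_set(
    space: Union[GenomeAnnotation, ArrayDesign, Sequence[Interval]],
    n: int,
    widths: Optional[Sequence[int]] = None,
    seed: int = 0,
    width_sampler: Optional[Callable[[np.random.Generator], int]] = None,
    id_prefix: str = "random",
) -> list[BindingSite]:
    """Place ``n`` sites uniformly over covered space; deterministic per seed.

    ``space`` may be an annotation (whole chromosomes), an array design
    (covered regions), or an explicit region list. Widths are resampled with
    replacement from ``widths`` (e.g. the observed site widths) unless a
    ``width_sampler(rng) -> int`` is supplied. Sites never straddle region
    boundaries: draws that do not fit are resampled.
    """
    if n <= 0:
        return []
    if isinstance(space, GenomeAnnotation):
        regions = space.chrom_intervals()
    elif isinstance(space, ArrayDesign):
        regions = space.covered_regions
    else:
        regions = list(space)
    if not regions:
        raise ValueError("random_site_set: empty covered space")
    if widths is None and width_sampler is None:
        raise ValueError("provide observed widths to resample, or a width_sampler")
    rng = np.random.default_rng(seed)
    lengths = np.array([r.width for r in regions], dtype=float)
    probs = lengths / lengths.sum()
    max_region = int(lengths.max())
    sites: list[BindingSite] = []
    for i in range(n):
        for _ in range(1000):
            if width_sampler is not None:
                w = int(width_sampler(rng))
            else:
                w = int(widths[rng.integers(0, len(widths))])
            if w < 1:
                raise ValueError("sampled width < 1")
            if w > max_region:
                raise ValueError(f"sampled width {w} exceeds the largest covered region")
            r = regions[rng.choice(len(regions), p=probs)]
            if w > r.width:
                continue
            start = int(rng.integers(r.start, r.end - w + 1))
            sites.append(BindingSite(Interval(r.chrom, start, start + w), f"{id_prefix}_{i + 1}"))
            break
        else:
            raise RuntimeError("random_site_set: retry cap exceeded placing a site")
    return sites


def gene_distance_map(
    sites: Sequence[BindingSite], annotation: GenomeAnnotation
) -> dict[str, int]:
    """Per-gene signed distance to its closest assigned site.

    Inverts nearest-TSS assignment: each assigned gene gets the signed
    distance of minimum magnitude over its sites (per-gene view of the
    distance histogram).
    """
    best: dict[str, int] = {}
    for site in sites:
        hit = nearest_tss(site, annotation)
        if hit is None:
            continue
        if hit.gene_id not in best or abs(hit.distance) < abs(best[hit.gene_id]):
            best[hit.gene_id] = hit.distance
    return best


def gene_site_counts(
    sites: Sequence[BindingSite], annotation: GenomeAnnotation
) -> dict[str, int]:
    """Number of sites assigned (nearest-TSS) to each gene."""
    counts: dict[str, int] = {}
    for site in sites:
        hit = nearest_tss(site, annotation)
        if hit is None:
            continue
        counts[hit.gene_id] = counts.get(hit.gene_id, 0) + 1
    return counts
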