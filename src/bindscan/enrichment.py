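"""Site classification against transcribed regions and regulatory-element tracks.

Two enrichment views are provided: the odds ratio of a site set's
non-transcribed fraction against a platform background (exact binomial test),
and the ratio-of-proportions fold of element proximity between an observed and
a random site set (Fisher's exact test). Both tests are two-sided with no
multiple-testing correction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .core import BindingSite, GenomeAnnotation, Interval, IntervalIndex

__all__ = [
    "EnrichmentResult",
    "classify_transcribed",
    "odds_enrichment",
    "element_proximity_fraction",
    "proximity_fold",
]


@dataclass
class EnrichmentResult:
    n_sites: int
    observed_fraction: float
    background_fraction: float
    fold: float  # ratio of proportions, observed / background
    odds_ratio: float
    p_value: float
    test_name: str


def classify_transcribed(
    sites: Sequence[BindingSite], annotation: GenomeAnnotation
) -> tuple[int, int]:
    """Partition sites into (transcribed, non-transcribed) counts.

    A site is transcribed iff its midpoint lies inside a merged transcribed
    region, so a site straddling a region edge is assigned to exactly one
    class.
    """
    index = annotation.transcribed_index()
    n_in = sum(
        1 for s in sites if index.contains_point(s.interval.chrom, s.interval.midpoint)
    )
    return n_in, len(sites) - n_in


def _odds(p: float) -> float:
    if p >= 1.0:
        return math.inf
    return p / (1.0 - p)


def odds_enrichment(
    count_non: int, count_tr: int, bg_non_fraction: float
) -> EnrichmentResult:
    """Enrichment of a site set in non-transcribed space vs a fixed background.

    ``bg_non_fraction`` is the platform's non-transcribed proportion. Reports
    the odds ratio (obs odds / background odds), the simple fold
    (obs / background), and a two-sided exact binomial p-value.
    """
    n = count_non + count_tr
    if n < 1:
        raise ValueError("need at least one site")
    if not 0.0 < bg_non_fraction < 1.0:
        raise ValueError("background fraction must be strictly between 0 and 1")
    obs = count_non / n
    odds_ratio = _odds(obs) / _odds(bg_non_fraction)
    fold = obs / bg_non_fraction
    p = stats.binomtest(count_non, n, bg_non_fraction, alternative="two-sided").pvalue
    return EnrichmentResult(
        n_sites=n,
        observed_fraction=obs,
        background_fraction=bg_non_fraction,
        fold=fold,
        odds_ratio=odds_ratio,
        p_value=p,
        test_name="binomial_exact",
    )


def _near_count(
    sites: Sequence[BindingSite], index: IntervalIndex, max_gap: int
) -> int:
    return sum(1 for s in sites if index.min_gap(s.interval) <= max_gap)


def element_proximity_fraction(
    sites: Sequence[BindingSite],
    elements: Sequence[Interval],
    max_gap: int = 1000,
) -> float:
    """Fraction of sites within ``max_gap`` bases (inclusive) of an element.

    Overlapping an element counts (gap 0). Empty site lists are undefined and
    raise.
    """
    if not sites:
        raise ValueError("element_proximity_fraction undefined for an empty site list")
    if not elements:
        return 0.0
    index = IntervalIndex(elements)
    return _near_count(sites, index, max_gap) / len(sites)


def proximity_fold(
    sites: Sequence[BindingSite],
    random_sites: Sequence[BindingSite],
    elements: Sequence[Interval],
    max_gap: int = 1000,
) -> EnrichmentResult:
    """Element-proximity fold of observed vs random sites.

    Fold is the ratio of proportions near an element; the p-value is a
    two-sided Fisher's exact test on the 2x2 (near/far x observed/random)
    table. A zero random fraction leaves fold as NaN (flagged).
    """
    if not sites or not random_sites:
        raise ValueError("both site sets must be non-empty")
    if elements:
        index = IntervalIndex(elements)
        near_obs = _near_count(sites, index, max_gap)
        near_rnd = _near_count(random_sites, index, max_gap)
    else:
        near_obs = near_rnd = 0
    n_obs, n_rnd = len(sites), len(random_sites)
    f_obs = near_obs / n_obs
    f_rnd = near_rnd / n_rnd
    fold = f_obs / f_rnd if f_rnd > 0 else math.nan
    table = [[near_obs, n_obs - near_obs], [near_rnd, n_rnd - near_rnd]]
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        n_sites=n_obs,
        observed_fraction=f_obs,
        background_fraction=f_rnd,
        fold=fold,
        odds_ratio=float(odds_ratio),
        p_value=float(p),
        test_name="fisher_exact",
    )
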