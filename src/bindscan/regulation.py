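"""Regulation calls from knockdown/overexpression contrasts and their summaries.

Each gene carries a (log2 fold change, p-value) pair per contrast. A contrast
passes as "up" when the linear fold is at or above the threshold and p is
strictly below the p cutoff, "down" when the fold is at or below the
reciprocal. Directions are mapped to the factor's effect: a gene down upon
knockdown or up upon overexpression is activated by the factor; the mirror
pattern is repression; contradictory passing contrasts are flagged
"conflicting" and count toward regulated totals but neither direction.

Summaries reproduce the standard regulated-fraction views: per contrast and
union, by nearest-site distance bin (with a chi-square homogeneity test), by
per-gene site count, and by gene-position type around each site (type 1 the
nearest gene, type 2 the nearest gene on the opposite side, type 3 the next
gene beyond type 1 on the same side).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import BindingSite, GenomeAnnotation
from .tss import bin_label, nearest_tss, _bin_labels

__all__ = [
    "RegulationThresholds",
    "call_contrast",
    "combine_calls",
    "call_genes",
    "read_expression",
    "write_expression",
    "summarize_regulation",
    "regulated_fraction",
    "regulated_by_distance_bin",
    "regulated_by_site_count",
    "GenePositionTypes",
    "classify_gene_position",
    "regulated_by_position_type",
]

CONTRASTS = ("KD", "OE")
STATUSES = ("up", "down", "unchanged")


@dataclass(frozen=True)
class RegulationThresholds:
    """Linear fold-change and p-value cutoffs for a regulation call."""

    fold: float = 1.5
    p: float = 0.05

    def __post_init__(self) -> None:
        if self.fold <= 1.0:
            raise ValueError("fold threshold must be > 1")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p threshold must be in (0, 1)")


def call_contrast(log2fc: float, p: float, thr: RegulationThresholds) -> str:
    """Status of one contrast row: "up", "down" or "unchanged".

    Fold thresholds are symmetric in linear space (>= thr up, <= 1/thr down);
    the p cutoff is strict. NaN inputs raise — exclusion of genes with missing
    data is handled by :func:`call_genes`.
    """
    if math.isnan(log2fc) or math.isnan(p):
        raise ValueError("missing fold change or p-value")
    if p < thr.p:
        fold = 2.0 ** log2fc
        if fold >= thr.fold:
            return "up"
        if fold <= 1.0 / thr.fold:
            return "down"
    return "unchanged"


def combine_calls(kd_status: str, oe_status: str) -> str:
    """Overall factor effect from the two contrast statuses.

    Down in KD or up in OE signals activation by the factor; up in KD or down
    in OE signals repression. Both signals present -> "conflicting"; no
    passing contrast -> "unchanged".
    """
    signals = set()
    if kd_status == "down" or oe_status == "up":
        signals.add("activated")
    if kd_status == "up" or oe_status == "down":
        signals.add("repressed")
    if signals == {"activated", "repressed"}:
        return "conflicting"
    if "activated" in signals:
        return "activated_by_factor"
    if "repressed" in signals:
        return "repressed_by_factor"
    return "unchanged"


def read_expression(path: Union[str, Path]) -> pd.DataFrame:
    """Read an expression-contrast TSV with columns gene, log2fc, p, contrast."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "contrast": str})
    missing = {"gene", "log2fc", "p", "contrast"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["contrast"]) - set(CONTRASTS)
    if bad:
        raise ValueError(f"{path}: unknown contrast labels {sorted(bad)}")
    return df


def write_expression(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)


def call_genes(
    expression: pd.DataFrame, thr: RegulationThresholds
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene regulation calls from a long-format contrast table.

    Returns (calls, excluded): ``calls`` is indexed by gene with columns
    kd_status, oe_status, overall and regulated (any contrast passed,
    conflicting included); ``excluded`` lists genes dropped because every row
    had a missing fold change or p-value. A gene with one usable contrast is
    called on that contrast alone (the other treated as unchanged).
    """
    statuses: dict[str, dict[str, str]] = {}
    usable: set[str] = set()
    seen: set[str] = set()
    for row in expression.itertuples(index=False):
        gene = row.gene
        seen.add(gene)
        if pd.isna(row.log2fc) or pd.isna(row.p):
            continue
        usable.add(gene)
        statuses.setdefault(gene, {})[row.contrast] = call_contrast(
            float(row.log2fc), float(row.p), thr
        )
    excluded = sorted(seen - usable)
    records = []
    for gene in sorted(usable):
        kd = statuses.get(gene, {}).get("KD", "unchanged")
        oe = statuses.get(gene, {}).get("OE", "unchanged")
        overall = combine_calls(kd, oe)
        records.append(
            {
                "gene": gene,
                "kd_status": kd,
                "oe_status": oe,
                "overall": overall,
                "regulated": overall != "unchanged",
            }
        )
    calls = pd.DataFrame.from_records(records).set_index("gene") if records else pd.DataFrame(
        columns=["kd_status", "oe_status", "overall", "regulated"]
    )
    return calls, excluded


def _contrast_direction_counts(calls: pd.DataFrame, contrast: str) -> tuple[int, int, int]:
    """(regulated, activated, repressed) counts for one contrast.

    KD statuses are sign-flipped to factor effect: down in KD = activated.
    """
    col = "kd_status" if contrast == "KD" else "oe_status"
    s = calls[col]
    n_up = int((s == "up").sum())
    n_down = int((s == "down").sum())
    if contrast == "KD":
        activated, repressed = n_down, n_up
    else:
        activated, repressed = n_up, n_down
    return n_up + n_down, activated, repressed


def summarize_regulation(calls: pd.DataFrame) -> pd.DataFrame:
    """Regulated / activated / repressed counts per contrast and for the union.

    "activated" and "repressed" are factor effects (KD sign-flipped);
    conflicting genes count as regulated in the union row but in neither
    direction.
    """
    n = len(calls)
    rows = []
    overall = calls["overall"] if n else pd.Series(dtype=object)
    union_reg = int((overall != "unchanged").sum())
    rows.append(
        {
            "scope": "union",
            "n_genes": n,
            "regulated": union_reg,
            "activated": int((overall == "activated_by_factor").sum()),
            "repressed": int((overall == "repressed_by_factor").sum()),
            "conflicting": int((overall == "conflicting").sum()),
            "fraction_regulated": union_reg / n if n else math.nan,
        }
    )
    for contrast in ("OE", "KD"):
        if n:
            reg, act, rep = _contrast_direction_counts(calls, contrast)
        else:
            reg = act = rep = 0
        rows.append(
            {
                "scope": contrast,
                "n_genes": n,
                "regulated": reg,
                "activated": act,
                "repressed": rep,
                "conflicting": 0,
                "fraction_regulated": reg / n if n else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("scope")


def regulated_fraction(
    target_genes: Iterable[str], calls: pd.DataFrame
) -> pd.DataFrame:
    """Regulation summary restricted to target genes with profiling data.

    Denominators are targets present in ``calls`` (i.e. with usable
    profiling rows).
    """
    targets = [g for g in set(target_genes) if g in calls.index]
    return summarize_regulation(calls.loc[sorted(targets)])


def _chi2_homogeneity(table: pd.DataFrame) -> tuple[float, float]:
    """Chi-square homogeneity of regulated fractions across non-empty bins."""
    sub = table[table["n_genes"] > 0]
    reg = sub["n_regulated"].to_numpy()
    unreg = (sub["n_genes"] - sub["n_regulated"]).to_numpy()
    if len(sub) < 2 or reg.sum() == 0 or unreg.sum() == 0:
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(np.vstack([reg, unreg]))
    return float(stat), float(p)


def regulated_by_distance_bin(
    gene_distances: Mapping[str, int],
    calls: pd.DataFrame,
    bin_width: int = 4000,
    max_distance: int = 40000,
) -> tuple[pd.DataFrame, float, float]:
    """Regulated fraction per nearest-site distance bin.

    ``gene_distances`` maps gene -> signed distance of its closest site (see
    :func:`bindscan.tss.gene_distance_map`). Only genes with profiling data
    enter the denominators. Returns (table, chi2_statistic, p_value) where
    the test asks whether the regulated fraction is homogeneous across
    non-empty bins. Empty bins are kept with denominator 0 and NaN fraction.
    """
    labels = _bin_labels(bin_width, max_distance)
    per_bin: dict[str, list[str]] = {lab: [] for lab in labels}
    for gene, d in gene_distances.items():
        if gene in calls.index:
            per_bin[bin_label(d, bin_width, max_distance)].append(gene)
    rows = []
    for lab in labels:
        genes = per_bin[lab]
        n_reg = int(calls.loc[genes, "regulated"].sum()) if genes else 0
        rows.append(
            {
                "bin": lab,
                "n_genes": len(genes),
                "n_regulated": n_reg,
                "fraction": n_reg / len(genes) if genes else math.nan,
            }
        )
    table = pd.DataFrame(rows)
    stat, p = _chi2_homogeneity(table)
    return table, stat, p


def regulated_by_site_count(
    site_counts: Mapping[str, int],
    calls_by_threshold: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Regulated fraction for genes with one site vs two or more.

    ``calls_by_threshold`` maps a threshold label (e.g. "1.5") to a calls
    frame; rows "any", "1", "2+" report denominators (genes with profiling
    data) and the regulated count/fraction at each threshold. Empty groups
    are flagged with NaN fractions.
    """
    groups = {
        "any": [g for g in site_counts],
        "1": [g for g, c in site_counts.items() if c == 1],
        "2+": [g for g, c in site_counts.items() if c >= 2],
    }
    rows = []
    for name, genes in groups.items():
        row: dict[str, object] = {"group": name, "n_targets": len(genes)}
        for label, calls in calls_by_threshold.items():
            with_data = [g for g in genes if g in calls.index]
            n_reg = int(calls.loc[with_data, "regulated"].sum()) if with_data else 0
            row[f"n_with_data_{label}"] = len(with_data)
            row[f"n_regulated_{label}"] = n_reg
            row[f"fraction_{label}"] = n_reg / len(with_data) if with_data else math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


@dataclass(frozen=True)
class GenePositionTypes:
    """Gene ids occupying the three position types around one site."""

    type1: Optional[str]  # nearest-TSS gene
    type2: Optional[str]  # nearest gene on the opposite side of the site
    type3: Optional[str]  # second-nearest gene on the type-1 side


def classify_gene_position(
    site: BindingSite, annotation: GenomeAnnotation
) -> GenePositionTypes:
    """Assign the type 1/2/3 genes around a binding site.

    Type 1 is the nearest-TSS gene; its side of the site midpoint defines the
    reference direction. Type 2 is the nearest gene whose TSS lies on the
    opposite side; type 3 the next gene beyond type 1 on the same side. Slots
    may be empty near chromosome ends; ties break by gene id.
    """
    hit = nearest_tss(site, annotation)
    if hit is None:
        return GenePositionTypes(None, None, None)
    genes = annotation.genes_on(site.interval.chrom)
    g1 = annotation.gene(hit.gene_id)
    mid = site.interval.midpoint
    d1_side = 1 if g1.tss >= mid else -1

    def side(g) -> int:
        return 1 if g.tss >= mid else -1

    def sort_key(g):
        from .core import signed_tss_distance

        return (abs(signed_tss_distance(site, g)), g.id)

    same = sorted(
        (g for g in genes if g.id != g1.id and side(g) == d1_side), key=sort_key
    )
    opposite = sorted(
        (g for g in genes if g.id != g1.id and side(g) == -d1_side), key=sort_key
    )
    return GenePositionTypes(
        type1=g1.id,
        type2=opposite[0].id if opposite else None,
        type3=same[0].id if same else None,
    )


def regulated_by_position_type(
    sites: Sequence[BindingSite],
    annotation: GenomeAnnotation,
    calls_by_threshold: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Regulated fraction of type 1/2/3 genes over all sites.

    Genes are deduplicated within each type; a gene occupying several types
    (for different sites) counts in each. Types with no genes are flagged
    with NaN fractions.
    """
    by_type: dict[str, set[str]] = {"1": set(), "2": set(), "3": set()}
    for site in sites:
        pos = classify_gene_position(site, annotation)
        for key, gid in (("1", pos.type1), ("2", pos.type2), ("3", pos.type3)):
            if gid is not None:
                by_type[key].add(gid)
    rows = []
    for key in ("1", "2", "3"):
        genes = sorted(by_type[key])
        row: dict[str, object] = {"type": key, "n_genes": len(genes)}
        for label, calls in calls_by_threshold.items():
            with_data = [g for g in genes if g in calls.index]
            n_reg = int(calls.loc[with_data, "regulated"].sum()) if with_data else 0
            row[f"n_with_data_{label}"] = len(with_data)
            row[f"n_regulated_{label}"] = n_reg
            row[f"fraction_{label}"] = n_reg / len(with_data) if with_data else math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("type")
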