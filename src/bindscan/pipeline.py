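"""End-to-end report generation tying the analysis stages together.

Each ``run_*`` function consumes in-memory objects and returns tidy
DataFrames; :func:`run_all` chains them on a synthetic dataset and writes one
TSV per report section plus a run log (config hash, seed, version). The CLI
is a thin wrapper over these functions.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .core import ArrayDesign, BindingSite, GenomeAnnotation, Interval
from .coverage import PLATFORM_WINDOWS, capture_fractions
from .enrichment import classify_transcribed, odds_enrichment, proximity_fold
from .motif import (
    compile_pattern,
    matched_random_fraction,
    motif_occupancy,
)
from .regulation import (
    RegulationThresholds,
    call_genes,
    regulated_by_distance_bin,
    regulated_by_position_type,
    regulated_by_site_count,
    regulated_fraction,
    summarize_regulation,
)
from .simulate import SimulationConfig, SyntheticDataset, simulate_dataset
from .tss import (
    distance_histogram,
    gene_distance_map,
    gene_site_counts,
    nearest_tss,
    random_site_set,
)

__all__ = ["run_tss", "run_enrichment", "run_motif", "run_coverage", "run_regulation", "run_all"]

DEFAULT_THRESHOLDS = (RegulationThresholds(1.5, 0.05), RegulationThresholds(1.25, 0.05))


def run_tss(
    peaks: Sequence[BindingSite],
    annotation: GenomeAnnotation,
    n_random_sets: int = 3,
    seed: int = 0,
    bin_width: int = 4000,
    max_distance: int = 40000,
) -> dict[str, pd.DataFrame]:
    """Distance histogram of the observed peaks plus random null sets."""
    hist = distance_histogram(peaks, annotation, bin_width, max_distance)
    out = {"distance_histogram": hist.to_frame()}
    widths = [p.width for p in peaks]
    frames = []
    for k in range(n_random_sets):
        rand = random_site_set(annotation, len(peaks), widths=widths, seed=seed + k)
        f = distance_histogram(rand, annotation, bin_width, max_distance).to_frame()
        f.insert(0, "set", k + 1)
        frames.append(f)
    if frames:
        out["random_distance_histograms"] = pd.concat(frames, ignore_index=True)
    return out


def run_enrichment(
    peaks: Sequence[BindingSite],
    annotation: GenomeAnnotation,
    element_tracks: dict[str, Sequence[Interval]],
    array_design: Optional[ArrayDesign] = None,
    seed: int = 0,
    max_gap: int = 1000,
    distal_cutoff: int = 4000,
) -> dict[str, pd.DataFrame]:
    """Transcribed/non-transcribed enrichment and element-proximity folds."""
    design = array_design or ArrayDesign(annotation.chrom_intervals())
    n_in, n_out = classify_transcribed(peaks, annotation)
    bg_non = 1.0 - design.transcribed_fraction(annotation)
    enr = odds_enrichment(n_out, n_in, bg_non)
    transcribed = pd.DataFrame(
        [
            {
                "n_sites": enr.n_sites,
                "n_transcribed": n_in,
                "n_non_transcribed": n_out,
                "non_transcribed_fraction": enr.observed_fraction,
                "background_non_transcribed_fraction": enr.background_fraction,
                "fold": enr.fold,
                "odds_ratio": enr.odds_ratio,
                "p_value": enr.p_value,
                "test": enr.test_name,
            }
        ]
    )
    distal = []
    for p in peaks:
        hit = nearest_tss(p, annotation)
        if hit is not None and abs(hit.distance) > distal_cutoff:
            distal.append(p)
    rows = []
    if distal:
        widths = [p.width for p in distal]
        rand = random_site_set(design, len(distal), widths=widths, seed=seed)
        for name in sorted(element_tracks):
            res = proximity_fold(distal, rand, list(element_tracks[name]), max_gap)
            rows.append(
                {
                    "track": name,
                    "n_distal_sites": res.n_sites,
                    "observed_fraction": res.observed_fraction,
                    "random_fraction": res.background_fraction,
                    "fold": res.fold,
                    "p_value": res.p_value,
                    "test": res.test_name,
                }
            )
    proximity = pd.DataFrame(rows)
    return {"transcribed_enrichment": transcribed, "element_proximity": proximity}


def run_motif(
    peaks: Sequence[BindingSite],
    genome,
    consensus: str = "ATCRAT",
    array_design: Optional[ArrayDesign] = None,
    annotation: Optional[GenomeAnnotation] = None,
    seed: int = 0,
    code_overrides=None,
) -> dict[str, pd.DataFrame]:
    """Consensus occupancy of bound regions vs width-matched random regions."""
    if array_design is None:
        if annotation is None:
            raise ValueError("need an array design or an annotation for covered space")
        array_design = ArrayDesign(annotation.chrom_intervals())
    pattern = compile_pattern(consensus, code_overrides=code_overrides)
    cmp_res = matched_random_fraction(peaks, array_design, genome, pattern, seed=seed)
    occ = motif_occupancy(array_design, peaks, genome, pattern)
    summary = pd.DataFrame(
        [
            {
                "set": "bound",
                "n_regions": cmp_res.bound.n_regions,
                "n_with_consensus": cmp_res.bound.n_with_match,
                "fraction_with_consensus": cmp_res.bound.fraction_with_match,
                "gc_content": cmp_res.bound.gc_content_of_regions,
            },
            {
                "set": "random",
                "n_regions": cmp_res.random.n_regions,
                "n_with_consensus": cmp_res.random.n_with_match,
                "fraction_with_consensus": cmp_res.random.fraction_with_match,
                "gc_content": cmp_res.random.gc_content_of_regions,
            },
        ]
    )
    summary["p_value_bound_vs_random"] = cmp_res.p_value
    occupancy = pd.DataFrame(
        [
            {
                "total_consensus_hits": occ.total_hits,
                "hits_in_bound_regions": occ.bound_hits,
                "fraction_bound": occ.fraction_bound,
            }
        ]
    )
    return {"consensus_summary": summary, "consensus_occupancy": occupancy}


def run_coverage(
    peaks: Sequence[BindingSite], annotation: GenomeAnnotation
) -> dict[str, pd.DataFrame]:
    """Promoter-array capture fractions for the default platform windows."""
    rows = []
    for name, window in PLATFORM_WINDOWS.items():
        res = capture_fractions(peaks, annotation, window)
        rows.append(
            {
                "platform": name,
                "upstream_bp": window.upstream_bp,
                "downstream_bp": window.downstream_bp,
                "n_sites": res.n_sites,
                "site_fraction": res.site_fraction,
                "n_target_genes": res.n_genes,
                "gene_fraction": res.gene_fraction,
            }
        )
    return {"promoter_array_capture": pd.DataFrame(rows)}


def run_regulation(
    peaks: Sequence[BindingSite],
    annotation: GenomeAnnotation,
    expression: pd.DataFrame,
    thresholds: Sequence[RegulationThresholds] = DEFAULT_THRESHOLDS,
    bin_width: int = 4000,
    max_distance: int = 40000,
) -> dict[str, pd.DataFrame]:
    """Regulated-fraction summaries: overall, by distance, site count, position."""
    targets = sorted(gene_site_counts(peaks, annotation))
    dmap = gene_distance_map(peaks, annotation)
    counts = gene_site_counts(peaks, annotation)
    out: dict[str, pd.DataFrame] = {}
    calls_by_label: dict[str, pd.DataFrame] = {}
    for thr in thresholds:
        label = f"{thr.fold:g}"
        calls, excluded = call_genes(expression, thr)
        calls_by_label[label] = calls
        summary = regulated_fraction(targets, calls).reset_index()
        summary.insert(0, "fold_threshold", thr.fold)
        summary["n_excluded_missing"] = len(excluded)
        out[f"regulation_summary_{label}"] = summary
        target_calls = calls.loc[[g for g in targets if g in calls.index]]
        table, stat, p = regulated_by_distance_bin(
            {g: d for g, d in dmap.items() if g in target_calls.index},
            target_calls,
            bin_width,
            max_distance,
        )
        table.insert(0, "fold_threshold", thr.fold)
        table["chi2_stat"] = stat
        table["chi2_p"] = p
        out[f"regulated_by_distance_{label}"] = table
    out["regulated_by_site_count"] = regulated_by_site_count(counts, calls_by_label).reset_index()
    out["regulated_by_position_type"] = regulated_by_position_type(
        peaks, annotation, calls_by_label
    ).reset_index()
    return out


def _config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(
    config: SimulationConfig,
    outdir: Optional[Union[str, Path]] = None,
    n_random_sets: int = 3,
) -> dict[str, pd.DataFrame]:
    """Simulate a dataset and run every analysis stage on it.

    When ``outdir`` is given, the dataset bundle, one TSV per report, and a
    ``run_log.txt`` (config hash, seed, version) are written there.
    """
    dataset = simulate_dataset(config, outdir=Path(outdir) / "dataset" if outdir else None)
    reports: dict[str, pd.DataFrame] = {}
    seed = int(config.seed)
    annotation = dataset.annotation
    reports.update(run_tss(dataset.peaks, annotation, n_random_sets=n_random_sets, seed=seed))
    reports.update(
        run_enrichment(dataset.peaks, annotation, dataset.elements, seed=seed)
    )
    if dataset.sequences is not None:
        reports.update(
            run_motif(
                dataset.peaks,
                dataset.sequences,
                consensus=config.consensus,
                annotation=annotation,
                seed=seed,
            )
        )
    reports.update(run_coverage(dataset.peaks, annotation))
    reports.update(run_regulation(dataset.peaks, annotation, dataset.expression))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in reports.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write(f"bindscan {__version__}\n")
            fh.write(f"seed\t{seed}\n")
            fh.write(f"config_hash\t{_config_hash(config)}\n")
            fh.write(f"reports\t{', '.join(sorted(reports))}\n")
    return reports
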