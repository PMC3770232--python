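"""Synthetic genomes, peak sets, element tracks and expression contrasts.

The generator emits a complete, parseable input bundle with a ground-truth
manifest so every downstream stage can be tested without external data. The
statistical structure mirrors a ChIP/ChAP-style binding-site study on a
gene-dense tiling platform:

* gene bodies cover ~80% of the genome (so the non-transcribed background is
  ~20%), placed uniformly without overlap, strands Bernoulli(1/2);
* peak widths are lognormal with mean ~503 bp truncated to [149, 1107] bp; a
  configurable fraction of peaks is centred on a truncated-normal bell around
  randomly chosen TSSs (defaults put ~47% of peaks within 4 kb of a TSS) and
  the remainder is uniform;
* sequences are i.i.d. bases at a configurable GC content (47% by default),
  with a degenerate 6-mer consensus written into a configurable fraction of
  peaks (47.2% by default) at a uniform position, random strand;
* element tracks (open-chromatin, enhancer, insulator proxies) are placed so
  the expected within-1-kb proximity fold of distal peaks over random sites
  equals a configured fold (defaults 1.49 / 1.45 / 1.01);
* two expression contrasts (KD, OE) carry a planted regulated fraction with a
  configurable activation share and KD/OE response asymmetry; unregulated
  genes draw log2 fold changes from a null normal and uniform p-values.

Every stage draws from its own RNG stream derived from the master seed, so
outputs are byte-identical across runs and adding a stage does not perturb
earlier ones.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    BindingSite,
    Gene,
    GenomeAnnotation,
    Interval,
    write_bed,
    write_chrom_lengths,
    write_gene_table,
)
from .motif import MotifPattern, compile_pattern
from .tss import nearest_tss

__all__ = [
    "ElementTrackConfig",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_peaks",
    "simulate_elements",
    "simulate_expression",
    "simulate_dataset",
]

_STAGE = {"genes": 11, "sequence": 12, "peaks": 13, "motif": 14, "elements": 15, "expression": 16}


@dataclass(frozen=True)
class ElementTrackConfig:
    """One regulatory-element track: count, element width, target proximity fold."""

    n_elements: int
    width_bp: int
    proximity_fold: float


def _default_tracks() -> dict[str, ElementTrackConfig]:
    return {
        "dhs": ElementTrackConfig(250, 300, 1.49),
        "enhancers": ElementTrackConfig(250, 600, 1.45),
        "insulators": ElementTrackConfig(90, 300, 1.01),
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Defaults are the study conditions the package's tests exercise: a
    gene-dense 5 Mb genome, 500 peaks averaging 503 bp, ~47% of peaks within
    4 kb of a TSS, 47% GC, a consensus planted in 47.2% of peaks, element
    proximity folds of 1.49/1.45/1.01, and 8.4% of genes regulated at
    1.5-fold with a 52% activation share.
    """

    seed: int
    n_chroms: int = 2
    chrom_length_bp: int = 2_500_000
    n_genes: int = 100
    gene_length_mean_bp: float = 40_000.0
    gene_length_sigma: float = 0.25  # lognormal log-sd
    n_sites: int = 500
    site_width_mean_bp: float = 503.0
    site_width_sigma: float = 0.30
    site_width_range: tuple[int, int] = (149, 1107)
    tss_proximal_fraction: float = 0.40
    tss_bell_sd_bp: float = 2000.0
    gc_content: float = 0.47
    motif_plant_fraction: float = 0.472
    consensus: str = "ATCRAT"
    element_tracks: dict[str, ElementTrackConfig] = field(default_factory=_default_tracks)
    proximity_gap_bp: int = 1000
    distal_cutoff_bp: int = 4000
    regulated_fraction: float = 0.084
    plant_fold: float = 1.5
    plant_log2fc_excess_scale: float = 0.25
    activated_share: float = 0.52
    kd_only_share: float = 0.755
    oe_only_share: float = 0.173
    null_log2fc_sd: float = 0.15
    plant_p_max: float = 0.05
    distance_decay: bool = False
    distance_decay_scale_bp: float = 20_000.0
    generate_sequence: bool = True

    def __post_init__(self) -> None:
        for name in (
            "tss_proximal_fraction",
            "gc_content",
            "motif_plant_fraction",
            "regulated_fraction",
            "activated_share",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.kd_only_share + self.oe_only_share > 1.0:
            raise ValueError("kd_only_share + oe_only_share must be <= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.site_width_mean_bp <= 0 or self.gene_length_mean_bp <= 0:
            raise ValueError("width/length means must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STAGE[stage], int(self.seed)])


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _lognormal_lengths(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sigma: float,
    lo: Optional[int] = None,
    hi: Optional[int] = None,
) -> np.ndarray:
    """Lognormal integer lengths with the requested arithmetic mean.

    Out-of-range draws (if bounds given) are resampled; the truncation is a
    mild one at the defaults so the realised mean stays close to the target.
    """
    mu = math.log(mean) - sigma**2 / 2.0
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.asarray(np.round(rng.lognormal(mu, sigma, size=(n - filled) * 2)), dtype=np.int64)
        if lo is not None:
            draw = draw[draw >= lo]
        if hi is not None:
            draw = draw[draw <= hi]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, Optional[dict[str, np.ndarray]]]:
    """Generate the annotation and (optionally) i.i.d. sequences.

    Genes are placed uniformly without overlap; strands are Bernoulli(1/2).
    Sequences are i.i.d. bases with P(G)+P(C) = ``gc_content``. Raises when
    the requested genes cannot fit in their chromosome.
    """
    rng = config.rng("genes")
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chroms)
    }
    chroms = sorted(chrom_lengths)
    # spread genes across chromosomes as evenly as possible
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: list[Gene] = []
    counter = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        L = chrom_lengths[chrom]
        lengths = _lognormal_lengths(
            rng, n_here, config.gene_length_mean_bp, config.gene_length_sigma, lo=1000
        )
        total = int(lengths.sum())
        free = L - total
        if free < 0:
            raise ValueError(
                f"genes cannot fit: {total} bp of gene bodies on {chrom} of length {L}"
            )
        gaps = np.sort(rng.integers(0, free + 1, size=n_here))
        starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
        strands = rng.random(n_here) < 0.5
        for s, ln, plus in zip(starts, lengths, strands):
            counter += 1
            genes.append(
                Gene(
                    f"gene_{counter:05d}",
                    Interval(chrom, int(s), int(s + ln), "+" if plus else "-"),
                )
            )
    annotation = GenomeAnnotation(chrom_lengths, genes)
    sequences: Optional[dict[str, np.ndarray]] = None
    if config.generate_sequence:
        seq_rng = config.rng("sequence")
        gc = config.gc_content
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
        sequences = {
            chrom: seq_rng.choice(_BASES, size=chrom_lengths[chrom], p=p)
            for chrom in chroms
        }
    return annotation, sequences


def _concrete_instance(rng: np.random.Generator, pattern: MotifPattern) -> bytes:
    """One concrete sequence drawn uniformly from a pattern's allowed sets."""
    out = []
    for s in pattern.allowed:
        bases = sorted(s)
        out.append(bases[int(rng.integers(0, len(bases)))])
    return "".join(out).encode("ascii")


_RC = bytes.maketrans(b"ACGT", b"TGCA")


def simulate_peaks(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    sequences: Optional[dict[str, np.ndarray]] = None,
) -> tuple[list[BindingSite], dict[str, dict]]:
    """Generate the peak set; plant motif instances into the sequences.

    A ``tss_proximal_fraction`` of peaks is centred at truncated-normal draws
    around randomly chosen TSSs; the rest is uniform over chromosomes. A
    ``motif_plant_fraction`` of peaks receives one concrete consensus
    instance written into the sequence at a uniform position, random strand.
    Returns (peaks, manifest) where the manifest records placement mode and
    any planted motif per peak id.
    """
    rng = config.rng("peaks")
    n = config.n_sites
    if n == 0:
        return [], {}
    chroms = sorted(annotation.chrom_lengths)
    chrom_len = annotation.chrom_lengths
    lengths = np.array([chrom_len[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    all_genes = sorted(annotation.genes, key=lambda g: g.id)
    lo, hi = config.site_width_range
    widths = _lognormal_lengths(
        rng, n, config.site_width_mean_bp, config.site_width_sigma, lo=lo, hi=hi
    )
    proximal = rng.random(n) < config.tss_proximal_fraction
    if not all_genes:
        proximal[:] = False
    peaks: list[BindingSite] = []
    manifest: dict[str, dict] = {}
    for i in range(n):
        w = int(widths[i])
        mode = "tss" if proximal[i] else "uniform"
        for _ in range(100):
            if mode == "tss":
                g = all_genes[int(rng.integers(0, len(all_genes)))]
                center = g.tss + int(round(rng.normal(0.0, config.tss_bell_sd_bp)))
                start = center - w // 2
                chrom = g.interval.chrom
            else:
                chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
                start = int(rng.integers(0, chrom_len[chrom] - w + 1))
            if 0 <= start and start + w <= chrom_len[chrom]:
                break
        else:
            raise RuntimeError("peak placement: retry cap exceeded")
        pid = f"peak_{i + 1:05d}"
        peaks.append(BindingSite(Interval(chrom, start, start + w), pid))
        manifest[pid] = {"mode": mode, "motif": False, "motif_pos": None, "motif_strand": None}
    peaks.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.id))
    # motif planting
    n_plant = int(round(config.motif_plant_fraction * n))
    if n_plant > 0:
        motif_rng = config.rng("motif")
        pattern = compile_pattern(config.consensus)
        chosen = motif_rng.choice(len(peaks), size=n_plant, replace=False)
        for idx in sorted(int(j) for j in chosen):
            site = peaks[idx]
            iv = site.interval
            if iv.width < pattern.length:
                continue
            inst = _concrete_instance(motif_rng, pattern)
            strand = "+" if motif_rng.random() < 0.5 else "-"
            if strand == "-":
                inst = inst.translate(_RC)[::-1]
            pos = int(motif_rng.integers(iv.start, iv.end - pattern.length + 1))
            if sequences is not None:
                sequences[iv.chrom][pos : pos + pattern.length] = np.frombuffer(inst, dtype=np.uint8)
            manifest[site.id].update(motif=True, motif_pos=pos, motif_strand=strand)
    return peaks, manifest


def _distal_peaks(
    peaks: Sequence[BindingSite], annotation: GenomeAnnotation, cutoff: int
) -> list[BindingSite]:
    out = []
    for p in peaks:
        hit = nearest_tss(p, annotation)
        if hit is not None and abs(hit.distance) > cutoff:
            out.append(p)
    return out


def simulate_elements(
    annotation: GenomeAnnotation,
    peaks: Sequence[BindingSite],
    config: SimulationConfig,
) -> tuple[dict[str, list[Interval]], dict[str, dict]]:
    """Generate element tracks with planted proximity enrichment.

    For each track, the number of peak-targeted elements k is chosen so the
    expected fraction of distal peaks within the proximity gap equals the
    configured fold times the uniform baseline; targeted elements sit a
    uniform 0..gap bp from a randomly chosen distal peak, the rest are
    uniform over chromosomes. Infeasible folds (fold < 1, or a target
    fraction above 0.95) raise a config error.
    """
    chroms = sorted(annotation.chrom_lengths)
    chrom_len = annotation.chrom_lengths
    genome_bp = annotation.total_bp
    lengths = np.array([chrom_len[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()
    distal = _distal_peaks(peaks, annotation, config.distal_cutoff_bp)
    gap = config.proximity_gap_bp
    tracks: dict[str, list[Interval]] = {}
    info: dict[str, dict] = {}
    for t_index, name in enumerate(sorted(config.element_tracks)):
        tcfg = config.element_tracks[name]
        rng = np.random.default_rng([_STAGE["elements"], t_index, int(config.seed)])
        m, w, fold = tcfg.n_elements, tcfg.width_bp, tcfg.proximity_fold
        if m == 0:
            tracks[name] = []
            info[name] = {"n_elements": 0, "n_targeted": 0, "fold_target": fold}
            continue
        mean_peak_w = float(np.mean([p.width for p in distal])) if distal else config.site_width_mean_bp
        p1 = min(1.0, (mean_peak_w + w + 2 * gap) / genome_bp)
        b0 = 1.0 - (1.0 - p1) ** m
        target = fold * b0
        if fold < 1.0 - 1e-9 or target > 0.95:
            raise ValueError(
                f"track {name}: requested fold {fold} is infeasible at density "
                f"{m} elements (uniform baseline {b0:.3f}, target {target:.3f})"
            )
        n_distal = len(distal)
        if n_distal == 0:
            k = 0
        else:
            # each targeted element covers its own peak plus, on average,
            # (n_distal-1)*p1 other distal peaks that happen to lie in its footprint
            spill = 1.0 + (n_distal - 1) * p1
            ks = np.arange(0, min(m, n_distal) + 1)
            u = 1.0 - (1.0 - p1) ** (m - ks)
            f_k = u + np.minimum(1.0, ks * spill / n_distal) * (1.0 - u)
            k = int(ks[np.argmin(np.abs(f_k - target))])
        elements: list[Interval] = []
        if k > 0:
            target_ids = rng.choice(n_distal, size=k, replace=False)
            for j in sorted(int(x) for x in target_ids):
                peak = distal[j]
                for _ in range(100):
                    g = int(rng.integers(0, gap + 1))
                    left = rng.random() < 0.5
                    if left:
                        start = peak.interval.start - g - w
                    else:
                        start = peak.interval.end + g
                    if 0 <= start and start + w <= chrom_len[peak.interval.chrom]:
                        elements.append(Interval(peak.interval.chrom, start, start + w))
                        break
                else:
                    raise RuntimeError("element placement: retry cap exceeded")
        for _ in range(m - k):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            start = int(rng.integers(0, chrom_len[chrom] - w + 1))
            elements.append(Interval(chrom, start, start + w))
        elements.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        tracks[name] = elements
        info[name] = {"n_elements": m, "n_targeted": k, "fold_target": fold}
    return tracks, info


def simulate_expression(
    annotation: GenomeAnnotation,
    peaks: Sequence[BindingSite],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Two expression contrasts (KD, OE) with a planted regulated fraction.

    Unregulated genes draw log2fc ~ Normal(0, sd_null) and p ~ Uniform(0,1)
    in each contrast. Planted genes draw |log2fc| above log2(plant_fold) and
    p below the plant p cutoff in the contrasts they respond to; direction is
    consistent with the activated/repressed assignment (activated by the
    factor: down in KD, up in OE). Planting is independent of peak distance
    by default; ``distance_decay`` weights planting toward TSS-proximal
    genes for power studies.
    """
    rng = config.rng("expression")
    genes = sorted(g.id for g in annotation.genes)
    n = len(genes)
    n_reg = int(round(config.regulated_fraction * n))
    if config.regulated_fraction > 0 and n_reg < 1:
        warnings.warn("regulated_fraction x n_genes < 1: planting zero regulated genes")
    if config.distance_decay and n_reg > 0:
        from .tss import gene_distance_map

        dmap = gene_distance_map(list(peaks), annotation)
        cap = 10 * config.distance_decay_scale_bp
        weights = np.array(
            [math.exp(-min(abs(dmap.get(g, cap)), cap) / config.distance_decay_scale_bp) for g in genes]
        )
        weights /= weights.sum()
        chosen = rng.choice(n, size=n_reg, replace=False, p=weights)
    else:
        chosen = rng.choice(n, size=n_reg, replace=False) if n_reg > 0 else np.array([], dtype=int)
    regulated = {genes[int(i)] for i in chosen}
    manifest: dict[str, dict] = {}
    rows = []
    p_both = max(0.0, 1.0 - config.kd_only_share - config.oe_only_share)
    for gid in genes:
        is_reg = gid in regulated
        direction = None
        responds: list[str] = []
        if is_reg:
            direction = "activated" if rng.random() < config.activated_share else "repressed"
            u = rng.random()
            if u < config.kd_only_share:
                responds = ["KD"]
            elif u < config.kd_only_share + config.oe_only_share:
                responds = ["OE"]
            else:
                responds = ["KD", "OE"]
        manifest[gid] = {"regulated": is_reg, "direction": direction, "responds": responds}
        for contrast in ("KD", "OE"):
            if is_reg and contrast in responds:
                mag = math.log2(config.plant_fold) + rng.exponential(config.plant_log2fc_excess_scale)
                if direction == "activated":
                    sign = -1.0 if contrast == "KD" else 1.0
                else:
                    sign = 1.0 if contrast == "KD" else -1.0
                log2fc = sign * mag
                p = float(rng.uniform(0.0, config.plant_p_max))
            else:
                log2fc = float(rng.normal(0.0, config.null_log2fc_sd))
                p = float(rng.uniform(0.0, 1.0))
            rows.append({"gene": gid, "log2fc": log2fc, "p": p, "contrast": contrast})
    expression = pd.DataFrame(rows, columns=["gene", "log2fc", "p", "contrast"])
    return expression, manifest


@dataclass
class SyntheticDataset:
    """An in-memory synthetic dataset plus its ground-truth manifest."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    sequences: Optional[dict[str, np.ndarray]]
    peaks: list[BindingSite]
    elements: dict[str, list[Interval]]
    expression: pd.DataFrame
    manifest: dict

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Write all artifacts as plain-text files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "chroms": outdir / "chroms.tsv",
            "peaks": outdir / "peaks.bed",
            "expression": outdir / "expression.tsv",
            "manifest": outdir / "ground_truth.json",
        }
        write_gene_table(self.annotation, paths["genes"])
        write_chrom_lengths(self.annotation.chrom_lengths, paths["chroms"])
        write_bed(self.peaks, paths["peaks"])
        self.expression.to_csv(paths["expression"], sep="\t", index=False)
        for name, elements in sorted(self.elements.items()):
            paths[name] = outdir / f"{name}.bed"
            write_bed(elements, paths[name])
        if self.sequences is not None:
            from Bio import SeqIO
            from Bio.Seq import Seq
            from Bio.SeqRecord import SeqRecord

            paths["fasta"] = outdir / "genome.fa"
            records = [
                SeqRecord(Seq(self.sequences[c].tobytes().decode("ascii")), id=c, description="")
                for c in sorted(self.sequences)
            ]
            SeqIO.write(records, str(paths["fasta"]), "fasta")
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def simulate_dataset(
    config: SimulationConfig, outdir: Optional[Union[str, Path]] = None
) -> SyntheticDataset:
    """Run every generator stage and optionally write the bundle to disk."""
    annotation, sequences = simulate_genome(config)
    peaks, peak_manifest = simulate_peaks(annotation, config, sequences)
    elements, element_info = simulate_elements(annotation, peaks, config)
    expression, gene_manifest = simulate_expression(annotation, peaks, config)
    manifest = {
        "seed": int(config.seed),
        "peaks": peak_manifest,
        "genes": gene_manifest,
        "elements": element_info,
    }
    dataset = SyntheticDataset(
        config=config,
        annotation=annotation,
        sequences=sequences,
        peaks=peaks,
        elements=elements,
        expression=expression,
        manifest=manifest,
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset
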