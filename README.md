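# bindscan

Downstream analysis of transcription-factor binding-site sets from
ChIP-chip / ChAP-chip style experiments: where do called peaks sit relative
to transcription start sites, do they carry the factor's consensus motif more
often than matched random regions, do distal peaks cluster near regulatory
elements, how much of the peak set would a promoter array see, and which
putative target genes actually respond when the factor is knocked down or
overexpressed.

The package is a library first (import `bindscan`), with an `examples/`
directory of narrative scripts and a thin `bindscan` command-line wrapper for
running the stages on flat files.

## What it computes

All coordinates are 0-based half-open (BED convention); the TSS of a `+`
gene is its start, of a `-` gene its last covered base.

* **TSS distance maps** — each site is assigned to the gene minimising the
  absolute signed TSS distance (0 when the site covers the TSS, negative
  upstream, positive downstream; magnitude = coordinate gap from the TSS
  point to the nearest site edge). Counts are binned into an `overlap` bin
  plus half-open 4 kb bins per side with a `>40 kb` catch-all, and compared
  with seeded random site sets that resample the observed widths.
* **Region enrichment** — sites are split transcribed / non-transcribed by
  the midpoint rule and compared with the platform's non-transcribed base
  fraction p₀ as an odds ratio (p₁/(1−p₁))/(p₀/(1−p₀)) with a two-sided
  exact binomial p-value; distal sites (nearest TSS > 4 kb) are compared
  with random sites for proximity (gap ≤ 1 kb) to element tracks as a
  ratio-of-proportions fold with Fisher's exact p-value.
* **Consensus motif scanning** — degenerate IUPAC patterns (e.g. the 6-mer
  `ATCRAT`, reverse complement `ATYGAT`) scanned on both strands with
  palindromic double-hits deduplicated; the fraction of bound regions with a
  match is contrasted with width-matched random regions (GC reported, and an
  optional GC-matching mode), and occupancy = bound matches / all matches in
  covered space.
* **Promoter-array capture** — platform windows (`[TSS − upstream, TSS +
  downstream]`, strand-oriented, inclusive) predict the fraction of sites
  and of target genes a promoter array would detect.
* **Regulation integration** — per-contrast calls at linear fold thresholds
  (≥ f up, ≤ 1/f down; f ∈ {1.5, 1.25}) with p < 0.05, mapped to factor
  effect (down upon knockdown or up upon overexpression ⇒ activated), then
  summarised per contrast and union, by distance bin (with a chi-square
  homogeneity test), by per-gene site count, and by gene-position type
  (1 = nearest gene, 2 = nearest on the opposite side, 3 = next gene beyond
  type 1 on the same side).
* **Synthetic data** — a fully seeded generator emits an annotation, FASTA
  sequences, peaks, element tracks and two expression contrasts with a
  ground-truth manifest, so every stage above is testable without downloads
  (see `docs/methods.md` for the generative model).

## Worked example

```python
from bindscan import SimulationConfig, simulate_dataset, compile_pattern
from bindscan.core import ArrayDesign
from bindscan.motif import matched_random_fraction, motif_occupancy

ds = simulate_dataset(SimulationConfig(seed=1))
design = ArrayDesign(ds.annotation.chrom_intervals())
pattern = compile_pattern("ATCRAT")
res = matched_random_fraction(ds.peaks, design, ds.sequences, pattern, seed=1)
occ = motif_occupancy(design, ds.peaks, ds.sequences, pattern)
```

Running `python examples/04_motif_occupancy.py` prints:

```
pattern ATCRAT / reverse complement ATYGAT
  bound: 327/500 regions with consensus (65.4%), GC 46.6%
 random: 199/500 regions with consensus (39.8%), GC 47.0%
bound vs random: Fisher p = 6.1e-16
occupancy: 443/4657 consensus sites bound (9.5%)
```

65.4% of bound regions carry the consensus versus a 39.8% width-matched
random background at practically identical GC — consistent with the
generator having planted an instance in 47.2% of peaks on top of that
background — while only ~9% of all consensus matches in covered space are
bound, the usual picture that a consensus site is necessary-ish but far from
sufficient. The other examples (`examples/01…06`) walk through simulation,
distance histograms, element enrichment, array capture and regulation
integration the same way.

The same stages run from the shell:

```
bindscan all --seed 1 --outdir out/        # simulate + every report
bindscan map-tss --peaks peaks.bed --genes genes.tsv --chroms chroms.tsv --outdir out/
```

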