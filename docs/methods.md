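# Methods

This note documents the conventions, statistical models and design choices
behind `bindscan`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and distances

Everything internal is 0-based half-open; BED is native and GFF3 is
converted on read. The TSS of a `+` gene is `start`, of a `-` gene
`end − 1` (the last covered base) — the standard convention when only gene
bodies are annotated. The gap between two intervals is the number of bases
strictly between them (0 for overlap or abutment); cross-chromosome
distances are an infinite sentinel, never a large finite number, so a
nearest-TSS search can never silently jump chromosomes.

The signed TSS distance of a site is 0 when the site covers the TSS
(`start ≤ tss < end`), otherwise the coordinate gap between the TSS point
and the nearest site edge, signed negative on the gene's upstream (5′)
side. Measuring to the peak edge rather than the midpoint makes the
"overlap = 0" rule exact; peak maxima are not modelled because input peaks
carry no shape information. Nearest-TSS ties prefer overlap, then the
lexicographically smallest gene id — an arbitrary but fixed rule that makes
runs reproducible.

Distance histograms use half-open bins closed on the far side, `(0, 4k],
(4k, 8k] …` up to a per-side `>40 kb` bin, so a distance of exactly 4000 bp
falls in the first bin. Sites on chromosomes without genes are counted in a
separate `n_unassigned` field rather than silently dropped.

## Enrichment statistics

Transcribed/non-transcribed classification uses the site midpoint
(`⌊(start+end)/2⌋`): a site straddling a boundary must land in exactly one
class for the counts to partition. Enrichment against a fixed platform
composition is reported both as the odds ratio
(p₁/(1−p₁))/(p₀/(1−p₀)) and the simple ratio p₁/p₀, with a two-sided exact
binomial p-value; comparisons between two site sets (element proximity)
use the ratio of proportions as the fold and Fisher's exact test on the
2×2 near/far table. No multiple-testing correction is applied — the
reports carry a handful of tests and print raw p-values with their
denominators. Element proximity is inclusive at the 1 kb gap
(`gap ≤ 1000`).

## Motif scanning

Patterns are IUPAC consensus strings expanded to per-position allowed-base
sets; the default table is standard IUPAC (R = A/G). A documented override
(`code_overrides={"R": "AC"}` or `--r-equals-ac`) supports the non-standard
R = A/C reading that circulates for the ATCRAT motif in parts of the
literature; the standard table is the default because the motif's accepted
reverse complement ATYGAT implies R = A/G. Scanning checks both strands;
`N` in the subject matches nothing; a window matching both the forward and
reverse-complement pattern (a palindromic instance) is counted once, strand
`+`, in every summary.

Random background regions are width-paired: the same number of regions with
exactly the observed widths, placed uniformly over the array-covered space
(region chosen with probability proportional to its length, then a uniform
start that fits). GC is reported for both sets rather than enforced; an
optional accept/reject mode resamples each random region until its GC is
within a tolerance (default ±1 GC point) of its paired bound region, at a
retry cap.

## Promoter-array windows

Platform windows ship as defaults — Nimblegen −3.5 kb/+0.75 kb, Agilent
−5.5 kb/+2.5 kb, Affymetrix −7.5 kb/+2.45 kb — and are user-overridable. A
site is captured when it overlaps *any* gene's strand-oriented window, not
only its assigned gene's: a probe at a neighbouring promoter still detects
the fragment. Window bounds are inclusive at both ends after orientation.
Gene-level capture uses nearest-TSS assignment for the denominator (genes
with ≥ 1 assigned site).

## Regulation calls

Fold thresholds are symmetric in linear space (up: fold ≥ f; down:
fold ≤ 1/f) and the p cutoff is strict (< 0.05), applied to the processed
per-gene (log2 fold change, p) pairs — array normalisation and
per-gene inference are upstream of this package. Contrast statuses are
mapped to factor effect with the knockdown sign flipped: down upon
knockdown or up upon overexpression means activated by the factor. Genes
whose passing contrasts disagree are flagged `conflicting`; they count
toward "regulated" totals but toward neither direction. Genes with missing
values in every contrast are excluded and listed; a gene with one usable
contrast is called on it alone. The regulated set at 1.5-fold is a subset
of the 1.25-fold set by construction, and the test suite asserts it on
full synthetic tables.

The gene-position analysis classifies, per site, type 1 (nearest-TSS
gene), type 2 (nearest gene whose TSS lies on the opposite side of the
site midpoint) and type 3 (next gene beyond type 1 on the same side);
slots near chromosome ends may be empty and ties break by gene id. Genes
are deduplicated within a type but may appear in several types for
different sites; both conventions for the denominator were defensible and
the deduplicating one is used because it keeps each type's denominator a
set of distinct genes.

## The synthetic-data generator

The generator emulates the statistical structure of a binding-site study on
a gene-dense tiling platform, with defaults chosen once as the package's
study conditions:

* **Genome**: 2 chromosomes × 2.5 Mb; 100 genes with lognormal lengths
  (mean 40 kb, log-sd 0.25, floor 1 kb) placed uniformly without overlap
  (gaps drawn by sorting uniform offsets over the free space), strands
  Bernoulli(1/2). Gene bodies then cover ≈ 80% of the genome, mirroring the
  ~20% non-transcribed composition of gene-dense tiling arrays.
* **Sequence**: i.i.d. bases with P(G)+P(C) = 0.47. Real genomes are not
  i.i.d. (CpG depletion, isochores, repeats), so absolute background motif
  rates here are higher than on real DNA; all motif analyses therefore
  compare bound regions against matched random regions from the *same*
  sequence model, which is the quantity the estimators consume.
* **Peaks**: 500 sites, lognormal widths with mean 503 bp truncated to
  [149, 1107] bp (the truncation bounds are the observed width range such
  peak sets report; the lognormal itself is a stand-in since only the mean
  and range are known). A fraction 0.40 of peaks is centred at
  Normal(TSS, 2 kb) draws around randomly chosen TSSs — together with the
  uniform remainder this puts ≈ 47% of peaks within 4 kb of a TSS — and
  placements that leave the chromosome are resampled with a retry cap, so
  widths stay honest.
* **Motif planting**: 47.2% of peaks receive one concrete instance of the
  consensus (allowed sets sampled uniformly, strand random) written into
  the sequence at a uniform position inside the peak; the manifest records
  position and strand per peak.
* **Element tracks**: `dhs` (250 × 300 bp, fold 1.49), `enhancers`
  (250 × 600 bp, fold 1.45), `insulators` (90 × 300 bp, fold 1.01). For a
  target fold F the generator solves for the number k of elements placed a
  uniform 0–1 kb from distinct random distal peaks, using the expected
  near-fraction model f(k) = u(k) + min(1, k·c/n_distal)(1 − u(k)) with
  u(k) = 1 − (1 − p₁)^(m−k) the uniform-part coverage, p₁ the single-element
  footprint probability, and c = 1 + (n_distal − 1)p₁ a spillover factor
  (a targeted element can sit near other distal peaks too); the remaining
  m − k elements are uniform. Folds below 1 or targets above 0.95 raise a
  config error as infeasible. Over 20 seeds the measured folds land within
  a few percent of the targets.
* **Expression**: two contrasts (KD, OE) per gene. Unregulated genes draw
  log2fc ~ Normal(0, 0.15) and p ~ Uniform(0,1) — at the 1.5-fold cutoff
  the null crossing rate is ~10⁻⁵ per contrast, so the planted fraction is
  recovered almost exactly. A fraction 0.084 of genes is planted regulated
  (|log2fc| = log2(1.5) + Exponential(0.25), p ~ Uniform(0, 0.05)), with a
  0.52 activation share and a KD/OE response mix of 0.755/0.173/0.072
  (KD-only / OE-only / both) so knockdown finds more responders than
  overexpression, as perturbation studies typically do. Planting is
  distance-independent by default — the flat regulation-versus-distance
  profile is the null the chi-square homogeneity test should not reject —
  with an optional exponential distance-decay mode (scale 20 kb) for power
  studies.
* **Determinism**: each stage draws from `default_rng([stage_id, seed])`,
  so all artifacts are byte-identical across runs with the same config and
  adding a stage never perturbs earlier outputs. Expression planting at
  4000 genes plants exactly `round(0.084·n)` genes, which is why the
  recovered fraction is nearly noise-free at that scale.

What passing tests on this generator do **not** show: robustness to
non-i.i.d. sequence composition, peak-width/GC confounding, probe-level
array artefacts, or read-level noise — none of which the generator models.

## Problem sizes and numerics

The default end-to-end run (5 Mb genome, 500 peaks, 100 genes) completes in
about a second; expression-scale analyses in the tests use 4000 genes and
5000 peaks on a 200 Mb coordinate space without sequences. Parameter-
recovery checks pool 3 seeds (motif fraction, delta-method CI) or 20 seeds
(element folds, regulated fraction, chi-square non-rejection rate ≥ 18/20).
Degenerate inputs are flagged rather than silently defaulted: empty site
lists, zero-hit occupancy, empty distance bins and empty position types all
surface as errors or NaN-with-denominator in the reports, and every
percentage in a report is printed next to its denominator.

## Known limitations

* Nearest-TSS assignment uses annotated gene bodies only; alternative TSSs
  and unannotated transcripts are out of scope.
* The odds-ratio enrichment treats the platform composition as a fixed
  known constant, not an estimate with error.
* The consensus scanner is exact-match over allowed sets; no PWM scoring,
  no mismatch tolerance, and no de novo discovery.
* Random region sampling is uniform over covered space; it does not model
  probe-level accessibility or mappability biases.
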