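"""Enrichment of peaks in non-transcribed space and near regulatory elements.

First the transcribed/non-transcribed split of the peak set is compared with
the platform's base composition as an odds ratio with an exact binomial
p-value. Then the distal peaks (nearest TSS > 4 kb away) are compared with a
width-matched random set for proximity (within 1 kb) to each element track
with a ratio-of-proportions fold and Fisher's exact p-value.
"""
from bindscan import SimulationConfig, simulate_dataset
from bindscan.core import ArrayDesign
from bindscan.enrichment import classify_transcribed, odds_enrichment, proximity_fold
from bindscan.tss import nearest_tss, random_site_set

ds = simulate_dataset(SimulationConfig(seed=1, generate_sequence=False))
design = ArrayDesign(ds.annotation.chrom_intervals())

n_in, n_out = classify_transcribed(ds.peaks, ds.annotation)
bg_non = 1.0 - design.transcribed_fraction(ds.annotation)
res = odds_enrichment(n_out, n_in, bg_non)
print(f"non-transcribed: {n_out}/{n_in + n_out} sites "
      f"({100 * res.observed_fraction:.1f}% vs {100 * bg_non:.1f}% background)")
print(f"odds ratio {res.odds_ratio:.2f}, fold {res.fold:.2f}, p = {res.p_value:.2g}\n")

distal = [p for p in ds.peaks if abs(nearest_tss(p, ds.annotation).distance) > 4000]
rand = random_site_set(ds.annotation, len(distal), widths=[p.width for p in distal], seed=1)
print(f"{'track':>11} {'peaks %':>8} {'random %':>9} {'fold':>6} {'p':>9}")
for name, elements in sorted(ds.elements.items()):
    r = proximity_fold(distal, rand, elements)
    print(f"{name:>11} {100 * r.observed_fraction:>7.1f} "
          f"{100 * r.background_fraction:>8.1f} {r.fold:>6.2f} {r.p_value:>9.3g}")
# Folds near the planted 1.49/1.45/1.01 indicate open-chromatin and enhancer
# proximity enrichment with no insulator signal.
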