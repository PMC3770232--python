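"""Integrate binding with knockdown/overexpression expression contrasts.

Genes are called up/down per contrast at a linear fold threshold with
p < 0.05, mapped to factor effect (down upon knockdown or up upon
overexpression = activated by the factor), and summarised overall, by
distance of the nearest site, and by per-gene site count.
"""
from bindscan import RegulationThresholds, SimulationConfig, call_genes, simulate_dataset
from bindscan.regulation import (
    regulated_by_distance_bin,
    regulated_by_site_count,
    regulated_fraction,
)
from bindscan.tss import gene_distance_map, gene_site_counts

ds = simulate_dataset(SimulationConfig(
    seed=1, n_chroms=4, chrom_length_bp=50_000_000, n_genes=4000, n_sites=5000,
    generate_sequence=False,
))

calls_15, _ = call_genes(ds.expression, RegulationThresholds(1.5, 0.05))
calls_125, _ = call_genes(ds.expression, RegulationThresholds(1.25, 0.05))
targets = sorted(gene_site_counts(ds.peaks, ds.annotation))

summary = regulated_fraction(targets, calls_15)
print("1.5-fold, p < 0.05 (targets with profiling data):")
print(summary[["n_genes", "regulated", "activated", "repressed", "fraction_regulated"]])

dmap = {g: d for g, d in gene_distance_map(ds.peaks, ds.annotation).items()
        if g in calls_15.index}
table, stat, p = regulated_by_distance_bin(dmap, calls_15)
print(f"\nregulated fraction vs distance: chi-square = {stat:.1f}, p = {p:.3f}")
print("(planting is distance-independent, so homogeneity is not rejected)")

counts = gene_site_counts(ds.peaks, ds.annotation)
by_count = regulated_by_site_count(counts, {"1.5": calls_15, "1.25": calls_125})
print("\nby number of sites per gene:")
print(by_count[["n_targets", "n_regulated_1.5", "fraction_1.5", "fraction_1.25"]])
# The overall regulated fraction tracks the planted 8.4% at 1.5-fold, and the
# per-bin fractions are statistically flat across distance.
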