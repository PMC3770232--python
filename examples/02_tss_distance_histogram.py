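"""Map peaks to their nearest TSS and print the signed-distance histogram.

Sites covering a TSS land in the "overlap" bin; the rest fall in half-open
4 kb bins on the upstream (negative) or downstream (positive) side, with a
catch-all beyond 40 kb. A width-matched random site set shows the flat
profile expected without promoter preference.
"""
from bindscan import SimulationConfig, distance_histogram, random_site_set, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=1, generate_sequence=False))

observed = distance_histogram(ds.peaks, ds.annotation)
random_sites = random_site_set(
    ds.annotation, len(ds.peaks), widths=[p.width for p in ds.peaks], seed=1
)
null = distance_histogram(random_sites, ds.annotation)

obs_pct, null_pct = observed.percentages(), null.percentages()
print(f"{'bin':>22} {'observed %':>11} {'random %':>9}")
for label in observed.labels:
    print(f"{label:>22} {obs_pct[label]:>10.1f} {null_pct[label]:>9.1f}")

near = obs_pct["overlap"] + obs_pct["upstream (0,4k]"] + obs_pct["downstream (0,4k]"]
print(f"\nwithin 4 kb of a TSS: {near:.1f}% of peaks (random sets stay flat)")
# The observed profile shows the planted TSS-centred bell; the random set
# reflects plain genome geometry.
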