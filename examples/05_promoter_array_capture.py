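"""Predict how much of a binding-site set a promoter array would capture.

Each platform tiles a strand-oriented window around every TSS. A site is
captured when it overlaps any gene's window; a target gene is captured when
at least one of its assigned sites is. Gene capture always exceeds site
capture because distal sites often co-occur with a proximal one.
"""
from bindscan import PLATFORM_WINDOWS, SimulationConfig, capture_fractions, simulate_dataset
from bindscan.coverage import target_overlap

ds = simulate_dataset(SimulationConfig(seed=1, generate_sequence=False))

print(f"{'platform':>11} {'window':>22} {'sites %':>8} {'genes %':>8}")
for name, window in PLATFORM_WINDOWS.items():
    res = capture_fractions(ds.peaks, ds.annotation, window)
    span = f"-{window.upstream_bp / 1000:g} kb / +{window.downstream_bp / 1000:g} kb"
    print(f"{name:>11} {span:>22} {100 * res.site_fraction:>7.1f} "
          f"{100 * res.gene_fraction:>7.1f}")

# cross-list overlap: what fraction of one target list appears in another
list_a = [g.id for g in ds.annotation.genes[:85]]
list_b = [g.id for g in ds.annotation.genes[58:]]
ov = target_overlap(list_a, list_b)
print(f"\nlist overlap: {ov.n_intersection}/{ov.n_a} "
      f"({100 * ov.fraction:.0f}%) of list A found in list B")
# Wider windows capture monotonically more sites and genes.
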