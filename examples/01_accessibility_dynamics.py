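"""Classify temporal accessibility and measure region sharing.

Simulates a 6-point ATAC time course for both transition directions
(serum->ground-state and back), unifies peaks into consensus loci, labels
each locus PO / CO_k / OC_k / EXCLUDED, builds Regions 1-4 and prints the
Venn-style sharing between the serum-specific regions. Percentages are the
fraction of the first region's peaks touching the second region.
"""

from chromdyn.dynamics import (
    build_consensus,
    classify_dynamics,
    define_regions,
    region_overlap_stats,
)
from chromdyn.simulate import SimConfig, simulate_timecourse_peaks

cfg = SimConfig(seed=1, n_peaks=2_000)
fwd = simulate_timecourse_peaks(cfg, "fwd")  # serum -> ground state
rev = simulate_timecourse_peaks(cfg, "rev")  # ground state -> serum

cons_f = build_consensus(fwd.peak_sets)
labels_f, counts_f = classify_dynamics(cons_f)
cons_r = build_consensus(rev.peak_sets)
labels_r, counts_r = classify_dynamics(cons_r)

print("forward-direction class counts (PO = stable open, COk/OCk = switch at k):")
for cls, n in sorted(counts_f.items()):
    print(f"  {cls:>8}: {n}")

regions = define_regions(cons_f, labels_f, cons_r, labels_r)
print("\nregion sizes:", {r: len(a) for r, a in regions.items()})

stats = region_overlap_stats(regions[1], regions[4])
print(
    f"\nRegion 1 shares {stats['percent']}% "
    f"({stats['n_a_overlapping_b']}/{stats['n_a']}) of its peaks with Region 4"
)
print("(both regions hold serum-specific chromatin, so sharing indicates the")
print(" same loci opening and closing reciprocally in the two directions)")
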