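"""DE-based gene specificity and five-pattern knockout clustering.

Simulates a DE table (ground-state vs serum) plus WT/KO expression
trajectories over days 0/3/6 drawn from the five canonical response
patterns, then recovers specific genes and the C1-C5 clusters.
"""

from sklearn.metrics import adjusted_rand_score

from chromdyn.expression import cluster_time_profiles, define_specific_genes
from chromdyn.simulate import SimConfig, simulate_expression

sim = simulate_expression(SimConfig(seed=3, n_genes=1_000))

spec = define_specific_genes(sim.de_table, q_max=0.05, fc_min=2.0)
print(f"2i-specific genes (up in ground state): {len(spec['two_i_specific'])}")
print(f"serum-specific genes (down):            {len(spec['serum_specific'])}")

res = cluster_time_profiles(sim.profiles, k=5, seed=3)
sizes = res.assignments["cluster"].value_counts().sort_index()
print("\ncluster sizes (C1 unchanged, C2 lower at serum baseline, C3 aberrantly")
print("high in KO, C4 rises in both, C5 rises only in WT):")
for name, n in sizes.items():
    print(f"  {name}: {n}")

ari = adjusted_rand_score(sim.truth.true_cluster, res.assignments.cluster)
print(f"\nadjusted Rand index vs planted labels: {ari:.3f}")
print("(1.0 would be perfect recovery; NB noise at the default dispersion")
print(" leaves a few boundary genes in neighbouring clusters)")
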