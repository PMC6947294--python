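"""Structural-evolutionary statistics of an age-annotated gene network.

Plants positive age assortativity (edge weight ~ exp(-beta * |dPAI|)) and
recovers it: scalar assortativity with jack-knife error, degree-age
correlation, and the |dPAI| distribution by shortest-path distance.
"""

import numpy as np

from phylostress import age_assortativity, degree_age_correlation, dpai_by_distance
from phylostress.network_analysis import greedy_modularity_clusters, cluster_quality
from phylostress.synthetic_data import SimulationConfig, simulate_network

rng = np.random.default_rng(0)
ages = {f"g{i:03d}": int(rng.integers(0, 15)) for i in range(120)}
config = SimulationConfig(seed=5, n_edges=200, assortativity_strength=0.8)
net = simulate_network(config, ages)

print(f"network: {net.n_nodes} nodes, {net.n_edges} edges "
      f"(mean degree {net.mean_degree():.2f})")

ar = age_assortativity(net)
print(f"age assortativity r_a = {ar.r_a:.3f} +/- {ar.sigma:.3f} "
      f"(Np = {ar.n_pairs} interacting pairs)")
corr = degree_age_correlation(net)
print(f"degree-age Pearson r = {corr.r:.3f} (p = {corr.p_value:.3f})")

print("\n|dPAI| by shortest-path distance (fractions):")
for bucket, counter in dpai_by_distance(net).items():
    total = sum(counter.values())
    same = counter.get(0, 0) / total if total else float("nan")
    print(f"  distance {bucket}: {total:5d} pairs, "
          f"{100 * same:.1f}% with identical age")

net.clusters = greedy_modularity_clusters(net)
print("\ncluster quality (deg_int > k_net marks a well-formed module):")
for lab in sorted(set(net.clusters.values()))[:4]:
    q = cluster_quality(net, lab)
    print(f"  {lab}: deg_int = {q.deg_int:.2f}, deg_ext = {q.deg_ext:.2f}, "
          f"k_net = {q.k_net:.2f}")
print("\ndirectly interacting genes share their age far more often than")
print("distant ones - the planted assortative structure.")
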