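"""Small-world topology of a group-mean connectivity graph.

Averages Fisher-z matrices over the control-like group, thresholds to
a binary graph, and compares its clustering and path length against
100 degree-preserving Maslov-Sneppen rewirings: gamma = C/C_rand,
lambda = L/L_rand, sigma = gamma/lambda (> 1 means small-world).
"""

import restgraph as rg
from restgraph.connectivity import ThresholdSpec

labels = tuple(rg.load_region_table()["abbreviation"])
cohort = rg.simulate_cohort(rg.CohortConfig(seed=1))

mats = [
    rg.correlation_matrix(rg.preprocess_subject(s), labels=labels)
    for s in cohort.subjects
    if s.group == "a"
]
mean = rg.group_mean_zmatrix(mats, tag="controls")
# 0.18 sits inside this cohort's small-world regime (see regime_sweep.py)
graph = rg.binarize(mean, ThresholdSpec("z_value", 0.18))
met = rg.network_metrics(graph)
print(f"group graph at |z| > 0.18: K = {met.K:.1f}, C_net = {met.C_net:.3f}, "
      f"L_net = {met.L_net:.3f}, E_glob = {met.E_glob:.3f}, E_loc = {met.E_loc:.3f}")

hubs = rg.hubs(graph)
print(f"hubs (degree > mean): {hubs.size} regions, e.g. "
      + ", ".join(labels[i] for i in hubs[:6]))

ens = rg.null_ensemble(graph, n_random=100, seed=9,
                       measures=("clustering", "paths"))
idx = rg.small_world_indices(met, ens)
c_th, l_th = rg.theoretical_random(met.K, 90)
print(f"rewired nulls: C_rand = {ens.mean_C_rand:.3f}, L_rand = {ens.mean_L_rand:.3f}")
print(f"theoretical ER values for comparison: C = {c_th:.3f}, L = {l_th:.3f}")
print(f"gamma = {idx.gamma:.2f}, lambda = {idx.lam:.2f}, sigma = {idx.sigma:.2f}")
print("\nsigma well above 1: clustering far exceeds degree-matched random")
print("graphs while path lengths stay comparable - the small-world signature.")
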