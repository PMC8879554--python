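"""PPI network induction, edge enrichment and Markov clustering.

Plants three dense modules inside a sparse 60-node background interactome,
induces the subnetwork on the module members, tests whether they are more
interconnected than random node sets, and clusters with MCL (inflation 1.4).
"""

from mitonet import (
    NetworkSimConfig,
    simulate_interactome,
    induce_network,
    ppi_enrichment,
    mcl,
    modularity,
)

config = NetworkSimConfig(
    n_clusters=4,
    cluster_sizes=(8, 8, 6, 38),          # 3 modules + sparse background
    p_within=(0.7, 0.7, 0.7, 0.02),
    p_between=0.02,
    seed=5,
)
background, labels = simulate_interactome(config)
members = [n for n, lab in labels.items() if lab < 3]

network, missing = induce_network(background, members)
enr = ppi_enrichment(background, members, n_permutations=1000, seed=0)
partition = mcl(network)

print(f"induced network: {network.n_nodes} nodes, {network.n_edges} edges")
print(
    f"PPI enrichment: observed {enr.observed_edges} internal edges vs "
    f"{enr.null_mean:.1f} expected at random -> p = {enr.p_value:.4g}"
)
print(f"MCL clusters (sizes): {partition.sizes()}")
print(f"modularity of the MCL partition: {modularity(network, partition):.3f}")
print()
print(
    "A tiny p-value says the planted proteins interact far more than chance;\n"
    "MCL should recover the three planted modules as its three clusters."
)
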