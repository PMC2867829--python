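"""Finding a co-regulated module with the k-core of a correlation network.

Plants a 20-gene module sharing a latent factor (loading 0.98) among 300
null genes, thresholds the pairwise Pearson matrix at |r| >= 0.9, and reads
the module back off the innermost k-cores.
"""

import hepacore as h
from hepacore.synthetic import SyntheticSpec

matrix, _ = h.generate_null_matrix(SyntheticSpec(n_genes=300, seed=3))
module_ids = sorted(matrix.gene_ids[:20])
matrix, truth = h.plant_correlated_module(
    matrix, n_genes=20, loading=0.98, seed=4, gene_ids=module_ids
)

r = h.correlation_matrix(matrix)
graph = h.build_graph(r, threshold=0.9, rule="absolute")
topology = h.node_topology(graph)
core_genes = h.select_core_genes(topology, depth=2)

print(f"graph: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")
print(f"max core {topology['core'].max()}, "
      f"{len(core_genes)} genes within 2 core levels of it")
recovered = len(set(core_genes) & set(module_ids))
print(f"{recovered}/20 module genes in the selected cores")
print(topology.head(5).to_string(index=False))
# Null gene pairs clear |r| >= 0.9 with probability ~7e-5 at n=12 samples,
# so background nodes stay at core 0-1 while the factor-driven module forms
# the dense innermost core -- the same logic that singles out hub genes in
# a real profile-selected network.
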