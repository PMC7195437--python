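"""Co-expression network centrality, top-percentile hubs, enrichment,
disease networks and effect-direction concordance.
"""

import numpy as np
import pandas as pd

from lifemr import centrality, concordance, disease_network, hypergeom_enrichment, top_percentile
from lifemr.simulate import sim_gene_disease, sim_network

g = sim_network(1000, 1600, model="preferential", seed=9)
cent = centrality(g).set_index("node")
hubs = top_percentile(cent["betweenness"], q=0.99)
print(f"network: {g.number_of_nodes()} nodes / {g.number_of_edges()} edges; "
      f"{len(hubs)} nodes above the 99th betweenness percentile")

universe = [f"g{i}" for i in range(500)]
causal = universe[:16]
bottlenecks = universe[:10] + universe[100:135]
res = hypergeom_enrichment(causal, bottlenecks, universe)
print(f"enrichment of causal genes among bottlenecks: k={res.k}/{res.n}, "
      f"fold={res.fold:.1f}, p={res.p:.2e}")

pairs = sim_gene_disease([f"g{i}" for i in range(30)], [f"D{j}" for j in range(8)],
                         density=0.2, seed=4)
dg = disease_network(pairs)
print(f"disease network: {dg.number_of_nodes()} diseases, {dg.number_of_edges()} "
      f"edges (weight = shared genes)")

calls = pd.DataFrame({
    "gene": ["PTPN22_like", "OTHER"],
    "disorder": ["autoimmune", "cvd"],
    "theta_disorder": [0.3, -0.2],
    "p_disorder": [1e-5, 0.2],
    "theta_lifespan": [-0.4, -0.3],
})
table, summary = concordance(calls)
print(table[["gene", "tier", "label"]].to_string(index=False))
print("concordant fraction per tier:", {k: round(v, 2) for k, v in summary.items()})
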