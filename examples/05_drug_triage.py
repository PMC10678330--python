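"""Filter drug-gene interactions and triage repurposing candidates.

Interactions are kept for approved drugs targeting key genes with >= 2
non-cancer database sources and >= 1 publication; weight-effect classes are
tallied per distinct drug; drugs with at most 10 very-common side effects
targeting a knockout-supported gene are flagged for repurposing.
"""

from postgwas import (
    SyntheticScenario,
    classify_weight_effects,
    filter_drug_interactions,
    flag_repurposing_candidates,
    generate_study,
    run_workflow,
    summarize_side_effects,
)

study = generate_study(SyntheticScenario(seed=1))
res = run_workflow(study, top_k=50, with_enrichment=False, with_validation=False)

filtered = filter_drug_interactions(study.knowledge.drug_gene, set(res.key_genes))
summary = classify_weight_effects(filtered)
se = summarize_side_effects(set(filtered["drug"]), study.knowledge.side_effects)
calls = flag_repurposing_candidates(filtered, se, study.knowledge.knockouts)

print(f"interactions kept: {len(filtered)}")
print(f"distinct drugs: {summary.n_drugs} over {summary.n_genes} key genes")
print(f"weight effects: {summary.counts}")
print(f"drugs flagged for repurposing: {int(calls['flagged'].sum())}")
print(calls.sort_values('very_common_effect_count').head(5).to_string(index=False))
# Flagged drugs combine a low very-common side-effect burden with at least
# one target gene showing an obesity-related mouse-knockout abnormality.
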