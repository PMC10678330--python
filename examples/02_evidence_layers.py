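"""Apply the three evidence filters and merge the prioritized gene lists.

eQTL-tier SNPs (regulatory categories 1a-1f) among the associated SNP list
are mapped to their target genes; brain-tissue upregulated genes pass at
adjusted p < 0.05; TWAS genes need an obesity phenotype hit in a brain
tissue.  The union with overlap accounting is the prioritized gene set.
"""

from postgwas import (
    SyntheticScenario,
    assemble_snp_list,
    expand_ld_snps,
    filter_regulatory_snps,
    generate_study,
    map_eqtl_genes,
    merge_evidence_sets,
    prioritize_tissue_degs,
    select_significant_snps,
    select_twas_genes,
)

study = generate_study(SyntheticScenario(seed=1))
sig = select_significant_snps(study.gwas)
snps = assemble_snp_list(sig, expand_ld_snps(sig, study.panel), study.panel, study.gwas)

eqtl_snps = filter_regulatory_snps(study.evidence.regulatory, snps)
eqtl_genes = map_eqtl_genes(eqtl_snps, study.evidence.eqtl_links)
deg_genes = prioritize_tissue_degs(study.evidence.tissue_deg)
twas_genes = select_twas_genes(study.evidence.twas)
sets = merge_evidence_sets(eqtl_genes, deg_genes, twas_genes)

print(f"eQTL-SNPs (category 1a-1f in SNP list): {len(eqtl_snps)}")
for name, value in sets.counts.items():
    print(f"  {name:>9}: {value}")
truth = study.truth
print(
    "true-gene share of union: "
    f"{len(sets.union & truth.true_genes) / len(sets.union):.2f} "
    f"(background {len(truth.true_genes) / study.scenario.n_genes:.2f})"
)
# The union obeys inclusion-exclusion exactly, and the planted true genes
# are several-fold over-represented relative to their background share.
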