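"""In-memory orchestration of the workflow over a synthetic study.

The file-based pipeline (:mod:`postgwas.pipeline`) is the production path;
this module chains the same stage functions directly over in-memory tables,
which is what simulation studies (many seeds, many replicates), the
examples and the acceptance script want.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import drugs as drugs_mod
from . import gwas_ld
from .enrichment import EnrichmentRecord, run_enrichment
from .evidence import (
    EvidenceGeneSets,
    filter_regulatory_snps,
    map_eqtl_genes,
    merge_evidence_sets,
    prioritize_tissue_degs,
    select_twas_genes,
)
from .exceptions import DegenerateTestError, SamplingError
from .network import KeyGeneResult, build_ppi_graph, compute_centralities, select_key_genes
from .synthio import SyntheticStudy
from .validation import (
    NegativeControlContext,
    ValidationConfig,
    ValidationReport,
    build_validation_report,
    run_negative_control,
)

__all__ = ["WorkflowResult", "run_workflow"]


@dataclass
class WorkflowResult:
    significant: pd.DataFrame
    expansion: pd.DataFrame
    snp_list: pd.DataFrame
    loci: list
    evidence_sets: EvidenceGeneSets
    centralities: pd.DataFrame
    key_result: KeyGeneResult
    enrichment: list[EnrichmentRecord] = field(default_factory=list)
    drug_filtered: pd.DataFrame | None = None
    drug_summary: object | None = None
    side_effect_counts: pd.DataFrame | None = None
    repurposing: pd.DataFrame | None = None
    validation_reports: list[ValidationReport] = field(default_factory=list)
    validation_skipped: list[dict] = field(default_factory=list)

    @property
    def key_genes(self) -> frozenset[str]:
        return self.key_result.key_genes


def run_workflow(
    study: SyntheticStudy,
    *,
    p_sig: float = 1e-8,
    window_bp: int = 500_000,
    r2_min: float = 0.9,
    locus_gap_bp: int = 500_000,
    deg_alpha: float = 0.05,
    score_min: float = 0.4,
    top_k: int = 100,
    enrich_alpha: float = 0.05,
    min_overlap: int = 4,
    min_sources: int = 2,
    min_pmids: int = 1,
    max_effects: int = 10,
    n_trials: int = 10,
    low_degree_max: int = 1,
    test_method: str = "one-sample",
    validation_schemes: tuple[str, ...] = (
        "stage1_random",
        "stage2_random",
        "stage2_low_degree",
    ),
    with_enrichment: bool = True,
    with_drugs: bool = True,
    with_validation: bool = True,
) -> WorkflowResult:
    """Run the staged workflow over an in-memory synthetic study."""
    significant = gwas_ld.select_significant_snps(study.gwas, p_sig)
    expansion = gwas_ld.expand_ld_snps(significant, study.panel, window_bp, r2_min)
    snp_list = gwas_ld.assemble_snp_list(significant, expansion, study.panel, study.gwas)
    loci = gwas_ld.cluster_loci(snp_list, locus_gap_bp)

    ev = study.evidence
    eqtl_snps = filter_regulatory_snps(ev.regulatory, snp_list)
    sets = merge_evidence_sets(
        map_eqtl_genes(eqtl_snps, ev.eqtl_links),
        prioritize_tissue_degs(ev.tissue_deg, alpha=deg_alpha),
        select_twas_genes(ev.twas),
    )

    edge_table = study.ppi.edge_table()
    net = build_ppi_graph(edge_table, set(sets.union), score_min)
    centralities = compute_centralities(net)
    key_result = select_key_genes(centralities, top_k)
    result = WorkflowResult(
        significant=significant,
        expansion=expansion,
        snp_list=snp_list,
        loci=loci,
        evidence_sets=sets,
        centralities=centralities,
        key_result=key_result,
    )
    key_genes = set(key_result.key_genes)

    if with_enrichment and key_genes:
        result.enrichment = run_enrichment(
            key_genes, study.knowledge.gene_sets, enrich_alpha, min_overlap
        )

    if with_drugs and key_genes:
        filtered = drugs_mod.filter_drug_interactions(
            study.knowledge.drug_gene, key_genes, min_sources, min_pmids
        )
        result.drug_filtered = filtered
        result.drug_summary = drugs_mod.classify_weight_effects(filtered)
        result.side_effect_counts = drugs_mod.summarize_side_effects(
            set(filtered["drug"]), study.knowledge.side_effects
        )
        result.repurposing = drugs_mod.flag_repurposing_candidates(
            filtered, result.side_effect_counts, study.knowledge.knockouts, max_effects
        )

    if with_validation and key_genes:
        ko = study.knowledge.knockouts
        references = {
            "knockout": frozenset(ko.loc[ko["obesity_phenotype"], "gene"].astype(str)),
            "drug": frozenset(study.knowledge.drug_gene["gene"].astype(str)),
        }
        ctx = NegativeControlContext(
            universe=frozenset(study.knowledge.gene_sets.effective_universe()),
            prioritized=frozenset(sets.union),
            ppi_edges=edge_table,
            references=references,
            score_min=score_min,
            top_k=top_k,
        )
        vcfg = ValidationConfig(
            n_trials=n_trials,
            universe_size=len(ctx.universe),
            stage1_sample_size=min(len(sets.union), len(ctx.universe)),
            stage2_sample_size=len(key_genes),
            low_degree_max=low_degree_max,
            seed=study.scenario.seed,
        )
        for scheme in validation_schemes:
            try:
                trials = run_negative_control(scheme, vcfg, ctx)
            except SamplingError as exc:
                result.validation_skipped.append({"scheme": scheme, "reason": str(exc)})
                continue
            for ref_name, ref in references.items():
                try:
                    result.validation_reports.append(
                        build_validation_report(
                            scheme, ref_name, key_genes, set(ref),
                            trials.rates[ref_name], method=test_method,
                        )
                    )
                except DegenerateTestError as exc:
                    result.validation_skipped.append(
                        {"scheme": scheme, "reference": ref_name, "reason": str(exc)}
                    )
    return result
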