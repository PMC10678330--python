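"""End-to-end pipeline runner.

Stages run in the workflow order — GWAS/LD, evidence, network, enrichment,
drugs, validation — each persisting its outputs to the configured output
directory before the next stage starts, so individual stages can also be
re-run from disk.  A run manifest (config hash, input checksums, per-stage
row counts) is written at the end; re-running with identical inputs and
config reproduces the stage counts exactly.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import drugs as drugs_mod
from . import gwas_ld, io
from .config import INPUT_FILES, PipelineConfig
from .evidence import (
    filter_regulatory_snps,
    map_eqtl_genes,
    merge_evidence_sets,
    prioritize_tissue_degs,
    select_twas_genes,
)
from .exceptions import DegenerateTestError, PostGwasError, SamplingError, StageError
from .network import build_ppi_graph, compute_centralities, select_key_genes
from .validation import (
    NegativeControlContext,
    ValidationConfig,
    build_validation_report,
    run_negative_control,
)

__all__ = ["run_pipeline", "run_stage", "RunManifest", "STAGES", "write_simulated_inputs"]

logger = logging.getLogger(__name__)

STAGES = ("gwas_ld", "evidence", "network", "enrichment", "drugs", "validation")


@dataclass
class RunManifest:
    config_hash: str
    input_checksums: dict[str, str]
    stage_counts: dict[str, dict[str, int]]
    version: str = __version__
    started: float = 0.0
    finished: float = 0.0

    def completed_stages(self) -> list[str]:
        return [s for s in STAGES if s in self.stage_counts]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_simulated_inputs(study, out_dir: str | Path) -> Path:
    """Persist every table of a synthetic study under the standard names."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_table(study.gwas, out / INPUT_FILES["summary"])
    io.write_vcf(study.panel, out / INPUT_FILES["panel"])
    io.write_table(study.evidence.regulatory, out / INPUT_FILES["regulatory"])
    io.write_table(study.evidence.eqtl_links, out / INPUT_FILES["eqtl_links"])
    io.write_table(study.evidence.tissue_deg, out / INPUT_FILES["tissue_deg"])
    io.write_table(study.evidence.twas, out / INPUT_FILES["twas"])
    io.write_table(study.ppi.edge_table(), out / INPUT_FILES["ppi_edges"])
    io.write_gmt(study.knowledge.gene_sets, out / INPUT_FILES["gene_sets"])
    drug = study.knowledge.drug_gene.copy()
    io.write_table(drug, out / INPUT_FILES["drug_gene"])
    io.write_table(study.knowledge.side_effects, out / INPUT_FILES["side_effects"])
    io.write_table(study.knowledge.knockouts, out / INPUT_FILES["knockouts"])
    io.write_truth(study.truth, out / INPUT_FILES["truth"])
    return out


class _Runner:
    """Stage implementations reading prerequisites from disk."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)

    # -- stage 1 -----------------------------------------------------------
    def stage_gwas_ld(self) -> dict[str, int]:
        cfg = self.cfg
        summary = io.read_table(cfg.input_path("summary"), "summary")
        panel = io.read_vcf(cfg.input_path("panel"))
        significant = gwas_ld.select_significant_snps(summary, cfg.p_sig)
        expansion = gwas_ld.expand_ld_snps(significant, panel, cfg.window_bp, cfg.r2_min)
        snp_list = gwas_ld.assemble_snp_list(significant, expansion, panel, summary)
        loci = gwas_ld.cluster_loci(snp_list, cfg.locus_gap_bp)
        io.write_table(significant, self.out / "significant_snps.tsv")
        io.write_table(expansion, self.out / "ld_expansion.tsv")
        io.write_table(snp_list, self.out / "snp_list.tsv")
        io.write_loci(loci, self.out / "loci.tsv", self.out / "loci.bed")
        return {
            "significant_snps": len(significant),
            "ld_pairs": len(expansion),
            "snp_list": len(snp_list),
            "loci": len(loci),
        }

    # -- stage 2 -----------------------------------------------------------
    def stage_evidence(self) -> dict[str, int]:
        cfg = self.cfg
        snp_list = io.read_table(self.out / "snp_list.tsv", "snp_list")
        regulatory = io.read_table(cfg.input_path("regulatory"), "regulatory")
        links = io.read_table(cfg.input_path("eqtl_links"), "eqtl_links")
        deg = io.read_table(cfg.input_path("tissue_deg"), "tissue_deg")
        twas = io.read_table(cfg.input_path("twas"), "twas")

        eqtl_snps = filter_regulatory_snps(regulatory, snp_list)
        eqtl_genes = map_eqtl_genes(eqtl_snps, links)
        deg_genes = prioritize_tissue_degs(deg, cfg.deg_tissues, cfg.deg_alpha)
        twas_genes = select_twas_genes(twas, cfg.twas_phenotypes, cfg.twas_tissues)
        sets = merge_evidence_sets(eqtl_genes, deg_genes, twas_genes)

        io.write_json({"eqtl_snps": sorted(eqtl_snps), **sets.counts}, self.out / "evidence_counts.json")
        rows = []
        for g in sorted(sets.union):
            rows.append(
                (
                    g,
                    int(g in sets.eqtl_genes),
                    int(g in sets.deg_genes),
                    int(g in sets.twas_genes),
                )
            )
        io.write_table(
            pd.DataFrame(rows, columns=["gene", "eqtl", "deg", "twas"]),
            self.out / "prioritized_genes.tsv",
        )
        return {"eqtl_snps": len(eqtl_snps), **sets.counts}

    # -- stage 3 -----------------------------------------------------------
    def stage_network(self) -> dict[str, int]:
        cfg = self.cfg
        prioritized = set(
            pd.read_csv(self.out / "prioritized_genes.tsv", sep="\t")["gene"]
        )
        edges = io.read_string_edges(cfg.input_path("ppi_edges"))
        net = build_ppi_graph(edges, prioritized, cfg.score_min)
        table = compute_centralities(net)
        result = select_key_genes(table, cfg.top_k)
        if not result.key_genes:
            raise StageError(
                "network",
                "no gene appears in all three top-k centrality lists",
                hint="raise top_k or lower score_min",
            )
        io.write_table(table.reset_index(), self.out / "centralities.tsv")
        io.write_table(
            pd.DataFrame(sorted(result.key_genes), columns=["gene"]),
            self.out / "key_genes.tsv",
        )
        return {
            "network_nodes": len(net.nodes),
            "network_edges": net.n_edges,
            "key_genes": len(result.key_genes),
        }

    # -- stage 4 -----------------------------------------------------------
    def stage_enrichment(self) -> dict[str, int]:
        cfg = self.cfg
        key_genes = set(pd.read_csv(self.out / "key_genes.tsv", sep="\t")["gene"])
        lib = io.read_gmt(cfg.input_path("gene_sets"))
        from .enrichment import run_enrichment

        records = run_enrichment(key_genes, lib, cfg.enrich_alpha, cfg.min_overlap)
        rows = [
            (
                r.term_id,
                r.term_name,
                f"{r.overlap_k}/{r.term_size_K}",
                r.p,
                r.adj_p,
                int(r.significant),
                "|".join(sorted(r.overlap_genes)),
            )
            for r in records
        ]
        io.write_table(
            pd.DataFrame(
                rows,
                columns=["term_id", "term_name", "overlap", "p", "adj_p", "significant", "genes"],
            ),
            self.out / "enrichment.tsv",
        )
        return {
            "terms_tested": len(records),
            "terms_significant": sum(r.significant for r in records),
        }

    # -- stage 5 -----------------------------------------------------------
    def stage_drugs(self) -> dict[str, int]:
        cfg = self.cfg
        key_genes = set(pd.read_csv(self.out / "key_genes.tsv", sep="\t")["gene"])
        dgi = io.read_table(cfg.input_path("drug_gene"), "drug_gene")
        sider = io.read_table(cfg.input_path("side_effects"), "side_effects")
        ko = io.read_table(cfg.input_path("knockouts"), "knockouts")

        filtered = drugs_mod.filter_drug_interactions(
            dgi, key_genes, cfg.min_sources, cfg.min_pmids
        )
        summary = drugs_mod.classify_weight_effects(filtered)
        se_counts = drugs_mod.summarize_side_effects(set(filtered["drug"]), sider)
        calls = drugs_mod.flag_repurposing_candidates(filtered, se_counts, ko, cfg.max_effects)

        out_tab = filtered.copy()
        out_tab["sources"] = out_tab["sources"].map(lambda s: "|".join(sorted(s)))
        io.write_table(out_tab, self.out / "drug_interactions.tsv")
        io.write_table(se_counts, self.out / "side_effect_counts.tsv")
        io.write_table(calls, self.out / "repurposing_calls.tsv")
        io.write_json(
            {
                "weight_effect_counts": summary.counts,
                "n_drugs": summary.n_drugs,
                "n_drug_genes": summary.n_genes,
                "drugs_per_gene": summary.drugs_per_gene,
            },
            self.out / "drug_summary.json",
        )
        return {
            "interactions": len(filtered),
            "drugs": summary.n_drugs,
            "drug_genes": summary.n_genes,
            "repurposing_flagged": int(calls["flagged"].sum()) if len(calls) else 0,
        }

    # -- stage 6 -----------------------------------------------------------
    def stage_validation(self) -> dict[str, int]:
        cfg = self.cfg
        prioritized = frozenset(
            pd.read_csv(self.out / "prioritized_genes.tsv", sep="\t")["gene"]
        )
        key_genes = set(pd.read_csv(self.out / "key_genes.tsv", sep="\t")["gene"])
        lib = io.read_gmt(cfg.input_path("gene_sets"))
        ko = io.read_table(cfg.input_path("knockouts"), "knockouts")
        dgi = io.read_table(cfg.input_path("drug_gene"), "drug_gene")
        edges = io.read_string_edges(cfg.input_path("ppi_edges"))

        universe = frozenset(lib.effective_universe())
        references = {
            "knockout": frozenset(
                ko.loc[ko["obesity_phenotype"], "gene"].astype(str)
            ),
            "drug": frozenset(dgi["gene"].astype(str)),
        }
        ctx = NegativeControlContext(
            universe=universe,
            prioritized=prioritized,
            ppi_edges=edges,
            references=references,
            score_min=cfg.score_min,
            top_k=cfg.top_k,
        )
        vcfg = ValidationConfig(
            n_trials=cfg.n_trials,
            universe_size=len(universe),
            stage1_sample_size=min(len(prioritized), len(universe)),
            stage2_sample_size=len(key_genes),
            low_degree_max=cfg.low_degree_max,
            seed=cfg.seed,
        )
        reports = []
        skipped = []
        for scheme in ("stage1_random", "stage2_random", "stage2_low_degree"):
            try:
                trials = run_negative_control(scheme, vcfg, ctx)
            except SamplingError as exc:
                logger.warning("scheme %s skipped: %s", scheme, exc)
                skipped.append({"scheme": scheme, "reason": str(exc)})
                continue
            for ref_name in references:
                try:
                    reports.append(
                        build_validation_report(
                            scheme,
                            ref_name,
                            key_genes,
                            set(references[ref_name]),
                            trials.rates[ref_name],
                            method=cfg.test_method,
                        )
                    )
                except DegenerateTestError as exc:
                    skipped.append(
                        {"scheme": scheme, "reference": ref_name, "reason": str(exc)}
                    )
        io.write_json({"reports": reports, "skipped": skipped}, self.out / "validation.json")
        rows = [
            (
                r.scheme,
                r.reference,
                r.observed_count,
                round(100 * r.observed_rate, 2),
                round(100 * r.trial_median, 2),
                round(100 * r.trial_sd, 2),
                r.t_stat,
                r.p_two_sided,
            )
            for r in reports
        ]
        io.write_table(
            pd.DataFrame(
                rows,
                columns=[
                    "scheme",
                    "reference",
                    "observed_count",
                    "observed_pct",
                    "trial_median_pct",
                    "trial_sd_pct",
                    "t",
                    "p",
                ],
            ),
            self.out / "validation_summary.tsv",
        )
        return {"validation_reports": len(reports), "schemes_skipped": len(skipped)}


def run_stage(config: PipelineConfig, stage: str) -> dict[str, int]:
    """Run a single named stage, reading prerequisites from disk."""
    if stage not in STAGES:
        raise StageError(stage, f"unknown stage; expected one of {STAGES}")
    runner = _Runner(config)
    method = getattr(runner, f"stage_{stage}")
    try:
        counts = method()
    except PostGwasError:
        raise
    except FileNotFoundError as exc:
        raise StageError(stage, f"missing input: {exc}", hint="run earlier stages first") from exc
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, str(exc)) from exc
    logger.info("stage %s: %s", stage, counts)
    return counts


def run_pipeline(config: PipelineConfig, stages=STAGES) -> RunManifest:
    """Run the staged workflow and write a manifest.

    Aborts on the first failing stage with a :class:`StageError` naming it.
    """
    manifest = RunManifest(
        config_hash=config.config_hash(),
        input_checksums={},
        stage_counts={},
        started=time.time(),
    )
    for key, fname in INPUT_FILES.items():
        path = config.input_dir / fname
        if path.exists():
            manifest.input_checksums[key] = _sha256(path)
    for stage in stages:
        manifest.stage_counts[stage] = run_stage(config, stage)
    manifest.finished = time.time()
    io.write_json(
        {
            "config_hash": manifest.config_hash,
            "config": config.to_dict(),
            "input_checksums": manifest.input_checksums,
            "stage_counts": manifest.stage_counts,
            "version": manifest.version,
            "started": manifest.started,
            "finished": manifest.finished,
        },
        Path(config.output_dir) / "manifest.json",
    )
    return manifest
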