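"""Properties of the synthetic-knowledgebase generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from postgwas import SyntheticScenario, generate_study
from postgwas.exceptions import ConsistencyError, ParameterError
from postgwas.synthio import (
    boosted_probability,
    gen_evidence_tables,
    gen_gwas_summary,
    gen_knowledge_tables,
    gen_ppi_network,
    gen_reference_panel,
    make_truth,
)

from conftest import pearson_r2, tiny_scenario


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_snps": 0},
            {"true_gene_fraction": 0.0},
            {"true_gene_fraction": 1.2},
            {"n_planted_hubs": 10_000},
            {"enrichment_strength": 0.0},
            {"mutation_rate": 0.9},
            {"n_causal_snps": 10_000},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            tiny_scenario(seed=1, **kwargs)

    def test_boost_identity_and_saturation(self):
        assert boosted_probability(0.2, 1.0) == pytest.approx(0.2)
        assert boosted_probability(0.2, 8.0) == pytest.approx(2.0 / 3.0)
        assert boosted_probability(0.2, 1e9) == pytest.approx(1.0, abs=1e-6)


class TestPanel:
    def test_seeded_determinism(self):
        sc = tiny_scenario(seed=5)
        a, b = gen_reference_panel(sc), gen_reference_panel(sc)
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_dimensions_and_values(self):
        sc = tiny_scenario(seed=2, n_snps=100, n_samples=50)
        panel = gen_reference_panel(sc)
        assert panel.dosages.shape == (50, 100)
        assert set(np.unique(panel.dosages)) <= {0, 1, 2}

    def test_positions_strictly_increasing_per_chrom(self):
        panel = gen_reference_panel(tiny_scenario(seed=3))
        for _, grp in panel.variants.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
            assert grp["pos"].is_unique

    def test_within_block_ld_exceeds_cross_block(self):
        """Adjacent same-block pairs are more correlated than cross-block
        pairs, measured with the direct Pearson formula."""
        sc = SyntheticScenario(
            seed=4, n_chromosomes=1, chrom_length_bp=500_000, n_snps=200,
            n_samples=80, ld_block_size_bp=50_000, mutation_rate=0.02,
            n_genes=100, true_gene_fraction=0.1, n_planted_hubs=5,
            n_causal_snps=10, ppi_attachment=8,
        )
        panel = gen_reference_panel(sc)
        blocks = panel.variants["pos"].to_numpy() // sc.ld_block_size_bp
        within, cross = [], []
        for j in range(len(blocks) - 1):
            r2 = pearson_r2(panel.dosages[:, j], panel.dosages[:, j + 1])
            (within if blocks[j] == blocks[j + 1] else cross).append(r2)
        assert np.mean(within) > np.mean(cross)
        assert np.mean(within) > 0.5  # copy-with-mutation keeps pairs tight


class TestGwasSummary:
    def test_causal_snps_all_significant(self):
        sc = tiny_scenario(seed=6)
        panel = gen_reference_panel(sc)
        truth = make_truth(sc, panel)
        gwas = gen_gwas_summary(panel, truth, sc)
        below = gwas.loc[gwas["pvalue"] < 1e-8, "variant_id"]
        assert set(below) == set(truth.causal_snps)
        assert len(gwas) == len(panel.variants)

    def test_background_never_significant(self):
        sc = tiny_scenario(seed=6)
        panel = gen_reference_panel(sc)
        truth = make_truth(sc, panel)
        gwas = gen_gwas_summary(panel, truth, sc)
        bg = gwas.loc[~gwas["variant_id"].isin(truth.causal_snps), "pvalue"]
        assert (bg > 1e-6).all()

    def test_two_seeds_differ_same_schema(self):
        sc1, sc2 = tiny_scenario(seed=1), tiny_scenario(seed=2)
        p1 = gen_reference_panel(sc1)
        g1 = gen_gwas_summary(p1, make_truth(sc1, p1), sc1)
        p2 = gen_reference_panel(sc2)
        g2 = gen_gwas_summary(p2, make_truth(sc2, p2), sc2)
        assert list(g1.columns) == list(g2.columns)
        assert not np.array_equal(g1["pvalue"].to_numpy(), g2["pvalue"].to_numpy())

    def test_foreign_causal_snp_rejected(self):
        sc = tiny_scenario(seed=6)
        panel = gen_reference_panel(sc)
        from postgwas import TruthBundle

        bad = TruthBundle(
            true_genes=frozenset({"G000001"}),
            causal_snps=frozenset({"rs_not_there"}),
            planted_hubs=frozenset(),
        )
        with pytest.raises(ConsistencyError):
            gen_gwas_summary(panel, bad, sc)


def _true_fraction(gene_list, truth):
    genes = set(gene_list)
    return len(genes & truth.true_genes) / max(len(genes), 1)


class TestEvidenceTables:
    def test_referential_integrity(self, tiny_study):
        ev = tiny_study.evidence
        snps = set(tiny_study.panel.variant_ids)
        genes = set(tiny_study.scenario.gene_ids())
        assert set(ev.regulatory["variant_id"]) <= snps
        assert set(ev.eqtl_links["variant_id"]) <= snps
        assert set(ev.eqtl_links["gene"]) <= genes
        assert set(ev.tissue_deg["gene"]) <= genes
        assert set(ev.twas["gene"]) <= genes

    def test_null_strength_gives_background_true_fraction(self):
        """At strength 1 the true-gene share of each evidence list matches
        true_gene_fraction (pooled binomial check over 20 seeds)."""
        hits = {"eqtl": 0, "deg": 0, "twas": 0}
        totals = {"eqtl": 0, "deg": 0, "twas": 0}
        for seed in range(20):
            sc = tiny_scenario(seed=seed, enrichment_strength=1.0)
            panel = gen_reference_panel(sc)
            truth = make_truth(sc, panel)
            ev = gen_evidence_tables(panel, truth, sc)
            lists = {
                "eqtl": set(ev.eqtl_links["gene"]),
                "deg": set(ev.tissue_deg.loc[ev.tissue_deg["adj_p"] < 0.05, "gene"]),
                "twas": set(ev.twas["gene"]),
            }
            for name, gl in lists.items():
                hits[name] += len(gl & truth.true_genes)
                totals[name] += len(gl)
        p0 = 0.2  # tiny_scenario true_gene_fraction
        for name in hits:
            n, k = totals[name], hits[name]
            sd = np.sqrt(p0 * (1 - p0) / n)
            assert abs(k / n - p0) < 4 * sd, f"{name}: {k}/{n}"

    def test_enrichment_boosts_true_fraction(self):
        sc = tiny_scenario(seed=9, enrichment_strength=10.0)
        panel = gen_reference_panel(sc)
        truth = make_truth(sc, panel)
        ev = gen_evidence_tables(panel, truth, sc)
        overall = len(truth.true_genes) / sc.n_genes
        for gl in (
            set(ev.eqtl_links["gene"]),
            set(ev.tissue_deg.loc[ev.tissue_deg["direction"] == "up", "gene"]),
            set(ev.twas["gene"]),
        ):
            assert _true_fraction(gl, truth) > overall


class TestPpi:
    def test_seeded_determinism(self, tiny_study):
        sc = tiny_study.scenario
        net2 = gen_ppi_network(sc.gene_ids(), tiny_study.truth, sc)
        assert net2.edges == tiny_study.ppi.edges

    def test_hub_degree_dominates_in_every_seed(self):
        for seed in range(20):
            sc = tiny_scenario(seed=seed)
            panel = gen_reference_panel(sc)
            truth = make_truth(sc, panel)
            net = gen_ppi_network(sc.gene_ids(), truth, sc)
            deg = net.degree()
            hub_mean = np.mean([deg[g] for g in truth.planted_hubs])
            non_hub = [deg[g] for g in net.nodes if g not in truth.planted_hubs]
            assert hub_mean > np.mean(non_hub)
            assert hub_mean > np.percentile(non_hub, 90)

    def test_no_hubs_degrees_indistinguishable(self):
        """Without planted hubs, true genes' degree distribution matches the
        background (rank-sum per seed; few rejections over 20 seeds)."""
        rejections = 0
        for seed in range(20):
            sc = tiny_scenario(seed=seed, n_planted_hubs=0)
            panel = gen_reference_panel(sc)
            truth = make_truth(sc, panel)
            net = gen_ppi_network(sc.gene_ids(), truth, sc)
            deg = net.degree()
            true_deg = [deg[g] for g in truth.true_genes]
            bg_deg = [deg[g] for g in net.nodes if g not in truth.true_genes]
            p = stats.mannwhitneyu(true_deg, bg_deg).pvalue
            rejections += p < 0.05
        assert rejections <= 4

    def test_universe_smaller_than_attachment_rejected(self):
        sc = tiny_scenario(seed=1, ppi_attachment=140)
        panel = gen_reference_panel(sc)
        truth = make_truth(sc, panel)
        with pytest.raises(ParameterError):
            gen_ppi_network(sc.gene_ids(), truth, sc)

    def test_structural_invariants(self, tiny_study):
        net = tiny_study.ppi
        for (a, b), s in net.edges.items():
            assert a < b and 0.0 <= s <= 1.0


class TestKnowledgeTables:
    def test_referential_integrity(self, tiny_study):
        genes = set(tiny_study.scenario.gene_ids())
        kt = tiny_study.knowledge
        assert set(kt.drug_gene["gene"]) <= genes
        assert set(kt.knockouts["gene"]) <= genes
        for term in kt.gene_sets.terms.values():
            assert term.genes <= genes
        # some drugs legitimately lack side-effect rows ("no data")
        assert set(kt.side_effects["drug"]) <= set(kt.drug_gene["drug"])

    def test_planted_term_structure(self, tiny_study):
        kt = tiny_study.knowledge
        truth = tiny_study.truth
        term = kt.gene_sets.terms[kt.planted_term]
        assert len(term.genes) == 20
        assert len(term.genes & truth.true_genes) == 15
        assert truth.planted_hubs <= term.genes

    def test_null_strength_ko_rate_uniform(self):
        """At strength 1 knockout flags are independent of gene truth."""
        true_hits = true_tot = bg_hits = bg_tot = 0
        for seed in range(20):
            sc = tiny_scenario(seed=seed, enrichment_strength=1.0)
            panel = gen_reference_panel(sc)
            truth = make_truth(sc, panel)
            kt = gen_knowledge_tables(sc.gene_ids(), truth, sc)
            flagged = set(kt.knockouts.loc[kt.knockouts["obesity_phenotype"], "gene"])
            true_hits += len(flagged & truth.true_genes)
            true_tot += len(truth.true_genes)
            bg_hits += len(flagged - truth.true_genes)
            bg_tot += sc.n_genes - len(truth.true_genes)
        p_true, p_bg = true_hits / true_tot, bg_hits / bg_tot
        pooled = (true_hits + bg_hits) / (true_tot + bg_tot)
        sd = np.sqrt(pooled * (1 - pooled) * (1 / true_tot + 1 / bg_tot))
        assert abs(p_true - p_bg) < 4 * sd

    def test_drug_rows_well_formed(self, tiny_study):
        dg = tiny_study.knowledge.drug_gene
        assert set(dg["weight_effect"]) <= {"loss", "gain", "unknown"}
        assert (dg["pmid_count"] >= 0).all()
        assert dg["sources"].str.len().gt(0).all()


class TestFullStudyDeterminism:
    def test_identical_seed_identical_tables(self):
        sc = tiny_scenario(seed=21)
        a, b = generate_study(sc), generate_study(sc)
        pd.testing.assert_frame_equal(a.gwas, b.gwas)
        pd.testing.assert_frame_equal(a.evidence.tissue_deg, b.evidence.tissue_deg)
        pd.testing.assert_frame_equal(a.knowledge.drug_gene, b.knowledge.drug_gene)
        assert a.ppi.edges == b.ppi.edges
        assert a.truth == b.truth
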