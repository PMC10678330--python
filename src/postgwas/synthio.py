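"""Seeded synthetic knowledgebase generator.

Every downstream stage of the prioritization workflow consumes exports of
large public resources (GWAS summary statistics, a reference genotype panel,
regulatory annotation, eQTL links, tissue differential expression, TWAS hits,
a scored protein-interaction network, gene-set libraries, drug-gene
interactions, side-effect tables, mouse-knockout phenotypes).  This module
generates small stand-ins for all of them with the statistical structure the
analysis assumes:

* a genotype panel with block-wise linkage disequilibrium (haplotype
  copy-with-mutation inside fixed-size blocks, free recombination between
  blocks);
* genome-wide significant association p-values at a planted set of causal
  SNPs;
* evidence tables in which a planted set of "true" genes is over-represented
  by a configurable odds multiplier;
* a scale-free protein network with planted hub genes;
* knowledge tables (gene sets, drugs, side effects, knockouts) whose overlap
  with the true genes exceeds background by the same multiplier.

All generators are deterministic functions of ``(scenario, seed)``: each
draws from an independent :class:`numpy.random.Generator` stream derived
from the scenario seed, so tables can be regenerated individually and
byte-identically.

Enrichment model
----------------
Inclusion probabilities are boosted on the odds scale.  For a background
inclusion probability ``q`` and multiplier ``m``::

    odds' = m * q / (1 - q)          p' = odds' / (1 + odds')

so ``m = 1`` leaves every rate untouched (the null scenario) and large ``m``
saturates at 1.  True genes receive multiplier ``enrichment_strength``;
planted hubs — the core causal genes, which in real data accumulate evidence
in several resources at once — receive ``enrichment_strength ** 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, ParameterError
from .network import PpiNetwork

__all__ = [
    "SyntheticScenario",
    "TruthBundle",
    "GenotypePanel",
    "EvidenceTables",
    "KnowledgeTables",
    "PpiNetwork",
    "boosted_probability",
    "gen_reference_panel",
    "make_truth",
    "gen_gwas_summary",
    "gen_evidence_tables",
    "gen_ppi_network",
    "gen_knowledge_tables",
    "generate_study",
    "SyntheticStudy",
    "DEG_TARGET_TISSUES",
    "DEG_OTHER_TISSUES",
    "OBESITY_PHENOTYPES",
    "TWAS_BRAIN_TISSUES",
]

# Fixed child-stream ids so each table has its own reproducible RNG.
_STREAM_PANEL = 1
_STREAM_TRUTH = 2
_STREAM_GWAS = 3
_STREAM_EVIDENCE = 4
_STREAM_PPI = 5
_STREAM_KNOWLEDGE = 6

#: Brain tissues with the strongest upregulation signal; used as the default
#: target list for the differential-expression evidence layer.
DEG_TARGET_TISSUES = (
    "cortex",
    "frontal cortex ba9",
    "cerebellum",
    "cerebellar hemisphere",
    "anterior cingulate cortex ba24",
)

DEG_OTHER_TISSUES = ("liver", "whole blood", "pituitary", "muscle skeletal")

#: Phenotypes accepted as defining obesity in the TWAS evidence layer.
OBESITY_PHENOTYPES = ("bmi", "fat mass", "waist circumference", "weight")

#: Brain tissues accepted in the TWAS evidence layer.
TWAS_BRAIN_TISSUES = (
    "caudate basal ganglia",
    "cerebellar hemisphere",
    "cerebellum",
    "cortex",
    "frontal cortex ba9",
    "hippocampus",
    "hypothalamus",
    "nucleus accumbens basal ganglia",
    "putamen basal ganglia",
)

_REGULOME_CAT1 = ("1a", "1b", "1c", "1d", "1e", "1f")
_REGULOME_OTHER = ("2a", "2b", "2c", "3a", "3b", "4", "5", "6", "7")

_DGI_SOURCES = (
    "DrugBank",
    "TTD",
    "ChemblInteractions",
    "PharmGKB",
    "TdgClinicalTrial",
    "GuideToPharmacology",
    "CancerCommons",
    "MyCancerGenome",
)

_SIDE_EFFECT_VOCAB = (
    "nausea",
    "headache",
    "asthenia",
    "fatigue",
    "dermatitis",
    "vomiting",
    "diarrhoea",
    "dizziness",
    "insomnia",
    "decreased appetite",
    "musculoskeletal discomfort",
    "dry mouth",
    "constipation",
    "somnolence",
    "anxiety",
    "pruritus",
    "tremor",
    "anaemia",
    "arthralgia",
    "rash",
)


def boosted_probability(base: float, multiplier: float) -> float:
    """Boost an inclusion probability on the odds scale.

    ``p' = m*q / (1 - q + m*q)``; identity at ``m = 1``.
    """
    if not 0.0 <= base < 1.0:
        raise ParameterError(f"base probability must be in [0, 1): {base}")
    if multiplier < 0:
        raise ParameterError(f"multiplier must be non-negative: {multiplier}")
    odds = multiplier * base / (1.0 - base)
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class SyntheticScenario:
    """Dials of the synthetic study.

    The defaults define a desk-scale study mirroring the proportions of a
    human post-GWAS workflow at roughly one-twelfth size: ~1,200 genes stand
    in for the ~15k annotated genome, ~10% of them trait genes, 15 planted
    hubs standing in for the core causal genes, and evidence base rates set
    so the merged prioritized set covers ~15% of the universe.
    """

    seed: int
    n_chromosomes: int = 4
    chrom_length_bp: int = 5_000_000
    n_snps: int = 1000
    n_samples: int = 99
    n_genes: int = 1200
    true_gene_fraction: float = 0.10
    ld_block_size_bp: int = 50_000
    n_planted_hubs: int = 15
    enrichment_strength: float = 8.0
    n_causal_snps: int = 60
    mutation_rate: float = 0.02
    maf_low: float = 0.15
    maf_high: float = 0.5
    evidence_base_rate: float = 0.05
    ppi_attachment: int = 30
    ppi_coverage: float = 0.7
    ko_base_rate: float = 0.12
    drug_base_rate: float = 0.12

    def __post_init__(self):
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_snps": self.n_snps,
            "n_samples": self.n_samples,
            "n_genes": self.n_genes,
            "ld_block_size_bp": self.ld_block_size_bp,
            "n_causal_snps": self.n_causal_snps,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ParameterError(f"{name} must be a positive integer, got {value}")
        if not 0.0 < self.true_gene_fraction < 1.0:
            raise ParameterError(
                f"true_gene_fraction must be in (0, 1), got {self.true_gene_fraction}"
            )
        if self.n_planted_hubs < 0 or self.n_planted_hubs > self.n_genes:
            raise ParameterError("n_planted_hubs must be in [0, n_genes]")
        if self.n_planted_hubs > int(round(self.true_gene_fraction * self.n_genes)):
            raise ParameterError("n_planted_hubs cannot exceed the number of true genes")
        if self.enrichment_strength <= 0:
            raise ParameterError("enrichment_strength must be positive")
        if not 0.0 < self.mutation_rate < 0.5:
            raise ParameterError("mutation_rate must be in (0, 0.5)")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ParameterError("require 0 < maf_low <= maf_high <= 0.5")
        if self.n_causal_snps > self.n_snps:
            raise ParameterError("n_causal_snps cannot exceed n_snps")
        if not 0.0 < self.ppi_coverage <= 1.0:
            raise ParameterError("ppi_coverage must be in (0, 1]")
        if not 0.0 <= self.evidence_base_rate < 1.0:
            raise ParameterError("evidence_base_rate must be in [0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one output table."""
        return np.random.default_rng([int(self.seed), int(stream)])

    @property
    def n_true_genes(self) -> int:
        return int(round(self.true_gene_fraction * self.n_genes))

    def gene_ids(self) -> list[str]:
        width = max(6, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass(frozen=True)
class TruthBundle:
    """Planted ground truth used by recovery and calibration tests."""

    true_genes: frozenset[str]
    causal_snps: frozenset[str]
    planted_hubs: frozenset[str]

    def __post_init__(self):
        if not self.planted_hubs <= self.true_genes:
            raise ParameterError("planted_hubs must be a subset of true_genes")

    def gene_multiplier(self, scenario: SyntheticScenario) -> Mapping[str, float]:
        """Per-gene evidence odds multiplier: hubs get strength**2, other
        true genes strength, background 1."""
        s = scenario.enrichment_strength
        mult = {}
        for g in self.true_genes:
            mult[g] = s * s if g in self.planted_hubs else s
        return mult


@dataclass
class GenotypePanel:
    """Reference panel: dosage matrix plus per-variant coordinates."""

    sample_ids: list[str]
    variants: pd.DataFrame  # columns: variant_id, chrom, pos
    dosages: np.ndarray  # (n_samples, n_variants), values in {0,1,2}

    def __post_init__(self):
        n_samples, n_variants = self.dosages.shape
        if n_samples != len(self.sample_ids) or n_variants != len(self.variants):
            raise ParameterError("dosage matrix dimensions do not match id lists")
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def column(self, variant_id: str) -> int:
        return self._index[variant_id]

    def dosage_vector(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self._index[variant_id]]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])


@dataclass
class EvidenceTables:
    regulatory: pd.DataFrame  # variant_id, category
    eqtl_links: pd.DataFrame  # variant_id, gene
    tissue_deg: pd.DataFrame  # tissue, gene, adj_p, direction
    twas: pd.DataFrame  # gene, phenotype, tissue


@dataclass
class KnowledgeTables:
    gene_sets: "object"  # GeneSetLibrary; late import avoids a cycle
    drug_gene: pd.DataFrame
    side_effects: pd.DataFrame
    knockouts: pd.DataFrame
    planted_term: str = "PATH:PLANTED"


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_reference_panel(scenario: SyntheticScenario) -> GenotypePanel:
    """Simulate a diploid reference panel with block-wise LD.

    Haplotypes are generated block by block: the first SNP of each
    ``ld_block_size_bp`` block draws a fresh allele frequency, and each
    subsequent SNP copies the previous SNP's haplotype column, flipping
    alleles with probability ``mutation_rate``.  Adjacent SNPs inside a
    block are therefore strongly correlated while SNPs in different blocks
    are independent.
    """
    rng = scenario.rng(_STREAM_PANEL)
    n_hap = 2 * scenario.n_samples

    per_chrom = _split_counts(scenario.n_snps, scenario.n_chromosomes)
    variant_rows = []
    hap_cols = []
    snp_no = 0
    for ci, n_c in enumerate(per_chrom, start=1):
        chrom = str(ci)
        positions = np.sort(
            rng.choice(np.arange(1, scenario.chrom_length_bp + 1), size=n_c, replace=False)
        )
        prev_block = None
        prev_hap = None
        for pos in positions:
            snp_no += 1
            block = int(pos) // scenario.ld_block_size_bp
            if block != prev_block or prev_hap is None:
                maf = rng.uniform(scenario.maf_low, scenario.maf_high)
                hap = (rng.random(n_hap) < maf).astype(np.int8)
            else:
                flip = rng.random(n_hap) < scenario.mutation_rate
                hap = np.where(flip, 1 - prev_hap, prev_hap).astype(np.int8)
            # guard against (very rare) monomorphic columns so pairwise LD
            # is always defined on the panel
            while hap.sum() == 0 or hap.sum() == n_hap:
                hap[rng.integers(n_hap)] ^= 1
            hap_cols.append(hap)
            prev_block, prev_hap = block, hap
            variant_rows.append((f"rs{snp_no:06d}", chrom, int(pos)))

    haplotypes = np.column_stack(hap_cols)
    dosages = (haplotypes[: scenario.n_samples] + haplotypes[scenario.n_samples :]).astype(
        np.int8
    )
    variants = pd.DataFrame(variant_rows, columns=["variant_id", "chrom", "pos"])
    sample_ids = [f"S{i:04d}" for i in range(1, scenario.n_samples + 1)]
    return GenotypePanel(sample_ids=sample_ids, variants=variants, dosages=dosages)


def make_truth(scenario: SyntheticScenario, panel: GenotypePanel) -> TruthBundle:
    """Draw the planted ground truth: true genes, hubs, causal SNPs."""
    rng = scenario.rng(_STREAM_TRUTH)
    genes = scenario.gene_ids()
    true_genes = rng.choice(genes, size=scenario.n_true_genes, replace=False)
    hubs = true_genes[: scenario.n_planted_hubs]
    causal = rng.choice(panel.variant_ids, size=scenario.n_causal_snps, replace=False)
    return TruthBundle(
        true_genes=frozenset(true_genes.tolist()),
        causal_snps=frozenset(causal.tolist()),
        planted_hubs=frozenset(hubs.tolist()),
    )


def gen_gwas_summary(
    panel: GenotypePanel, truth: TruthBundle, scenario: SyntheticScenario
) -> pd.DataFrame:
    """Per-variant association p-values.

    Causal SNPs get ``p = 10**(-8 - Exp(1))`` (always genome-wide
    significant); all other SNPs draw uniformly on (1e-6, 1], so the null
    never produces a false significant at the 1e-8 cut.
    """
    missing = sorted(v for v in truth.causal_snps if v not in panel)
    if missing:
        raise ConsistencyError(f"causal SNPs absent from panel: {missing[:5]}")
    rng = scenario.rng(_STREAM_GWAS)
    out = panel.variants.copy()
    p = rng.uniform(1e-6, 1.0, size=len(out))
    causal_mask = out["variant_id"].isin(truth.causal_snps).to_numpy()
    p[causal_mask] = 10.0 ** (-8.0 - rng.exponential(1.0, size=causal_mask.sum()))
    out["pvalue"] = p
    return out


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    rem = total - base * parts
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _gene_inclusion(
    rng: np.random.Generator,
    genes: Iterable[str],
    base: float,
    mult: Mapping[str, float],
) -> list[str]:
    out = []
    for g in genes:
        p = boosted_probability(base, mult.get(g, 1.0))
        if rng.random() < p:
            out.append(g)
    return out


def gen_evidence_tables(
    panel: GenotypePanel, truth: TruthBundle, scenario: SyntheticScenario
) -> EvidenceTables:
    """Regulatory annotation, eQTL links, tissue DEG rows and TWAS hits.

    Each evidence layer includes a gene with probability
    ``boosted_probability(evidence_base_rate, multiplier(gene))``, so at
    ``enrichment_strength = 1`` the layers are uniform random samples of the
    gene universe.  eQTL links attach to causal SNPs with a boosted
    probability for true genes, which is what lets the SNP-level filters
    recover them downstream.
    """
    rng = scenario.rng(_STREAM_EVIDENCE)
    genes = scenario.gene_ids()
    mult = truth.gene_multiplier(scenario)
    q = scenario.evidence_base_rate
    causal = sorted(truth.causal_snps)
    all_snps = panel.variant_ids

    # --- eQTL layer -------------------------------------------------------
    eqtl_genes = _gene_inclusion(rng, genes, q, mult)
    link_rows = []
    for g in eqtl_genes:
        n_links = int(rng.integers(1, 4))
        w_causal = boosted_probability(0.15, mult.get(g, 1.0))
        for _ in range(n_links):
            if causal and rng.random() < w_causal:
                snp = causal[int(rng.integers(len(causal)))]
            else:
                snp = all_snps[int(rng.integers(len(all_snps)))]
            link_rows.append((snp, g))
    eqtl_links = pd.DataFrame(link_rows, columns=["variant_id", "gene"]).drop_duplicates()

    # --- regulatory categories -------------------------------------------
    linked = set(eqtl_links["variant_id"])
    categories = []
    for v in all_snps:
        if v in linked:
            categories.append(_REGULOME_CAT1[int(rng.integers(len(_REGULOME_CAT1)))])
        elif rng.random() < 0.05:
            # eQTL-category SNPs without a link table entry exist in real
            # annotation snapshots; the mapper simply finds no gene for them
            categories.append(_REGULOME_CAT1[int(rng.integers(len(_REGULOME_CAT1)))])
        else:
            categories.append(_REGULOME_OTHER[int(rng.integers(len(_REGULOME_OTHER)))])
    regulatory = pd.DataFrame({"variant_id": all_snps, "category": categories})

    # --- tissue differential expression ----------------------------------
    deg_rows = []
    for g in _gene_inclusion(rng, genes, q, mult):
        tissue = DEG_TARGET_TISSUES[int(rng.integers(len(DEG_TARGET_TISSUES)))]
        deg_rows.append((tissue, g, rng.uniform(0.0, 0.0499), "up"))
    for g in genes:
        if rng.random() < 0.10:  # decoy rows that must fail one filter
            kind = rng.integers(3)
            if kind == 0:
                tissue = DEG_TARGET_TISSUES[int(rng.integers(len(DEG_TARGET_TISSUES)))]
                deg_rows.append((tissue, g, rng.uniform(0.0, 0.0499), "down"))
            elif kind == 1:
                tissue = DEG_OTHER_TISSUES[int(rng.integers(len(DEG_OTHER_TISSUES)))]
                deg_rows.append((tissue, g, rng.uniform(0.0, 0.0499), "up"))
            else:
                tissue = DEG_TARGET_TISSUES[int(rng.integers(len(DEG_TARGET_TISSUES)))]
                deg_rows.append((tissue, g, rng.uniform(0.05, 1.0), "up"))
    tissue_deg = pd.DataFrame(deg_rows, columns=["tissue", "gene", "adj_p", "direction"])

    # --- TWAS hits --------------------------------------------------------
    twas_rows = []
    for g in _gene_inclusion(rng, genes, q, mult):
        phen = OBESITY_PHENOTYPES[int(rng.integers(len(OBESITY_PHENOTYPES)))]
        tissue = TWAS_BRAIN_TISSUES[int(rng.integers(len(TWAS_BRAIN_TISSUES)))]
        twas_rows.append((g, phen, tissue))
    for g in genes:
        if rng.random() < 0.08:
            if rng.random() < 0.5:
                twas_rows.append((g, "height", TWAS_BRAIN_TISSUES[0]))
            else:
                twas_rows.append(
                    (g, OBESITY_PHENOTYPES[int(rng.integers(len(OBESITY_PHENOTYPES)))], "whole blood")
                )
    twas = pd.DataFrame(twas_rows, columns=["gene", "phenotype", "tissue"])

    return EvidenceTables(
        regulatory=regulatory, eqtl_links=eqtl_links, tissue_deg=tissue_deg, twas=twas
    )


def gen_ppi_network(
    gene_universe: Iterable[str], truth: TruthBundle, scenario: SyntheticScenario
) -> PpiNetwork:
    """Scale-free scored interaction network with planted hubs.

    A preferential-attachment (Barabasi-Albert) graph is built over a random
    ``ppi_coverage`` fraction of the universe (planted hubs always
    participate; the rest of the universe stays isolated, as many genes do
    in real interaction databases).  Hub status is decoupled from gene
    identity by shuffling the node labels, then each planted hub receives
    extra high-confidence edges until its degree reaches twice the 90th
    percentile of non-hub degree.
    """
    import networkx as nx

    universe = sorted(set(gene_universe))
    if not truth.planted_hubs <= set(universe):
        raise ParameterError("planted hubs must be inside the gene universe")
    rng = scenario.rng(_STREAM_PPI)

    n_part = int(round(scenario.ppi_coverage * len(universe)))
    if n_part <= scenario.ppi_attachment:
        raise ParameterError(
            f"participating gene count {n_part} must exceed attachment "
            f"parameter {scenario.ppi_attachment}"
        )
    hubs = sorted(truth.planted_hubs)
    non_hubs = [g for g in universe if g not in truth.planted_hubs]
    extra = rng.choice(non_hubs, size=n_part - len(hubs), replace=False).tolist()
    participating = hubs + extra
    # shuffle so BA hub positions are independent of gene identity
    order = rng.permutation(len(participating))
    labels = [participating[i] for i in order]

    ba_seed = int(rng.integers(2**31 - 1))
    g = nx.barabasi_albert_graph(len(participating), scenario.ppi_attachment, seed=ba_seed)

    edges: dict[tuple[str, str], float] = {}
    for u, v in g.edges():
        a, b = sorted((labels[u], labels[v]))
        edges[(a, b)] = float(rng.uniform(0.2, 1.0))

    deg = {n: 0 for n in participating}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    if hubs and scenario.enrichment_strength > 0:
        non_hub_deg = [deg[n] for n in participating if n not in truth.planted_hubs]
        target = int(2 * np.percentile(non_hub_deg, 90)) if non_hub_deg else 0
        for h in hubs:
            attempts = 0
            while deg[h] < target and attempts < 20 * target:
                partner = participating[int(rng.integers(len(participating)))]
                attempts += 1
                if partner == h:
                    continue
                key = tuple(sorted((h, partner)))
                if key in edges:
                    continue
                edges[key] = float(rng.uniform(0.7, 1.0))
                deg[h] += 1
                deg[partner] += 1

    return PpiNetwork(nodes=tuple(universe), edges=edges)


def gen_knowledge_tables(
    gene_universe: Iterable[str], truth: TruthBundle, scenario: SyntheticScenario
) -> KnowledgeTables:
    """Gene-set library, drug-gene interactions, side effects, knockouts.

    The library contains one planted term built around the planted hubs
    (the core causal pathway) plus random terms.  Drug interactions and
    knockout flags use the same odds-boost model as the evidence layers,
    so at ``enrichment_strength = 1`` both are independent of gene truth.
    """
    from .enrichment import GeneSetLibrary, GeneSetTerm

    rng = scenario.rng(_STREAM_KNOWLEDGE)
    universe = sorted(set(gene_universe))
    mult = truth.gene_multiplier(scenario)

    # --- gene-set library -------------------------------------------------
    planted_size, planted_true = 20, 15
    hubs = sorted(truth.planted_hubs)
    other_true = sorted(truth.true_genes - truth.planted_hubs)
    background = [g for g in universe if g not in truth.true_genes]
    members = list(hubs[:planted_true])
    if len(members) < planted_true:
        fill = rng.choice(other_true, size=planted_true - len(members), replace=False)
        members.extend(fill.tolist())
    bg_fill = rng.choice(background, size=planted_size - len(members), replace=False)
    members.extend(bg_fill.tolist())
    planted_id = "PATH:PLANTED"
    terms = {
        planted_id: GeneSetTerm(planted_id, "planted core causal pathway", frozenset(members))
    }
    for i in range(1, 40):
        size = int(rng.integers(15, 61))
        term_genes = rng.choice(universe, size=size, replace=False)
        tid = f"PATH:{i:04d}"
        terms[tid] = GeneSetTerm(tid, f"random pathway {i}", frozenset(term_genes.tolist()))
    library = GeneSetLibrary(terms=terms, universe=frozenset(universe))

    # --- drug catalog and interactions ------------------------------------
    drug_rows = []
    catalog: list[dict] = []

    def _new_drug() -> dict:
        i = len(catalog) + 1
        heavy = rng.random() < 0.10
        drug = {
            "drug": f"D{i:04d}",
            "approved": bool(rng.random() < 0.85),
            "weight_effect": ["loss", "gain", "unknown"][
                int(rng.choice(3, p=[0.5, 0.3, 0.2]))
            ],
            "n_very_common": int(rng.poisson(20 if heavy else 1.2)),
        }
        catalog.append(drug)
        return drug

    for g in universe:
        p = boosted_probability(scenario.drug_base_rate, mult.get(g, 1.0))
        if rng.random() >= p:
            continue
        for _ in range(int(rng.integers(1, 4))):
            # reuse an existing drug half the time so drugs hit several genes
            if catalog and rng.random() < 0.5:
                drug = catalog[int(rng.integers(len(catalog)))]
            else:
                drug = _new_drug()
            n_src = int(rng.integers(1, 5))
            sources = rng.choice(_DGI_SOURCES, size=n_src, replace=False)
            drug_rows.append(
                (
                    drug["drug"],
                    g,
                    drug["approved"],
                    "|".join(sorted(sources.tolist())),
                    int(rng.poisson(2.0)),
                    drug["weight_effect"],
                )
            )
    drug_gene = pd.DataFrame(
        drug_rows,
        columns=["drug", "gene", "approved", "sources", "pmid_count", "weight_effect"],
    ).drop_duplicates(subset=["drug", "gene"])

    # --- side effects ------------------------------------------------------
    se_rows = []
    for drug in catalog:
        vocab = rng.permutation(len(_SIDE_EFFECT_VOCAB))
        n_vc = min(drug["n_very_common"], len(_SIDE_EFFECT_VOCAB))
        for j in range(n_vc):
            se_rows.append((drug["drug"], _SIDE_EFFECT_VOCAB[vocab[j]], "very common"))
        for _ in range(int(rng.poisson(2.0))):
            eff = _SIDE_EFFECT_VOCAB[int(rng.integers(len(_SIDE_EFFECT_VOCAB)))]
            cls = ["common", "uncommon", "rare", "very rare"][int(rng.integers(4))]
            se_rows.append((drug["drug"], eff, cls))
    side_effects = pd.DataFrame(
        se_rows, columns=["drug", "effect", "frequency_class"]
    ).drop_duplicates()

    # --- knockout phenotypes ----------------------------------------------
    ko_rows = []
    for g in universe:
        p = boosted_probability(scenario.ko_base_rate, mult.get(g, 1.0))
        ko_rows.append((g, bool(rng.random() < p)))
    knockouts = pd.DataFrame(ko_rows, columns=["gene", "obesity_phenotype"])

    return KnowledgeTables(
        gene_sets=library,
        drug_gene=drug_gene,
        side_effects=side_effects,
        knockouts=knockouts,
        planted_term=planted_id,
    )


@dataclass
class SyntheticStudy:
    """All inputs of one synthetic study, generated from a single scenario."""

    scenario: SyntheticScenario
    panel: GenotypePanel
    truth: TruthBundle
    gwas: pd.DataFrame
    evidence: EvidenceTables
    ppi: PpiNetwork
    knowledge: KnowledgeTables

    @property
    def gene_universe(self) -> list[str]:
        return self.scenario.gene_ids()


def generate_study(scenario: SyntheticScenario) -> SyntheticStudy:
    """Generate every input table of one synthetic study."""
    panel = gen_reference_panel(scenario)
    truth = make_truth(scenario, panel)
    gwas = gen_gwas_summary(panel, truth, scenario)
    evidence = gen_evidence_tables(panel, truth, scenario)
    ppi = gen_ppi_network(scenario.gene_ids(), truth, scenario)
    knowledge = gen_knowledge_tables(scenario.gene_ids(), truth, scenario)
    return SyntheticStudy(
        scenario=scenario,
        panel=panel,
        truth=truth,
        gwas=gwas,
        evidence=evidence,
        ppi=ppi,
        knowledge=knowledge,
    )
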