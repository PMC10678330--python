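"""Evidence-layer filters and gene-set merging.

Three independent lines of in-silico evidence nominate candidate genes from
the associated SNP list:

* regulatory/eQTL — SNPs in the top regulatory annotation tier (categories
  1a-1f, i.e. eQTL-SNPs) mapped to the genes whose expression they affect;
* tissue differential expression — genes upregulated in the target brain
  tissues at adjusted p < 0.05;
* TWAS — genes whose imputed expression associates with an obesity-defining
  phenotype in a brain tissue.

The three gene sets are merged by union with full overlap accounting
(every pairwise intersection and the triple), and the inclusion-exclusion
identity is verified on every merge.

Gene identity is the symbol string after uppercase/whitespace
normalization; cross-resource synonym resolution is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ValidationError
from .synthio import DEG_TARGET_TISSUES, OBESITY_PHENOTYPES, TWAS_BRAIN_TISSUES

__all__ = [
    "REGULOME_CATEGORIES",
    "CATEGORY_1",
    "normalize_symbol",
    "filter_regulatory_snps",
    "map_eqtl_genes",
    "prioritize_tissue_degs",
    "select_twas_genes",
    "merge_evidence_sets",
    "EvidenceGeneSets",
]

#: Closed vocabulary of regulatory annotation categories.
REGULOME_CATEGORIES = frozenset(
    ["1a", "1b", "1c", "1d", "1e", "1f", "2a", "2b", "2c", "3a", "3b", "4", "5", "6", "7"]
)

#: The eQTL-SNP tier: strong evidence of affecting expression.
CATEGORY_1 = frozenset(["1a", "1b", "1c", "1d", "1e", "1f"])


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def _norm_tissue(t: str) -> str:
    return str(t).strip().lower()


def filter_regulatory_snps(
    annot: pd.DataFrame,
    snps: pd.DataFrame,
    categories: frozenset[str] = CATEGORY_1,
) -> set[str]:
    """Variants from ``snps`` whose annotation category is in ``categories``.

    ``categories`` defaults to the 1a-1f eQTL tier; passing a different set
    supports numeric-rank style annotations.  Unknown category strings raise
    :class:`ValidationError`.
    """
    unknown = set(annot["category"].astype(str)) - REGULOME_CATEGORIES
    if unknown:
        raise ValidationError(f"unknown regulatory categories: {sorted(unknown)}")
    snp_ids = set(snps["variant_id"])
    keep = annot.loc[annot["category"].isin(categories), "variant_id"]
    return {v for v in keep if v in snp_ids}


def map_eqtl_genes(eqtl_snps: set[str], links: pd.DataFrame) -> set[str]:
    """Union of genes linked to any retained eQTL-SNP."""
    hit = links.loc[links["variant_id"].isin(eqtl_snps), "gene"]
    return {normalize_symbol(g) for g in hit}


def prioritize_tissue_degs(
    deg: pd.DataFrame,
    target_tissues: list[str] | tuple[str, ...] = DEG_TARGET_TISSUES,
    alpha: float = 0.05,
) -> set[str]:
    """Genes upregulated in a target tissue at adjusted p strictly < alpha."""
    if not target_tissues:
        raise ValidationError("target_tissues must be non-empty")
    targets = {_norm_tissue(t) for t in target_tissues}
    mask = (
        (deg["direction"] == "up")
        & (deg["adj_p"] < alpha)
        & deg["tissue"].map(_norm_tissue).isin(targets)
    )
    return {normalize_symbol(g) for g in deg.loc[mask, "gene"]}


def select_twas_genes(
    twas: pd.DataFrame,
    phenotypes: list[str] | tuple[str, ...] = OBESITY_PHENOTYPES,
    brain_tissues: list[str] | tuple[str, ...] = TWAS_BRAIN_TISSUES,
) -> set[str]:
    """Genes with >= 1 hit for an accepted phenotype in an accepted tissue."""
    if not phenotypes or not brain_tissues:
        raise ValidationError("phenotype and tissue lists must be non-empty")
    phen = {_norm_tissue(p) for p in phenotypes}
    tiss = {_norm_tissue(t) for t in brain_tissues}
    mask = twas["phenotype"].map(_norm_tissue).isin(phen) & twas["tissue"].map(
        _norm_tissue
    ).isin(tiss)
    return {normalize_symbol(g) for g in twas.loc[mask, "gene"]}


@dataclass(frozen=True)
class EvidenceGeneSets:
    """The three evidence gene lists plus their union and overlap counts."""

    eqtl_genes: frozenset[str]
    deg_genes: frozenset[str]
    twas_genes: frozenset[str]
    union: frozenset[str] = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "union", frozenset(self.eqtl_genes | self.deg_genes | self.twas_genes)
        )

    @property
    def counts(self) -> dict[str, int]:
        e, d, t = self.eqtl_genes, self.deg_genes, self.twas_genes
        return {
            "eqtl": len(e),
            "deg": len(d),
            "twas": len(t),
            "eqtl_deg": len(e & d),
            "twas_deg": len(t & d),
            "twas_eqtl": len(t & e),
            "triple": len(e & d & t),
            "union": len(self.union),
        }

    def check_inclusion_exclusion(self) -> None:
        c = self.counts
        lhs = c["union"]
        rhs = (
            c["eqtl"] + c["deg"] + c["twas"]
            - c["eqtl_deg"] - c["twas_deg"] - c["twas_eqtl"]
            + c["triple"]
        )
        if lhs != rhs:
            raise AssertionError(f"inclusion-exclusion violated: {lhs} != {rhs}")


def merge_evidence_sets(
    eqtl_genes: set[str], deg_genes: set[str], twas_genes: set[str]
) -> EvidenceGeneSets:
    """Merge the three prioritized gene lists with overlap accounting."""
    out = EvidenceGeneSets(
        eqtl_genes=frozenset(normalize_symbol(g) for g in eqtl_genes),
        deg_genes=frozenset(normalize_symbol(g) for g in deg_genes),
        twas_genes=frozenset(normalize_symbol(g) for g in twas_genes),
    )
    out.check_inclusion_exclusion()
    return out
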