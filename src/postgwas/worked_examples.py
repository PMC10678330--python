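"""Synthetic stand-ins for the published supplementary tables.

The full-scale study's supplementary gene and drug tables are not
redistributable, but their reported marginal and overlap structure is: the
three evidence lists (243 eQTL genes, 845 tissue-DEG genes, 396 TWAS genes
with 63 TWAS/DEG, 31 TWAS/eQTL and 14 triple overlaps, union 1,372), the
drug-interaction table (23 target genes, 78 approved drugs: 47 weight-loss,
19 weight-gain, 12 unknown) and the side-effect profile (19 of the 78 drugs
with very-common side effects; e.g. ribavirin 52, duloxetine 1,
paliperidone 1, quetiapine 2, amisulpride 7, oxcarbazepine 8).

The builders here construct *synthetic* tables realizing exactly that
structure, so the merging, filtering and counting operations can be
exercised end to end on inputs with the published shape.  Gene and drug
identifiers (beyond the handful of drug names quoted with their side-effect
counts) are synthetic.
"""

from __future__ import annotations

import itertools

import pandas as pd

__all__ = [
    "evidence_gene_lists",
    "drug_interaction_table",
    "side_effect_table",
    "NAMED_SIDE_EFFECT_COUNTS",
]

#: Very-common side-effect counts quoted for real drugs.
NAMED_SIDE_EFFECT_COUNTS = {
    "ribavirin": 52,
    "duloxetine": 1,
    "paliperidone": 1,
    "quetiapine": 2,
    "amisulpride": 7,
    "oxcarbazepine": 8,
}

# Region sizes of the three-set Venn diagram implied by the published
# counts (the eQTL/DEG pairwise overlap of 32 follows from
# inclusion-exclusion: 243 + 845 + 396 - 63 - 31 - x + 14 = 1372).
_TRIPLE = 14
_TWAS_DEG_ONLY = 63 - 14
_TWAS_EQTL_ONLY = 31 - 14
_EQTL_DEG_ONLY = 32 - 14
_EQTL_ONLY = 243 - _TRIPLE - _TWAS_EQTL_ONLY - _EQTL_DEG_ONLY
_DEG_ONLY = 845 - _TRIPLE - _TWAS_DEG_ONLY - _EQTL_DEG_ONLY
_TWAS_ONLY = 396 - _TRIPLE - _TWAS_DEG_ONLY - _TWAS_EQTL_ONLY


def evidence_gene_lists() -> tuple[set[str], set[str], set[str]]:
    """Three synthetic evidence gene lists with the published overlap
    structure; returns (eqtl_genes, deg_genes, twas_genes)."""
    counter = itertools.count(1)

    def draw(n: int) -> set[str]:
        return {f"EV{next(counter):05d}" for _ in range(n)}

    triple = draw(_TRIPLE)
    twas_deg = draw(_TWAS_DEG_ONLY)
    twas_eqtl = draw(_TWAS_EQTL_ONLY)
    eqtl_deg = draw(_EQTL_DEG_ONLY)
    eqtl_only = draw(_EQTL_ONLY)
    deg_only = draw(_DEG_ONLY)
    twas_only = draw(_TWAS_ONLY)

    eqtl = triple | twas_eqtl | eqtl_deg | eqtl_only
    deg = triple | twas_deg | eqtl_deg | deg_only
    twas = triple | twas_deg | twas_eqtl | twas_only
    return eqtl, deg, twas


def _drug_names() -> list[str]:
    named = sorted(NAMED_SIDE_EFFECT_COUNTS)
    synthetic = [f"drug{i:03d}" for i in range(1, 79 - len(named) + 1)]
    return named + synthetic  # 78 drugs total


def drug_interaction_table() -> pd.DataFrame:
    """Synthetic filtered-eligible interaction table: 78 approved drugs,
    23 target genes, weight effects 47 loss / 19 gain / 12 unknown, plus
    decoy rows that the evidence filter must remove."""
    drugs = _drug_names()
    genes = [f"KEY{i:02d}" for i in range(1, 24)]
    effects = ["loss"] * 47 + ["gain"] * 19 + ["unknown"] * 12
    rows = []
    for i, (drug, effect) in enumerate(zip(drugs, effects)):
        gene = genes[i % len(genes)]
        rows.append((drug, gene, True, "DrugBank|TTD", 3, effect))
        if i % 4 == 0:  # some drugs hit a second key gene
            rows.append((drug, genes[(i + 7) % len(genes)], True, "DrugBank|TTD", 2, effect))
    # decoys: unapproved, under-sourced, cancer-only-sourced, non-key gene
    rows.append(("decoy_unapproved", genes[0], False, "DrugBank|TTD", 5, "loss"))
    rows.append(("decoy_single_source", genes[1], True, "DrugBank", 5, "gain"))
    rows.append(("decoy_cancer_source", genes[2], True, "DrugBank|CancerCommons", 5, "loss"))
    rows.append(("decoy_offtarget", "NOTKEY1", True, "DrugBank|TTD", 5, "loss"))
    return pd.DataFrame(
        rows, columns=["drug", "gene", "approved", "sources", "pmid_count", "weight_effect"]
    )


def side_effect_table() -> pd.DataFrame:
    """Synthetic side-effect table: the six named drugs with their quoted
    very-common counts, 13 further drugs with one very-common effect each
    (19 of 78 in total), and common-only rows for a handful of others."""
    rows = []
    for drug, n in NAMED_SIDE_EFFECT_COUNTS.items():
        for j in range(n):
            rows.append((drug, f"effect_{j:03d}", "very common"))
        rows.append((drug, "effect_common", "common"))
    extra_vc = [f"drug{i:03d}" for i in range(1, 14)]  # 13 more with data
    for drug in extra_vc:
        rows.append((drug, "effect_000", "very common"))
        rows.append((drug, "effect_001", "rare"))
    for drug in (f"drug{i:03d}" for i in range(14, 20)):  # data but no very-common
        rows.append((drug, "effect_002", "common"))
    return pd.DataFrame(rows, columns=["drug", "effect", "frequency_class"])
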