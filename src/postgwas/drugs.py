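"""Drug-gene interaction filtering, weight-effect tallies, side-effect
summaries and repurposing triage.

Interactions are kept when the drug is approved, the target gene is a key
gene, the interaction is supported by at least ``min_sources`` databases
after removing cancer-specific sources, and at least ``min_pmids``
supporting publications exist.  Per-drug weight-effect classes (loss /
gain / unknown — input annotations derived from the literature) are
tallied over distinct drugs.  Side-effect burden counts distinct "very
common" effects (MedDRA frequency >= 10%) per drug, and a drug is flagged
as a repurposing candidate when that burden is at most ``max_effects`` and
it targets at least one gene with an obesity-related mouse-knockout
abnormality.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evidence import normalize_symbol
from .exceptions import ValidationError

__all__ = [
    "DEFAULT_EXCLUDED_SOURCES",
    "FREQUENCY_CLASSES",
    "filter_drug_interactions",
    "classify_weight_effects",
    "WeightEffectSummary",
    "summarize_side_effects",
    "flag_repurposing_candidates",
]

#: Cancer-specific interaction sources excluded from the evidence count.
DEFAULT_EXCLUDED_SOURCES = frozenset({"CancerCommons", "MyCancerGenome"})

FREQUENCY_CLASSES = frozenset(
    {"very common", "common", "uncommon", "rare", "very rare", "unknown"}
)

WEIGHT_EFFECTS = frozenset({"loss", "gain", "unknown"})


def _split_sources(value) -> frozenset[str]:
    if isinstance(value, (set, frozenset, list, tuple)):
        return frozenset(str(s) for s in value)
    return frozenset(s for s in str(value).split("|") if s)


def filter_drug_interactions(
    table: pd.DataFrame,
    key_genes: set[str],
    min_sources: int = 2,
    min_pmids: int = 1,
    excluded_source_tags: frozenset[str] = DEFAULT_EXCLUDED_SOURCES,
) -> pd.DataFrame:
    """Evidence-filtered drug-gene interactions restricted to key genes."""
    keys = {normalize_symbol(g) for g in key_genes}
    out = table.copy()
    out["gene"] = out["gene"].map(normalize_symbol)
    out["sources"] = out["sources"].map(_split_sources)
    n_eff = out["sources"].map(lambda s: len(s - excluded_source_tags))
    mask = (
        out["gene"].isin(keys)
        & out["approved"].astype(bool)
        & (n_eff >= min_sources)
        & (out["pmid_count"] >= min_pmids)
    )
    return out.loc[mask].reset_index(drop=True)


@dataclass(frozen=True)
class WeightEffectSummary:
    """Distinct-drug counts per weight-effect class and per-gene tallies."""

    counts: dict[str, int]  # loss / gain / unknown -> distinct drugs
    drugs_per_gene: dict[str, int]  # gene -> number of interacting drugs
    n_drugs: int
    n_genes: int


def classify_weight_effects(filtered: pd.DataFrame) -> WeightEffectSummary:
    """Tally weight-effect classes over distinct drugs.

    A drug listed under several genes is counted once; a drug carrying
    conflicting class annotations across rows is a validation error.
    """
    if len(filtered) == 0:
        return WeightEffectSummary(
            counts={"loss": 0, "gain": 0, "unknown": 0}, drugs_per_gene={}, n_drugs=0, n_genes=0
        )
    bad = set(filtered["weight_effect"]) - WEIGHT_EFFECTS
    if bad:
        raise ValidationError(f"unknown weight-effect labels: {sorted(bad)}")
    per_drug = filtered.groupby("drug")["weight_effect"].agg(set)
    conflicts = per_drug[per_drug.map(len) > 1]
    if len(conflicts):
        raise ValidationError(
            f"conflicting weight-effect annotations for drugs: {sorted(conflicts.index)[:5]}"
        )
    effect = per_drug.map(lambda s: next(iter(s)))
    counts = {cls: int((effect == cls).sum()) for cls in ("loss", "gain", "unknown")}
    pairs = filtered.drop_duplicates(subset=["gene", "drug"])
    drugs_per_gene = pairs.groupby("gene")["drug"].nunique().to_dict()
    return WeightEffectSummary(
        counts=counts,
        drugs_per_gene=drugs_per_gene,
        n_drugs=int(len(per_drug)),
        n_genes=int(len(drugs_per_gene)),
    )


def summarize_side_effects(drugs: set[str], side_effects: pd.DataFrame) -> pd.DataFrame:
    """Distinct very-common side effects per drug.

    Drugs absent from the side-effect table get count 0 and
    ``has_data = False``.
    """
    bad = set(side_effects["frequency_class"]) - FREQUENCY_CLASSES
    if bad:
        raise ValidationError(f"unknown frequency classes: {sorted(bad)}")
    with_data = set(side_effects["drug"])
    vc = side_effects.loc[side_effects["frequency_class"] == "very common"]
    counts = vc.drop_duplicates(subset=["drug", "effect"]).groupby("drug")["effect"].size()
    rows = [
        (d, int(counts.get(d, 0)), d in with_data)
        for d in sorted(drugs)
    ]
    return pd.DataFrame(rows, columns=["drug", "very_common_count", "has_data"])


def flag_repurposing_candidates(
    filtered: pd.DataFrame,
    side_effect_counts: pd.DataFrame,
    ko_table: pd.DataFrame,
    max_effects: int = 10,
) -> pd.DataFrame:
    """Per-drug repurposing triage.

    A drug is flagged when its very-common side-effect burden is at most
    ``max_effects`` and at least one of its (filtered) target genes has an
    obesity-related knockout abnormality.  An empty knockout table flags
    nothing.
    """
    ko_genes = {
        normalize_symbol(g)
        for g in ko_table.loc[ko_table["obesity_phenotype"].astype(bool), "gene"]
    } if len(ko_table) else set()
    se = side_effect_counts.set_index("drug")["very_common_count"]
    rows = []
    for drug, grp in filtered.groupby("drug"):
        targets = {normalize_symbol(g) for g in grp["gene"]}
        n_se = int(se.get(drug, 0))
        ko_supported = bool(targets & ko_genes)
        rows.append(
            (
                drug,
                "|".join(sorted(targets)),
                n_se,
                ko_supported,
                bool(ko_supported and n_se <= max_effects),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["drug", "target_genes", "very_common_effect_count", "ko_supported", "flagged"],
    )
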