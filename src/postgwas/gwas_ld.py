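"""Significant-SNP selection, LD expansion and locus clustering.

The first stage of the workflow: keep genome-wide significant SNPs
(p < 1e-8 by default), expand each by linkage disequilibrium against a
reference panel (same chromosome, within +/- 500 kb, r^2 > 0.9), merge into
a non-redundant SNP list, and chain the list into genomic loci wherever
consecutive SNPs lie less than 500 kb apart.

r^2 is the squared Pearson correlation of unphased allele dosages (the
standard composite-LD estimator).  Samples with a missing dosage at either
variant are dropped pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    MissingVariantError,
    MonomorphicVariantError,
    ValidationError,
)
from .synthio import GenotypePanel

__all__ = [
    "select_significant_snps",
    "compute_ld_r2",
    "expand_ld_snps",
    "assemble_snp_list",
    "cluster_loci",
    "Locus",
]


@dataclass(frozen=True)
class Locus:
    """A distance-chained cluster of associated SNPs on one chromosome."""

    locus_id: int
    chrom: str
    start: int
    end: int
    member_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _check_pvalues(summary: pd.DataFrame) -> None:
    p = summary["pvalue"].to_numpy(dtype=float)
    bad = ~np.isfinite(p) | (p < 0.0) | (p > 1.0)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        vid = summary["variant_id"].iloc[idx]
        raise ValidationError(
            f"malformed p-value {summary['pvalue'].iloc[idx]!r} at row {idx} "
            f"(variant {vid})"
        )


def select_significant_snps(summary: pd.DataFrame, threshold: float = 1e-8) -> pd.DataFrame:
    """Rows with ``pvalue`` strictly below ``threshold``, order preserved."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    _check_pvalues(summary)
    return summary.loc[summary["pvalue"] < threshold].copy()


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def compute_ld_r2(panel: GenotypePanel, id_a: str, id_b: str) -> float:
    """Squared Pearson correlation of the two dosage vectors."""
    for vid in (id_a, id_b):
        if vid not in panel:
            raise MissingVariantError(f"variant {vid!r} not in panel")
    x, y = _pairwise_complete(panel.dosage_vector(id_a), panel.dosage_vector(id_b))
    if len(x) < 2:
        raise MonomorphicVariantError(
            f"fewer than two complete genotype pairs for ({id_a}, {id_b})"
        )
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        mono = id_a if vx == 0.0 else id_b
        raise MonomorphicVariantError(f"variant {mono!r} is monomorphic; LD undefined")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    r2 = (cov * cov) / (vx * vy)
    return float(min(max(r2, 0.0), 1.0))


def expand_ld_snps(
    significant: pd.DataFrame,
    panel: GenotypePanel,
    window_bp: int = 500_000,
    r2_min: float = 0.9,
) -> pd.DataFrame:
    """LD partners of each significant SNP.

    One row per (query, partner) with the partner on the same chromosome,
    ``0 < distance_bp <= window_bp`` and ``r2`` strictly greater than
    ``r2_min``.  Monomorphic partners are skipped (their LD with anything is
    undefined, hence they cannot satisfy the r^2 rule).
    """
    if window_bp < 1:
        raise ValidationError("window_bp must be positive")
    if not 0.0 <= r2_min <= 1.0:
        raise ValidationError("r2_min must be in [0, 1]")
    queries = list(significant["variant_id"])
    missing = sorted(q for q in queries if q not in panel)
    if missing:
        raise MissingVariantError(f"query SNPs absent from panel: {missing}")

    var = panel.variants
    chrom_arr = var["chrom"].to_numpy()
    pos_arr = var["pos"].to_numpy()
    id_arr = var["variant_id"].to_numpy()

    rows = []
    for q in queries:
        qi = panel.column(q)
        q_chrom, q_pos = chrom_arr[qi], pos_arr[qi]
        dist = np.abs(pos_arr - q_pos)
        cand = np.flatnonzero((chrom_arr == q_chrom) & (dist > 0) & (dist <= window_bp))
        if cand.size == 0:
            continue
        x = panel.dosages[:, qi].astype(float)
        if x.var() == 0.0:
            raise MonomorphicVariantError(f"query variant {q!r} is monomorphic")
        for j in cand:
            pid = id_arr[j]
            if pid == q:
                continue
            y = panel.dosages[:, j].astype(float)
            if y.var() == 0.0:
                continue
            cov = np.mean((x - x.mean()) * (y - y.mean()))
            r2 = float(cov * cov / (x.var() * y.var()))
            if r2 > r2_min:
                rows.append((q, pid, min(r2, 1.0), int(dist[j])))
    out = pd.DataFrame(rows, columns=["query_id", "partner_id", "r2", "distance_bp"])
    return out.sort_values(["query_id", "partner_id"], ignore_index=True)


def assemble_snp_list(
    significant: pd.DataFrame,
    expansion: pd.DataFrame,
    panel: GenotypePanel,
    summary: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Non-redundant union of significant SNPs and their LD partners.

    Significant records win over partner records on dedup (the provenance
    column says which rule admitted each SNP); output is sorted by
    (chrom, pos, variant_id).  ``summary`` fills partner p-values when
    available.
    """
    sig = significant[["variant_id", "chrom", "pos", "pvalue"]].copy()
    sig["provenance"] = "significant"
    partner_ids = [
        v for v in expansion["partner_id"].drop_duplicates() if v not in set(sig["variant_id"])
    ]
    part = panel.variants.set_index("variant_id").loc[partner_ids].reset_index()
    if summary is not None:
        pmap = summary.set_index("variant_id")["pvalue"]
        part["pvalue"] = part["variant_id"].map(pmap)
    else:
        part["pvalue"] = np.nan
    part["provenance"] = "ld_partner"
    out = pd.concat([sig, part[sig.columns]], ignore_index=True)
    out = out.drop_duplicates(subset="variant_id", keep="first")
    return out.sort_values(["chrom", "pos", "variant_id"], ignore_index=True)


def cluster_loci(snps: pd.DataFrame, max_gap_bp: int = 500_000) -> list[Locus]:
    """Chain SNPs into loci by single linkage on genomic distance.

    Per chromosome, consecutive SNPs (sorted by position) whose gap is
    strictly below ``max_gap_bp`` share a locus; a gap of ``max_gap_bp`` or
    more starts a new locus.  The loci partition the input.
    """
    if len(snps) == 0:
        raise ValidationError("cannot cluster an empty SNP table")
    if max_gap_bp < 1:
        raise ValidationError("max_gap_bp must be positive")
    loci: list[Locus] = []
    locus_id = 0
    ordered = snps.sort_values(["chrom", "pos", "variant_id"])
    for chrom, grp in ordered.groupby("chrom", sort=True):
        positions = grp["pos"].to_numpy()
        ids = grp["variant_id"].to_numpy()
        start_idx = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or positions[i] - positions[i - 1] >= max_gap_bp:
                locus_id += 1
                members = ids[start_idx:i]
                loci.append(
                    Locus(
                        locus_id=locus_id,
                        chrom=str(chrom),
                        start=int(positions[start_idx]),
                        end=int(positions[i - 1]),
                        member_ids=tuple(members.tolist()),
                    )
                )
                start_idx = i
    return loci
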