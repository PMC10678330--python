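"""Readers and writers for the pipeline's on-disk formats.

Tabular inputs are TSV with configurable column names; the genotype panel
travels as minimal VCF v4.2 with GT fields (read back through pysam);
gene-set libraries as GMT; loci additionally as BED (0-based half-open);
reports and the truth bundle as JSON.  Every writer's output is readable by
its paired reader with equality.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetLibrary, GeneSetTerm
from .exceptions import SchemaError
from .gwas_ld import Locus
from .synthio import GenotypePanel, TruthBundle

__all__ = [
    "read_table",
    "read_summary_stats",
    "write_vcf",
    "read_vcf",
    "read_gmt",
    "write_gmt",
    "write_loci",
    "write_truth",
    "read_truth",
    "write_json",
    "read_json",
    "read_string_edges",
    "TABLE_SCHEMAS",
]

#: Mandatory columns per logical table.
TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "summary": ("variant_id", "chrom", "pos", "pvalue"),
    "regulatory": ("variant_id", "category"),
    "eqtl_links": ("variant_id", "gene"),
    "tissue_deg": ("tissue", "gene", "adj_p", "direction"),
    "twas": ("gene", "phenotype", "tissue"),
    "ppi_edges": ("protein1", "protein2", "score"),
    "drug_gene": ("drug", "gene", "approved", "sources", "pmid_count", "weight_effect"),
    "side_effects": ("drug", "effect", "frequency_class"),
    "knockouts": ("gene", "obesity_phenotype"),
    "ld_expansion": ("query_id", "partner_id", "r2", "distance_bp"),
    "snp_list": ("variant_id", "chrom", "pos", "pvalue", "provenance"),
}


def read_table(
    path: str | Path, schema: str, columns: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a TSV and validate it against a named schema.

    ``columns`` maps file column names to schema names (e.g. ``{"SNP":
    "variant_id"}``).  Missing mandatory columns raise :class:`SchemaError`
    naming the column.
    """
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(TABLE_SCHEMAS)}")
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # noqa: BLE001 - reported with file context
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    if columns:
        df = df.rename(columns=columns)
    for col in TABLE_SCHEMAS[schema]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r} for schema {schema!r}")
    if schema == "knockouts":
        df["obesity_phenotype"] = df["obesity_phenotype"].astype(bool)
    if schema == "drug_gene":
        df["approved"] = df["approved"].astype(bool)
    return df


def read_summary_stats(
    path: str | Path, columns: dict[str, str] | None = None
) -> pd.DataFrame:
    """GWAS summary statistics; default columns SNP/CHR/POS/P are remapped."""
    default = {"SNP": "variant_id", "CHR": "chrom", "POS": "pos", "P": "pvalue"}
    return read_table(path, "summary", columns={**default, **(columns or {})})


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_string_edges(path: str | Path) -> pd.DataFrame:
    """STRING-style edge export; integer 0-1000 combined scores are scaled
    to [0, 1]."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "combined_score" in df.columns and "score" not in df.columns:
        df = df.rename(columns={"combined_score": "score"})
    for col in ("protein1", "protein2", "score"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r} for STRING edges")
    if df["score"].max() > 1.0:
        df["score"] = df["score"] / 1000.0
    return df


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Minimal VCF v4.2 with unphased GT fields encoding the dosages."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.variants["chrom"]):
            max_pos = int(panel.variants.loc[panel.variants["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j, row in enumerate(panel.variants.itertuples(index=False)):
            gts = "\t".join(gt_map[int(d)] for d in panel.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a GT-only VCF back into a genotype panel (alt-allele dosages)."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        rows = []
        cols = []
        for rec in vf:
            rows.append((rec.id, str(rec.chrom), int(rec.pos)))
            dos = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    raise SchemaError(f"{path}: missing genotype for {rec.id}/{s}")
                dos[i] = sum(1 for a in gt if a != 0)
            cols.append(dos)
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"])
    dosages = np.column_stack(cols) if cols else np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypePanel(sample_ids=samples, variants=variants, dosages=dosages)


# --------------------------------------------------------------------------
# GMT
# --------------------------------------------------------------------------


def write_gmt(lib: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(lib.terms):
            t = lib.terms[tid]
            fh.write("\t".join([t.term_id, t.name, *sorted(t.genes)]) + "\n")


def read_gmt(path: str | Path, universe: frozenset[str] | None = None) -> GeneSetLibrary:
    terms: dict[str, GeneSetTerm] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{lineno}: GMT line needs term, description, members")
            tid, name, *genes = parts
            terms[tid] = GeneSetTerm(tid, name, frozenset(genes))
    return GeneSetLibrary(terms=terms, universe=universe)


# --------------------------------------------------------------------------
# loci, truth, reports
# --------------------------------------------------------------------------


def write_loci(loci: list[Locus], tsv_path: str | Path, bed_path: str | Path) -> None:
    """Loci as 1-based inclusive TSV and 0-based half-open BED."""
    rows = [
        (l.locus_id, l.chrom, l.start, l.end, l.size, ",".join(l.member_ids)) for l in loci
    ]
    pd.DataFrame(
        rows, columns=["locus_id", "chrom", "start", "end", "n_snps", "member_ids"]
    ).to_csv(tsv_path, sep="\t", index=False)
    with open(bed_path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start - 1}\t{l.end}\tlocus_{l.locus_id}\t{l.size}\n")


def write_truth(truth: TruthBundle, path: str | Path) -> None:
    write_json(
        {
            "true_genes": sorted(truth.true_genes),
            "causal_snps": sorted(truth.causal_snps),
            "planted_hubs": sorted(truth.planted_hubs),
        },
        path,
    )


def read_truth(path: str | Path) -> TruthBundle:
    data = read_json(path)
    return TruthBundle(
        true_genes=frozenset(data["true_genes"]),
        causal_snps=frozenset(data["causal_snps"]),
        planted_hubs=frozenset(data["planted_hubs"]),
    )


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_Encoder)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
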