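"""Validated TSV readers/writers for every table the pipeline exchanges.

All tables are plain tab-separated text. Tidy tables are validated against a
named schema (required columns, dtypes); column order on input is free and
canonicalized on read. The genotype matrix is a wide table (rows = strains,
columns = markers named chrom:binstart, cells = A/B) with its own reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ALLELE_A, ALLELE_B, ExpressionSet, GeneticMap

#: schema id -> {column: kind}, kind in {str, int, float, bool}
SCHEMAS: dict[str, dict[str, type]] = {
    "snp_calls": {"strain": str, "chrom": str, "pos": int},
    "design": {"sample": str, "treatment": str, "strain": str},
    "gene_location": {"spot": str, "gene": str, "chrom": str,
                      "start": int, "end": int},
    "annotation": {"gene": str, "category": str, "database": str},
    "de": {"spot": str, "comparison": str, "effect": float, "p": float,
           "p_adj": float, "neglogp": float, "significant": bool},
    "eqtl": {"spot": str, "treatment": str, "qtl_type": str, "chrom": str,
             "marker": str, "pos": int, "ci_left": int, "ci_right": int,
             "neglogp": float, "effect": float, "r2": float, "gene": str,
             "gene_chrom": str, "gene_start": int, "gene_end": int},
    "transband": {"treatment": str, "chrom": str, "start": int, "end": int,
                  "spots": int, "genes": int, "rate": float, "k_min": int,
                  "p": float},
    "power": {"marker": str, "chrom": str, "pos": int,
              "variance_explained": float, "effect": float, "reps": int,
              "detected": int, "undetected": int, "false_positives": int,
              "effect_ratio_median": float, "location_error_median": float},
    "enrichment": {"database": str, "category": str, "category_size": int,
                   "overlap": int, "p": float, "p_bonferroni": float},
}

_DTYPES = {str: "string", int: "int64", float: "float64", bool: "boolean"}


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a tidy table, schema-checked, in canonical column order."""
    cols = SCHEMAS[schema]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{schema} table missing columns {sorted(missing)}")
    df[list(cols)].to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a tidy table; column order is canonicalized.

    Errors cite the 1-based data row of the first offending record.
    """
    cols = SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", dtype="string")
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: {schema} table missing columns "
                         f"{sorted(missing)}")
    df = df[list(cols)]
    out = {}
    for col, kind in cols.items():
        s = df[col]
        if kind in (int, float):
            conv = pd.to_numeric(s, errors="coerce")
            bad = conv.isna() & s.notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0]) + 1
                raise ValueError(f"{path}: non-numeric value "
                                 f"{s.iloc[row - 1]!r} in column {col!r} "
                                 f"at row {row}")
            out[col] = conv.astype(_DTYPES[kind])
        elif kind is bool:
            out[col] = s.str.lower().map({"true": True, "false": False}) \
                .astype("boolean")
        else:
            out[col] = s
    return pd.DataFrame(out)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    """Genotype matrix TSV: rows = strains, columns = chrom:binstart, A/B."""
    labels = gmap.genotypes.replace({ALLELE_A: "A", ALLELE_B: "B"})
    labels.index.name = "strain"
    labels.to_csv(path, sep="\t")


def read_genetic_map(path: str | Path, provenance: str = "constructed"
                     ) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", index_col="strain", dtype="string")
    cols = {}
    for col in df.columns:
        vals = df[col]
        bad = ~vals.isin(["A", "B"])
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(f"{path}: allele {vals.iloc[row - 1]!r} outside "
                             f"{{A,B}} in column {col!r} at row {row}")
        cols[col] = (vals == "A").astype(np.int8)
    geno = pd.DataFrame(cols, index=df.index.astype(str))
    rows = []
    for m in geno.columns:
        chrom, pos = m.rsplit(":", 1)
        rows.append((m, chrom, int(pos)))
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos"])
    return GeneticMap(markers, geno, provenance=provenance)


def write_marker_bed(gmap: GeneticMap, path: str | Path) -> None:
    """Markers as BED intervals (chrom, binstart, binstart + bin, marker id)."""
    bed = gmap.markers.assign(end=gmap.markers["pos"] + gmap.bin_size)
    bed[["chrom", "pos", "end", "marker"]].to_csv(path, sep="\t", index=False,
                                                  header=False)


def write_expression(expr: ExpressionSet, prefix: str | Path) -> None:
    """Expression matrix + design + gene-location tables under a prefix."""
    prefix = Path(prefix)
    vals = expr.values.copy()
    vals.index.name = "spot"
    vals.to_csv(f"{prefix}_expression.tsv", sep="\t")
    write_table(expr.design, f"{prefix}_design.tsv", "design")
    write_table(expr.annotation, f"{prefix}_genes.tsv", "gene_location")


def read_expression(prefix: str | Path) -> ExpressionSet:
    prefix = Path(prefix)
    vals = pd.read_csv(f"{prefix}_expression.tsv", sep="\t", index_col="spot")
    design = read_table(f"{prefix}_design.tsv", "design")
    ann = read_table(f"{prefix}_genes.tsv", "gene_location")
    return ExpressionSet(vals, design, ann)
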