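"""Hypergeometric gene-set enrichment with size filters and Bonferroni
correction, and the chi-squared polymorphism-frequency comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def hypergeometric_enrichment(gene_set: set, annotation: pd.DataFrame,
                              universe: set | None = None,
                              min_category: int = 3, min_overlap: int = 2,
                              bonferroni_scope: str = "database"
                              ) -> pd.DataFrame:
    """Overrepresentation of annotation categories in a gene set.

    Only categories with size > ``min_category`` and overlap > ``min_overlap``
    (strict inequalities) are tested, by gene name. The universe defaults to
    the genes in the annotation table; Bonferroni correction is applied per
    database (``bonferroni_scope="all"`` pools every tested category).
    Columns: database, category, category_size, overlap, p, p_bonferroni.
    """
    if annotation.duplicated(["gene", "category"]).any():
        annotation = annotation.drop_duplicates(["gene", "category"])
    if universe is None:
        universe = set(annotation["gene"])
    gene_set = set(gene_set) & universe
    if not gene_set:
        return pd.DataFrame(columns=["database", "category", "category_size",
                                     "overlap", "p", "p_bonferroni"])
    ann = annotation[annotation["gene"].isin(universe)]
    M, N = len(universe), len(gene_set)
    rows = []
    for (db, cat), grp in ann.groupby(["database", "category"]):
        members = set(grp["gene"])
        K = len(members)
        k = len(members & gene_set)
        if K > min_category and k > min_overlap:
            p = float(stats.hypergeom.sf(k - 1, M, K, N))
            rows.append((db, cat, K, k, p))
    out = pd.DataFrame(rows, columns=["database", "category", "category_size",
                                      "overlap", "p"])
    if out.empty:
        out["p_bonferroni"] = pd.Series(dtype=float)
        return out
    if bonferroni_scope == "database":
        out["p_bonferroni"] = out.groupby("database")["p"].transform(
            lambda s: np.minimum(1.0, s * len(s)))
    elif bonferroni_scope == "all":
        out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    else:
        raise ValueError(f"unknown bonferroni_scope {bonferroni_scope!r}")
    return out.sort_values("p").reset_index(drop=True)


def polymorphism_association(table: pd.DataFrame | np.ndarray
                             ) -> tuple[float, float, int]:
    """Pearson chi-squared test (no continuity correction) on a groups x
    categories contingency table of gene counts. Returns (statistic, p, df).
    """
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must hold non-negative integer counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be positive")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p), int(df)
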