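"""Treatment effects on expression: pairwise differential expression with
Benjamini-Yekutieli control, Venn-group assignment of DE genes, the
log2-ratio transform, PCA of treatment responses, and transcriptional-ruler
age estimation."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionSet


@dataclass
class DEResult:
    """Per-spot pairwise differential-expression tests, BY-adjusted.

    ``table`` columns: spot, comparison ("a_vs_b"), effect (mean(a) - mean(b),
    log2 units), p, p_adj, neglogp, significant. ``thresholds`` maps each
    comparison to its realized -log10(p) cutoff (the smallest significant
    spot's raw score), NaN when nothing is significant.
    """

    table: pd.DataFrame
    fdr: float
    thresholds: dict[str, float] = field(default_factory=dict)


def pairwise_de(expr: ExpressionSet, fdr: float = 0.05,
                treatments: list[str] | None = None) -> DEResult:
    """Two-group equal-variance tests per spot for every treatment pair.

    The per-spot model "expression ~ treatment" with two levels is the
    classic pooled-variance two-sample t test (F with 1 and n-2 df);
    genotype is ignored. P values are Benjamini-Yekutieli adjusted across
    spots within each comparison.
    """
    if treatments is None:
        treatments = list(dict.fromkeys(expr.design["treatment"]))
    groups = {}
    for t in treatments:
        cols = expr.samples_for(t)
        if len(cols) < 2:
            raise ValueError(f"treatment {t!r} has < 2 samples")
        groups[t] = expr.values[cols].to_numpy()

    frames, thresholds = [], {}
    for a, b in combinations(treatments, 2):
        res = stats.ttest_ind(groups[a], groups[b], axis=1, equal_var=True)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)  # constant spots
        rej, p_adj, *_ = multipletests(p, alpha=fdr, method="fdr_by")
        comp = f"{a}_vs_{b}"
        neglogp = -np.log10(np.maximum(p, np.finfo(float).tiny))
        frames.append(pd.DataFrame({
            "spot": expr.spots, "comparison": comp,
            "effect": groups[a].mean(axis=1) - groups[b].mean(axis=1),
            "p": p, "p_adj": p_adj, "neglogp": neglogp, "significant": rej}))
        thresholds[comp] = float(neglogp[rej].min()) if rej.any() else float("nan")
    return DEResult(pd.concat(frames, ignore_index=True), fdr, thresholds)


def venn_groups(de: DEResult, annotation: pd.DataFrame,
                collapse: str = "any") -> pd.DataFrame:
    """Assign every ever-significant gene to one of the 7 significance
    patterns over the three pairwise comparisons.

    Spot-level significance is collapsed to genes by ``collapse``: "any"
    (default; a gene is significant if any of its spots is), "all", or
    "best" (only the spot with the smallest adjusted p counts). A gene
    significant in the two comparisons involving one treatment but not the
    third is labelled "<treatment>-specific"; significance everywhere is
    "all"; a single significant comparison is labelled "<comparison>-only".
    """
    comps = sorted(de.table["comparison"].unique())
    if len(comps) != 3:
        raise ValueError("venn_groups expects exactly three comparisons")
    spot_gene = annotation.set_index("spot")["gene"]
    tab = de.table.assign(gene=de.table["spot"].map(spot_gene))

    if collapse == "any":
        sig = tab.groupby(["gene", "comparison"])["significant"].any()
    elif collapse == "all":
        sig = tab.groupby(["gene", "comparison"])["significant"].all()
    elif collapse == "best":
        best = tab.sort_values("p_adj").drop_duplicates(["gene", "comparison"])
        sig = best.set_index(["gene", "comparison"])["significant"]
    else:
        raise ValueError(f"unknown collapse rule {collapse!r}")
    wide = sig.unstack("comparison").fillna(False)

    treatments = sorted({t for c in comps for t in c.split("_vs_")})
    rows = []
    for gene, flags in wide.iterrows():
        pattern = frozenset(c for c in comps if flags[c])
        if not pattern:
            continue
        if len(pattern) == 3:
            label = "all"
        elif len(pattern) == 1:
            label = f"{next(iter(pattern))}-only"
        else:
            absent = next(c for c in comps if c not in pattern)
            spared = [t for t in absent.split("_vs_")]
            specific = [t for t in treatments if t not in spared]
            label = f"{specific[0]}-specific"
        rows.append((gene, label, ",".join(sorted(pattern))))
    return pd.DataFrame(rows, columns=["gene", "category", "pattern"])


def log2_ratio_transform(expr: ExpressionSet) -> pd.DataFrame:
    """Relative expression R_ij = log2(y_ij / mean_j(y_ij)) on the raw
    (de-logged) intensity scale, mean taken over all samples of all
    treatments. The per-spot mean of 2**R is exactly 1."""
    y = np.power(2.0, expr.values.to_numpy())
    if (y <= 0).any():
        raise ValueError("nonpositive intensity after de-logging")
    ratio = y / y.mean(axis=1, keepdims=True)
    return pd.DataFrame(np.log2(ratio), index=expr.values.index,
                        columns=expr.values.columns)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x axes
    loadings: pd.DataFrame        # spots x axes
    variance_fraction: np.ndarray


def pca_treatments(ratio: pd.DataFrame, n_axes: int = 6) -> PCAResult:
    """Principal components of samples in log2-ratio space (top axes only)."""
    n_samples = ratio.shape[1]
    k = min(n_axes, n_samples - 1, ratio.shape[0])
    if k < n_axes:
        import warnings
        warnings.warn(f"only {k} axes available for {n_samples} samples")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(ratio.to_numpy().T)
    axes = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=ratio.columns, columns=axes),
        loadings=pd.DataFrame(pca.components_.T, index=ratio.index, columns=axes),
        variance_fraction=pca.explained_variance_ratio_)


def estimate_age(expr: ExpressionSet, ruler: pd.DataFrame,
                 anchor: float = 48.0, anchor_group: str = "control") -> pd.Series:
    """Developmental age per sample from ruler genes with known positive
    slopes (log2 units/hour).

    Each sample's raw score is the slope-normalized mean of its ruler-gene
    expression; ages are the scores shifted so the anchor treatment's mean
    is exactly ``anchor`` hours. Only relative ages are meaningful.
    """
    ruler = ruler[ruler["spot"].isin(expr.spots)]
    if ruler.empty:
        raise ValueError("no ruler genes found in the expression set")
    if (ruler["slope"] <= 0).any():
        raise ValueError("ruler slopes must be positive")
    sub = expr.values.loc[ruler["spot"]]
    score = (sub.to_numpy() / ruler["slope"].to_numpy()[:, None]).mean(axis=0)
    score = pd.Series(score, index=expr.values.columns)
    anchor_samples = expr.samples_for(anchor_group)
    if not anchor_samples:
        raise ValueError(f"no samples in anchor group {anchor_group!r}")
    return score + (anchor - score[anchor_samples].mean())
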