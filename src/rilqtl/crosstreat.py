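"""Cross-treatment comparison of eQTL: gene-level overlap with a permutation
false-overlap estimate, same-marker lookup, effect correlations, genotypic
plasticity (sign flips), power-versus-absence attribution for
single-treatment trans eQTL, and trans-band gene-overlap tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EQTLProfiles, GeneticMap
from .mapping import detect_peaks, permute_within_spots, scan
from .power import analytic_power


@dataclass
class OverlapReport:
    """Gene-level eQTL presence across treatments for one class (cis/trans)."""

    qtl_class: str
    presence: pd.DataFrame            # gene x treatment booleans
    venn: dict[frozenset, int]        # treatment-subset -> gene count
    pair_shared: dict[tuple[str, str], int] = field(default_factory=dict)
    false_overlap: dict[tuple[str, str], float] = field(default_factory=dict)


def overlap_by_gene(peaks_by_treatment: dict[str, pd.DataFrame],
                    qtl_class: str) -> OverlapReport:
    """Which genes carry an eQTL of a class in which treatments (locus
    ignored): presence matrix, Venn counts over the nonempty treatment
    subsets, and pairwise shared-gene counts."""
    gene_sets = {t: set(p.loc[p["qtl_type"] == qtl_class, "gene"])
                 for t, p in peaks_by_treatment.items()}
    treatments = list(peaks_by_treatment)
    genes = sorted(set().union(*gene_sets.values()))
    presence = pd.DataFrame({t: [g in gene_sets[t] for g in genes]
                             for t in treatments}, index=genes)
    venn: dict[frozenset, int] = {}
    for g in genes:
        key = frozenset(t for t in treatments if g in gene_sets[t])
        venn[key] = venn.get(key, 0) + 1
    pair_shared = {(a, b): len(gene_sets[a] & gene_sets[b])
                   for a, b in combinations(treatments, 2)}
    return OverlapReport(qtl_class, presence, venn, pair_shared)


def permutation_false_overlap(expr_by_strain: dict[str, pd.DataFrame],
                              gmap: GeneticMap, annotation: pd.DataFrame,
                              threshold: float, n_perm: int = 10,
                              seed: int = 0) -> dict[tuple[str, str], float]:
    """Chance level of the gene-overlap comparison: repeat it on per-spot
    permuted data at the fixed threshold and average pairwise overlap counts."""
    rng = np.random.default_rng(seed)
    spot_gene = annotation.set_index("spot")["gene"]
    treatments = list(expr_by_strain)
    totals = {pair: 0.0 for pair in combinations(treatments, 2)}
    for _ in range(n_perm):
        gene_sets = {}
        for t, mat in expr_by_strain.items():
            perm = pd.DataFrame(permute_within_spots(mat.to_numpy(), rng),
                                index=mat.index, columns=mat.columns)
            pk = detect_peaks(scan(perm, gmap, t), threshold)
            gene_sets[t] = set(pk["spot"].map(spot_gene))
        for a, b in totals:
            totals[(a, b)] += len(gene_sets[a] & gene_sets[b])
    return {pair: v / n_perm for pair, v in totals.items()}


def overlap_at_marker(peaks: pd.DataFrame,
                      profiles_by_treatment: dict[str, EQTLProfiles]
                      ) -> pd.DataFrame:
    """Same-marker lookup: for every peak, look up -log10(p) and effect at the
    identical marker in every other treatment's scan."""
    rows = []
    for r in peaks.itertuples():
        rec = {"spot": r.spot, "gene": getattr(r, "gene", None),
               "treatment": r.treatment, "marker": r.marker,
               "chrom": r.chrom, "pos": r.pos,
               "qtl_type": getattr(r, "qtl_type", None)}
        for t, prof in profiles_by_treatment.items():
            if r.marker not in prof.neglogp.columns:
                raise KeyError(f"marker {r.marker} absent from {t} profiles")
            rec[f"neglogp_{t}"] = float(prof.neglogp.at[r.spot, r.marker])
            rec[f"effect_{t}"] = float(prof.effect.at[r.spot, r.marker])
        rows.append(rec)
    return pd.DataFrame(rows)


def effect_correlation(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame,
                       qtl_class: str) -> tuple[float, int]:
    """Pearson r of allelic effects over genes sharing an eQTL of a class in
    two treatments (best spot by significance per gene). Undefined (NaN)
    below 3 shared genes."""
    def best(p):
        sub = p[p["qtl_type"] == qtl_class].sort_values("neglogp",
                                                        ascending=False)
        return sub.drop_duplicates("gene").set_index("gene")["effect"]
    ea, eb = best(peaks_a), best(peaks_b)
    shared = ea.index.intersection(eb.index)
    if len(shared) < 3:
        return float("nan"), len(shared)
    r, _ = stats.pearsonr(ea[shared], eb[shared])
    return float(r), len(shared)


def genotypic_plasticity(marker_lookup: pd.DataFrame, threshold: float,
                         treatments: list[str]) -> pd.DataFrame:
    """Genes whose allelic effect flips sign between treatments while
    significant in both (cryptic variation acting in opposite directions)."""
    rows = []
    for r in marker_lookup.itertuples():
        sig = [(t, getattr(r, f"effect_{t}")) for t in treatments
               if getattr(r, f"neglogp_{t}") >= threshold]
        signs = {np.sign(e) for _, e in sig if e != 0}
        if len(sig) >= 2 and len(signs) > 1:
            rows.append({"spot": r.spot, "gene": r.gene, "marker": r.marker,
                         **{f"effect_{t}": getattr(r, f"effect_{t}")
                            for t in treatments}})
    return pd.DataFrame(rows).drop_duplicates(subset=["gene", "marker"]) \
        if rows else pd.DataFrame(columns=["spot", "gene", "marker"])


def power_vs_absence(single_trans_lookup: pd.DataFrame, n: int,
                     threshold: float, treatments: list[str],
                     noise_sd: float = 1.0) -> dict:
    """How much of trans-eQTL treatment specificity is mere detection power?

    For every trans eQTL seen in exactly one treatment, the observed allelic
    effect at the same marker in each other treatment is converted to a
    variance-explained fraction (balanced 0/1 coding: v = (b^2/4) /
    (b^2/4 + sd^2)) and run through the analytic power curve at the
    genome-wide threshold. The mean of those detection probabilities is the
    eQTL's chance of being attributable to limited power; their sum over
    eQTL, divided by the count, is the attributable fraction, the remainder
    being labelled cryptic (truly absent).
    """
    if single_trans_lookup.empty:
        return {"attributable_fraction": float("nan"),
                "cryptic_fraction": float("nan"), "n": 0, "per_eqtl": None}
    probs = []
    for r in single_trans_lookup.itertuples():
        others = [t for t in treatments if t != r.treatment]
        p_each = []
        for t in others:
            b = getattr(r, f"effect_{t}")
            if not np.isfinite(b):
                continue
            v = (b * b / 4.0) / (b * b / 4.0 + noise_sd ** 2)
            p_each.append(analytic_power(v, n, threshold) if v > 0 else 0.0)
        probs.append(float(np.mean(p_each)) if p_each else 0.0)
    probs = np.asarray(probs)
    frac = float(probs.sum() / len(probs))
    per = single_trans_lookup[["spot", "gene", "treatment", "marker"]].copy()
    per["p_attributable"] = probs
    return {"attributable_fraction": frac, "cryptic_fraction": 1.0 - frac,
            "n": len(probs), "per_eqtl": per}


def transband_overlap_test(genes_a: set, genes_b: set, universe: int) -> float:
    """Upper-tail hypergeometric p for the observed overlap between the gene
    sets of two trans-bands, given the number of assayed genes."""
    k = len(genes_a & genes_b)
    if len(genes_a) > universe or len(genes_b) > universe:
        raise ValueError("set larger than universe")
    if k > min(len(genes_a), len(genes_b)):
        raise ValueError("overlap exceeds smaller set")
    return float(stats.hypergeom.sf(k - 1, universe, len(genes_a), len(genes_b)))
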