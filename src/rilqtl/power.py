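"""QTL detection power: effect-size/variance calibration, a closed-form
noncentral-F power oracle, and the per-marker simulation study.

With balanced 0/1 genotype coding and noise sd sigma, an additive effect b
explains v = (b^2/4) / (b^2/4 + sigma^2) of trait variance, so a peak of
size 1 (sigma = 1) corresponds to 20% explained variation, and
b = 2 * sigma * sqrt(v / (1 - v)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import CI_DROP
from .containers import GeneticMap
from .mapping import _scan_arrays, detect_peaks, scan


def effect_for_variance(v: float, noise_sd: float = 1.0) -> float:
    """Allelic effect (expression units) explaining fraction ``v`` of
    variance under balanced 0/1 coding."""
    if not 0 <= v < 1:
        raise ValueError("variance fraction must lie in [0, 1)")
    return 2.0 * noise_sd * np.sqrt(v / (1.0 - v))


def analytic_power(v: float, n: int, threshold: float,
                   p1: float = 0.5) -> float:
    """Detection probability at the causal marker for a QTL explaining
    fraction ``v`` of variance in ``n`` strains at a genome-wide
    -log10(p) ``threshold``.

    The test statistic follows a noncentral F(1, n-2) with noncentrality
    n * v / (1 - v) for balanced groups; for allele frequency ``p1`` the
    noncentrality is b^2 * p1 * (1 - p1) * n with b sized for v at balance.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if v <= 0:
        return float(10.0 ** -threshold)
    crit = stats.f.isf(10.0 ** -threshold, 1, n - 2)
    b = effect_for_variance(v)
    lam = b * b * p1 * (1 - p1) * n
    return float(stats.ncf.sf(crit, 1, n - 2, lam))


def run_power_simulation(gmap: GeneticMap, levels=None, reps: int = 10,
                         threshold: float = 3.9,
                         seed: int | np.random.Generator = 0,
                         markers: list[str] | None = None,
                         detection: str = "ci",
                         noise_sd: float = 1.0) -> pd.DataFrame:
    """Simulate QTL of known size on real map markers and score the scan.

    For every (marker, variance level): ``reps`` traits are drawn as
    b * genotype + N(0, noise_sd^2) and scanned genome-wide. A simulated QTL
    is *detected* when a peak clears ``threshold`` and — under the default
    ``detection="ci"`` rule — its 1.5-drop confidence interval covers the
    simulated marker (``detection="chrom"`` only requires the right
    chromosome); peaks elsewhere are false positives. Effect-estimate ratio
    (mapped/simulated) and location error (bp) are recorded per detection.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if levels is None:
        levels = [round(0.20 + 0.05 * i, 2) for i in range(13)]
    marker_tab = gmap.markers.set_index("marker")
    if markers is None:
        markers = list(gmap.markers["marker"])
    G = gmap.genotypes

    rows = []
    for m in markers:
        g = G[m].to_numpy(dtype=float)
        chrom = marker_tab.at[m, "chrom"]
        pos = int(marker_tab.at[m, "pos"])
        for v in levels:
            b = effect_for_variance(v, noise_sd)
            traits = b * g[None, :] + rng.normal(0.0, noise_sd,
                                                 (reps, g.size))
            mat = pd.DataFrame(traits, index=[f"rep{k}" for k in range(reps)],
                               columns=G.index)
            peaks = detect_peaks(scan(mat, gmap), threshold)
            detected = 0
            false_pos = 0
            ratios, loc_err = [], []
            for rep in mat.index:
                sub = peaks[peaks["spot"] == rep]
                hit = False
                for r in sub.itertuples():
                    covers = (r.chrom == chrom and
                              (detection == "chrom"
                               or r.ci_left <= pos <= r.ci_right))
                    if covers and not hit:
                        hit = True
                        ratios.append(r.effect / b if b else np.nan)
                        loc_err.append(abs(r.pos - pos))
                    else:
                        false_pos += 1
                detected += hit
            rows.append((m, chrom, pos, v, b, reps, detected, reps - detected,
                         false_pos,
                         float(np.median(ratios)) if ratios else np.nan,
                         float(np.median(loc_err)) if loc_err else np.nan))
    return pd.DataFrame(rows, columns=[
        "marker", "chrom", "pos", "variance_explained", "effect", "reps",
        "detected", "undetected", "false_positives", "effect_ratio_median",
        "location_error_median"])


def causal_marker_power(v: float, n: int, threshold: float, n_traits: int,
                        rng: np.random.Generator,
                        noise_sd: float = 1.0) -> float:
    """Empirical detection rate at the causal marker itself: fraction of
    ``n_traits`` simulated traits whose two-group test at a balanced binary
    marker exceeds the -log10(p) threshold."""
    g = np.zeros(n)
    g[: n // 2] = 1.0
    b = effect_for_variance(v, noise_sd)
    traits = b * g[None, :] + rng.normal(0.0, noise_sd, (n_traits, n))
    neglogp, _ = _scan_arrays(traits, g[:, None])
    return float((neglogp[:, 0] > threshold).mean())
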