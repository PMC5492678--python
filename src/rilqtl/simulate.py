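"""Synthetic two-parent RIL cross with a fully known expression architecture.

Generates (1) recombinant inbred genotypes as parental mosaics, (2) the
per-strain SNP-call table a sequencing pipeline would emit (SNPs only inside
parent-B blocks, optional isolated false-positive bins), and (3) per-treatment
log2 expression matrices with planted cis effects (active in every
treatment), trans effects (largely single-treatment), trans-band hubs,
developmental-age "ruler" genes and Gaussian noise. Every planted effect is
recorded in a :class:`~rilqtl.containers.PlantedTruth` so downstream stages
can be tested against ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BIN_SIZE, SimConfig
from .containers import (ALLELE_A, ALLELE_B, ExpressionSet, GeneticMap,
                         PlantedTruth, marker_id)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class RILGenotypes:
    """Mosaic structure of every simulated strain plus the truth map.

    ``breakpoints[strain][chrom]`` is a sorted array of crossover positions
    (bp, snapped to 10 kb bin starts); ``start_allele[strain][chrom]`` is the
    founder allele of the leftmost segment.
    """

    breakpoints: dict[str, dict[str, np.ndarray]]
    start_allele: dict[str, dict[str, int]]
    truth_map: GeneticMap
    chromosomes: list[tuple[str, int]]

    def allele_at(self, strain: str, chrom: str, pos: float) -> int:
        bp = self.breakpoints[strain][chrom]
        k = int(np.searchsorted(bp, pos, side="right"))
        return self.start_allele[strain][chrom] if k % 2 == 0 else \
            1 - self.start_allele[strain][chrom]

    def segments(self, strain: str, chrom: str, length: int):
        """Yield (start, end, allele) half-open segments tiling the chromosome."""
        bp = self.breakpoints[strain][chrom]
        bounds = np.concatenate([[0], bp, [length]])
        allele = self.start_allele[strain][chrom]
        for s, e in zip(bounds[:-1], bounds[1:]):
            yield int(s), int(e), allele
            allele = 1 - allele


def simulate_ril_genotypes(config: SimConfig,
                           rng: np.random.Generator | None = None) -> RILGenotypes:
    """Draw parental mosaics for every strain and assemble the truth map.

    Crossover counts are Poisson per chromosome, placement uniform; with
    minimum-spacing enforcement on, breakpoints closer than the spacing (in
    10 kb bins) to each other or to a chromosome end are dropped, mirroring
    the resolution limit of the density-based map builder. The truth marker
    set is the union over strains of breakpoint bins.
    """
    config.validate()
    rng = rng or substream(config.seed, "genotypes")
    strains = [f"RIL{i:03d}" for i in range(config.n_strains)]
    spacing = config.min_breakpoint_spacing_bins * BIN_SIZE

    breakpoints: dict[str, dict[str, np.ndarray]] = {}
    start_allele: dict[str, dict[str, int]] = {}
    marker_bins: dict[str, set[int]] = {name: set() for name, _ in config.chromosomes}

    for strain in strains:
        breakpoints[strain], start_allele[strain] = {}, {}
        for chrom, length in config.chromosomes:
            if length <= 0:
                raise ValueError(f"zero-length chromosome {chrom!r}")
            n_xo = rng.poisson(config.mean_crossovers_per_chrom)
            pos = np.sort(rng.uniform(0, length, n_xo))
            pos = (pos // BIN_SIZE).astype(np.int64) * BIN_SIZE  # snap to bin start
            if spacing > 0:
                kept: list[int] = []
                for p in pos:
                    if p < spacing + BIN_SIZE or p > length - spacing - BIN_SIZE:
                        continue  # too close to a telomere to ever be recovered
                    if kept and p - kept[-1] <= spacing:
                        continue
                    kept.append(int(p))
                pos = np.array(kept, dtype=np.int64)
            else:
                pos = np.unique(pos)
            breakpoints[strain][chrom] = pos
            start_allele[strain][chrom] = int(rng.integers(2))
            marker_bins[chrom].update(int(p // BIN_SIZE) for p in pos)

    rows = []
    for chrom, _ in config.chromosomes:
        for b in sorted(marker_bins[chrom]):
            rows.append((marker_id(chrom, b * BIN_SIZE), chrom, b * BIN_SIZE))
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos"])

    geno = np.zeros((len(strains), len(markers)), dtype=np.int8)
    genos = RILGenotypes(breakpoints, start_allele,
                         truth_map=None, chromosomes=config.chromosomes)  # type: ignore
    for i, strain in enumerate(strains):
        for j, (chrom, p) in enumerate(zip(markers["chrom"], markers["pos"])):
            geno[i, j] = genos.allele_at(strain, chrom, p)  # breakpoint bin -> new allele

    gmap = GeneticMap(markers,
                      pd.DataFrame(geno, index=strains, columns=list(markers["marker"])),
                      provenance="truth")
    genos.truth_map = gmap
    return genos


def simulate_snp_calls(genos: RILGenotypes, config: SimConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit the per-strain SNP-call table implied by the mosaics.

    SNPs fall only inside parent-B (CB4856-like) blocks at the configured
    density. With ``snp_noise_rate > 0``, isolated false-positive bins are
    planted inside parent-A blocks, each flanked by at least 10 empty bins,
    to exercise the map builder's island-suppression rule.
    """
    rng = rng or substream(config.seed, "snps")
    margin = (config.min_breakpoint_spacing_bins + 1) * BIN_SIZE
    strain_col: list[str] = []
    chrom_col: list[str] = []
    pos_chunks: list[np.ndarray] = []

    def emit(strain, chrom, positions):
        strain_col.extend([strain] * len(positions))
        chrom_col.extend([chrom] * len(positions))
        pos_chunks.append(positions.astype(np.int64))

    for strain in genos.breakpoints:
        for chrom, length in genos.chromosomes:
            noise_bins_used: list[int] = []
            for start, end, allele in genos.segments(strain, chrom, length):
                if allele == ALLELE_B:
                    n = rng.poisson((end - start) * config.snp_rate_per_bp)
                    emit(strain, chrom, rng.uniform(start, end, n))
                elif config.snp_noise_rate > 0:
                    lo = int((start + margin) // BIN_SIZE)
                    hi = int((end - margin) // BIN_SIZE)
                    if hi <= lo:
                        continue
                    hits = lo + np.flatnonzero(
                        rng.random(hi - lo) < config.snp_noise_rate)
                    for b in hits:
                        if noise_bins_used and b - noise_bins_used[-1] < 12:
                            continue  # keep false bins mutually isolated
                        noise_bins_used.append(int(b))
                        emit(strain, chrom,
                             rng.uniform(b * BIN_SIZE, (b + 1) * BIN_SIZE,
                                         rng.integers(1, 4)))
    df = pd.DataFrame({"strain": strain_col, "chrom": chrom_col,
                       "pos": np.concatenate(pos_chunks)
                       if pos_chunks else np.array([], dtype=np.int64)})
    return df.sort_values(["strain", "chrom", "pos"]).reset_index(drop=True)


def _place_gene(rng, chrom_lengths, chrom=None, near=None, max_offset=800_000):
    """Gene interval (chrom, start, end); near a position if requested."""
    gene_len = 2000
    if near is not None:
        lo = max(0, near - max_offset)
        hi = min(chrom_lengths[chrom] - gene_len, near + max_offset)
        start = int(rng.uniform(lo, hi))
    else:
        if chrom is None:
            chrom = rng.choice(list(chrom_lengths))
        start = int(rng.uniform(0, chrom_lengths[chrom] - gene_len))
    return chrom, start, start + gene_len


def simulate_expression(gmap: GeneticMap, config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[dict[str, ExpressionSet], PlantedTruth]:
    """Per-treatment log2 expression with planted cis/trans architecture.

    Model per spot i, sample j (strain s, treatment T):
        y_ij = baseline_i + treatmentEffect_iT + sum(active QTL effects * x_sj)
               + rulerSlope_i * age_j + N(0, noise_sd)
    where x is the 0/1 genotype (parent A = 1). Cis effects are active in all
    treatments; treatment-specific trans effects in exactly one; trans-band
    targets share one hub marker and one direction within a band.
    """
    rng = rng or substream(config.seed, "expression")
    chrom_lengths = dict(config.chromosomes)
    markers = gmap.markers
    n_markers = len(markers)
    strains = gmap.strains
    n = len(strains)
    G = gmap.genotype_array()          # strains x markers

    for band in config.trans_bands:
        if not (0 <= band.marker_index < n_markers):
            raise ValueError(f"trans band references nonexistent marker "
                             f"index {band.marker_index}")
        if band.treatment not in config.treatments:
            raise ValueError(f"trans band references unknown treatment "
                             f"{band.treatment!r}")

    spots = [f"spot_{i:05d}" for i in range(config.n_spots)]
    genes = [f"gene_{i:05d}" for i in range(config.n_spots)]

    def draw_effect():
        v = rng.uniform(*config.effect_size_range)
        sign = 1 if rng.random() < 0.5 else -1
        b = 2.0 * config.noise_sd * np.sqrt(v / (1.0 - v))
        return v, sign * b

    effect_rows = []      # planted QTL records
    ann_rows = []         # spot annotation
    qtl_terms = []        # (spot index, marker index, effect, active treatments)
    ruler_rows = []
    idx = 0

    def marker_loc(j):
        return markers.iloc[j]["chrom"], int(markers.iloc[j]["pos"])

    # cis: gene within 1 Mb of its causal marker, active in all treatments
    for _ in range(config.n_cis):
        j = int(rng.integers(n_markers))
        chrom, pos = marker_loc(j)
        v, b = draw_effect()
        gchrom, gs, ge = _place_gene(rng, chrom_lengths, chrom=chrom, near=pos)
        active = list(config.treatments)
        ann_rows.append((spots[idx], genes[idx], gchrom, gs, ge))
        effect_rows.append((spots[idx], genes[idx], markers.iloc[j]["marker"],
                            chrom, pos, "cis", ",".join(active), b, v, ""))
        qtl_terms.append((idx, j, b, active))
        idx += 1

    # treatment-specific trans: gene on another chromosome, active in one treatment
    for k in range(config.n_trans_specific):
        j = int(rng.integers(n_markers))
        chrom, pos = marker_loc(j)
        v, b = draw_effect()
        other = rng.choice([c for c in chrom_lengths if c != chrom])
        gchrom, gs, ge = _place_gene(rng, chrom_lengths, chrom=other)
        active = [config.treatments[k % len(config.treatments)]]
        ann_rows.append((spots[idx], genes[idx], gchrom, gs, ge))
        effect_rows.append((spots[idx], genes[idx], markers.iloc[j]["marker"],
                            chrom, pos, "trans", ",".join(active), b, v, ""))
        qtl_terms.append((idx, j, b, active))
        idx += 1

    # shared trans: active in all treatments
    for _ in range(config.n_trans_shared):
        j = int(rng.integers(n_markers))
        chrom, pos = marker_loc(j)
        v, b = draw_effect()
        other = rng.choice([c for c in chrom_lengths if c != chrom])
        gchrom, gs, ge = _place_gene(rng, chrom_lengths, chrom=other)
        active = list(config.treatments)
        ann_rows.append((spots[idx], genes[idx], gchrom, gs, ge))
        effect_rows.append((spots[idx], genes[idx], markers.iloc[j]["marker"],
                            chrom, pos, "trans", ",".join(active), b, v, ""))
        qtl_terms.append((idx, j, b, active))
        idx += 1

    # trans-band hubs: many targets, one marker, one direction, one treatment
    for bi, band in enumerate(config.trans_bands):
        j = band.marker_index
        chrom, pos = marker_loc(j)
        for _ in range(band.n_targets):
            v = rng.uniform(*config.effect_size_range)
            b = band.sign * 2.0 * config.noise_sd * np.sqrt(v / (1.0 - v))
            other = rng.choice([c for c in chrom_lengths if c != chrom])
            gchrom, gs, ge = _place_gene(rng, chrom_lengths, chrom=other)
            active = [band.treatment]
            ann_rows.append((spots[idx], genes[idx], gchrom, gs, ge))
            effect_rows.append((spots[idx], genes[idx], markers.iloc[j]["marker"],
                                chrom, pos, "trans", ",".join(active), b, v,
                                f"band{bi}"))
            qtl_terms.append((idx, j, b, active))
            idx += 1

    # ruler genes: positive linear age response, no treatment main effect
    slopes = rng.uniform(*config.ruler_slope_range, config.n_ruler_genes)
    ruler_idx = list(range(idx, idx + config.n_ruler_genes))
    for s in slopes:
        gchrom, gs, ge = _place_gene(rng, chrom_lengths)
        ann_rows.append((spots[idx], genes[idx], gchrom, gs, ge))
        ruler_rows.append((spots[idx], genes[idx], float(s)))
        idx += 1

    # background spots
    n_dup = int(config.duplicate_spot_fraction * (config.n_spots - idx))
    first_bg = idx
    while idx < config.n_spots:
        if idx >= config.n_spots - n_dup and first_bg < config.n_spots - n_dup:
            src = first_bg + (idx - (config.n_spots - n_dup))  # duplicate spot
            g = ann_rows[src]
            ann_rows.append((spots[idx], g[1], g[2], g[3], g[4]))
        else:
            gchrom, gs, ge = _place_gene(rng, chrom_lengths)
            ann_rows.append((spots[idx], genes[idx], gchrom, gs, ge))
        idx += 1

    annotation = pd.DataFrame(ann_rows, columns=["spot", "gene", "chrom",
                                                 "start", "end"])
    baseline = rng.normal(7.0, 1.0, config.n_spots)
    treat_eff = {t: rng.normal(0.0, config.treatment_effect_sd, config.n_spots)
                 if config.treatment_effect_sd > 0 else np.zeros(config.n_spots)
                 for t in config.treatments}
    for t in config.treatments:
        treat_eff[t][ruler_idx] = 0.0   # rulers respond to age only

    exprs: dict[str, ExpressionSet] = {}
    age_rows = []
    for t in config.treatments:
        samples = [f"{t}_{s}" for s in strains]
        ages = (config.ages_by_treatment.get(t, 48.0)
                + rng.normal(0.0, config.age_jitter_sd, n))
        age_rows += [(t, smp, float(a)) for smp, a in zip(samples, ages)]
        Y = baseline[:, None] + treat_eff[t][:, None] \
            + rng.normal(0.0, config.noise_sd, (config.n_spots, n))
        for spot_i, j, b, active in qtl_terms:
            if t in active:
                Y[spot_i] += b * G[:, j]
        for r, spot_i in enumerate(ruler_idx):
            Y[spot_i] += slopes[r] * (ages - 48.0)
        values = pd.DataFrame(Y, index=spots, columns=samples)
        design = pd.DataFrame({"sample": samples, "treatment": t,
                               "strain": strains})
        exprs[t] = ExpressionSet(values, design, annotation)

    truth = PlantedTruth(
        effects=pd.DataFrame(effect_rows, columns=[
            "spot", "gene", "marker", "chrom", "pos", "qtl_type",
            "treatments", "effect", "variance_explained", "band"]),
        ruler=pd.DataFrame(ruler_rows, columns=["spot", "gene", "slope"]),
        ages=pd.DataFrame(age_rows, columns=["treatment", "sample", "age"]),
    )
    return exprs, truth


def simulate_annotation(truth: PlantedTruth, gene_table: pd.DataFrame,
                        rng: np.random.Generator | None = None,
                        n_categories: int = 25,
                        mean_category_size: int = 20,
                        polymorph_background: float = 0.02
                        ) -> pd.DataFrame:
    """Synthetic gene -> category annotation table for enrichment tests.

    Random categories are drawn over the assayed genes (database "synthcat");
    a "polymorphism" database labels genes as high-polymorphism, covering
    most planted cis genes plus a small background fraction, emulating the
    excess of sequence variants under cis-regulated genes.
    """
    rng = rng or np.random.default_rng(0)
    genes = list(dict.fromkeys(gene_table["gene"]))
    rows = []
    for c in range(n_categories):
        size = max(2, rng.poisson(mean_category_size))
        for g in rng.choice(genes, size=min(size, len(genes)), replace=False):
            rows.append((g, f"cat{c:03d}", "synthcat"))
    cis_genes = set(truth.effects.loc[truth.effects["qtl_type"] == "cis",
                                      "gene"])
    for g in genes:
        hit = (rng.random() < 0.8) if g in cis_genes \
            else (rng.random() < polymorph_background)
        if hit:
            rows.append((g, "high_polymorphism", "polymorphism"))
    return pd.DataFrame(rows, columns=["gene", "category", "database"]) \
        .drop_duplicates(["gene", "category"]).reset_index(drop=True)


def simulate_dataset(config: SimConfig):
    """Convenience: genotypes + SNP calls + expression from one config/seed."""
    genos = simulate_ril_genotypes(config)
    snps = simulate_snp_calls(genos, config)
    exprs, truth = simulate_expression(genos.truth_map, config)
    return genos, snps, exprs, truth
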