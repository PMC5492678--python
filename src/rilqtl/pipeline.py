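"""Deterministic end-to-end orchestration of the full analysis.

Stages: simulate -> genetic map from SNP calls -> treatment response
(pairwise DE, Venn groups, PCA, age estimation) -> per-treatment eQTL scans
with permutation thresholds -> peaks -> cis/trans classification ->
trans-bands -> cross-treatment comparison -> power simulation -> enrichment.
Every output directory carries a manifest with the config hash, the seed and
per-stage row counts, and all randomness flows from one seed through named
substreams.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cl
from . import crosstreat as ct
from . import enrich as en
from . import genmap, io, mapping, treatment
from .config import PipelineConfig
from .containers import ExpressionSet
from .power import run_power_simulation
from .simulate import simulate_annotation, simulate_dataset, substream

log = logging.getLogger("rilqtl")


def combine_treatments(exprs: dict[str, ExpressionSet]) -> ExpressionSet:
    """Stack per-treatment expression sets into one spots x all-samples set."""
    values = pd.concat([e.values for e in exprs.values()], axis=1)
    design = pd.concat([e.design for e in exprs.values()], ignore_index=True)
    ann = next(iter(exprs.values())).annotation
    return ExpressionSet(values, design, ann)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> dict:
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    results: dict = {}
    sim = config.sim
    sim.seed = config.seed

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("simulate")
        genos, snps, exprs, truth = simulate_dataset(sim)
        annotation_table = simulate_annotation(
            truth, exprs[sim.treatments[0]].annotation,
            substream(config.seed, "annotation"))
        counts["snp_calls"] = len(snps)
        counts["spots"] = sim.n_spots
        io.write_table(snps, out / "snp_calls.tsv", "snp_calls")
        io.write_genetic_map(genos.truth_map, out / "genotypes_truth.tsv")
        for t, e in exprs.items():
            io.write_expression(e, out / t)
        with open(out / "truth.json", "w") as fh:
            json.dump({"effects": truth.effects.to_dict("records"),
                       "ruler": truth.ruler.to_dict("records"),
                       "ages": truth.ages.to_dict("records")}, fh)
        results.update(truth=truth, exprs=exprs, genos=genos)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("map")
        gmap = genmap.construct_map(snps, genos.truth_map.strains,
                                    sim.chromosomes, config.map_bin_size)
        counts["markers"] = gmap.n_markers
        io.write_genetic_map(gmap, out / "genotypes_constructed.tsv")
        io.write_marker_bed(gmap, out / "markers.bed")
        results["gmap"] = gmap
    except Exception as exc:
        raise RuntimeError(f"stage 'map' failed: {exc}") from exc

    try:
        stage("treatment_response")
        combined = combine_treatments(exprs)
        de = treatment.pairwise_de(combined, fdr=config.de_fdr)
        venn = treatment.venn_groups(de, combined.annotation)
        ratio = treatment.log2_ratio_transform(combined)
        pca = treatment.pca_treatments(ratio)
        ages = treatment.estimate_age(combined, truth.ruler,
                                      anchor_group=sim.treatments[0])
        io.write_table(de.table, out / "de.tsv", "de")
        venn.to_csv(out / "venn_groups.tsv", sep="\t", index=False)
        ages.rename("age").to_csv(out / "ages.tsv", sep="\t",
                                  index_label="sample")
        counts["de_significant"] = int(de.table["significant"].sum())
        results.update(de=de, venn=venn, pca=pca, ages=ages)
    except Exception as exc:
        raise RuntimeError(f"stage 'treatment_response' failed: {exc}") from exc

    try:
        stage("eqtl")
        profiles, thresholds = {}, {}
        for t in sim.treatments:
            mat = exprs[t].by_strain(t)
            if config.eqtl_threshold is None:
                thr = mapping.permutation_threshold(
                    mat, gmap, q=config.eqtl_fdr,
                    n_perm=config.n_permutations,
                    seed=substream(config.seed, f"perm_{t}"))
                thresholds[t] = thr.threshold
            else:
                thresholds[t] = config.eqtl_threshold
        # the most conservative (largest) treatment threshold is used for all
        found = [v for v in thresholds.values() if v is not None]
        if not found:
            raise ValueError("no treatment yielded discoveries at any "
                             "threshold; set a fixed eqtl_threshold")
        threshold = max(found)
        peaks = {}
        for t in sim.treatments:
            pk, prof = mapping.map_eqtl(exprs[t].by_strain(t), gmap, threshold,
                                        exprs[t].annotation, t, config.ci_drop)
            pk = cl.classify_cis_trans(pk, config.cis_distance)
            profiles[t] = prof
            peaks[t] = pk
            counts[f"eqtl_{t}"] = len(pk)
        all_peaks = pd.concat(peaks.values(), ignore_index=True)
        io.write_table(all_peaks.drop(columns=["untyped"]),
                       out / "eqtl.tsv", "eqtl")
        results.update(profiles=profiles, peaks=peaks, threshold=threshold,
                       thresholds_by_treatment=thresholds)
    except Exception as exc:
        raise RuntimeError(f"stage 'eqtl' failed: {exc}") from exc

    try:
        stage("trans_bands")
        bands = []
        for t in sim.treatments:
            trans = peaks[t][peaks[t]["qtl_type"] == "trans"]
            if len(trans):
                b = cl.detect_trans_bands(trans, config.trans_band_bin,
                                          config.trans_band_p)
                bands.append(b)
        band_table = pd.concat(bands, ignore_index=True) if bands else \
            pd.DataFrame(columns=list(io.SCHEMAS["transband"]))
        io.write_table(band_table, out / "trans_bands.tsv", "transband")
        counts["trans_bands"] = len(band_table)
        results["trans_bands"] = band_table
        results["direction"] = cl.allelic_direction_summary(all_peaks)
    except Exception as exc:
        raise RuntimeError(f"stage 'trans_bands' failed: {exc}") from exc

    try:
        stage("cross_treatment")
        overlap = {c: ct.overlap_by_gene(peaks, c) for c in ("cis", "trans")}
        lookup = ct.overlap_at_marker(all_peaks, profiles)
        plasticity = ct.genotypic_plasticity(lookup, threshold,
                                             list(sim.treatments))
        single = lookup[lookup["qtl_type"] == "trans"].copy()
        gene_treats = all_peaks[all_peaks["qtl_type"] == "trans"] \
            .groupby("gene")["treatment"].nunique()
        single = single[single["gene"].map(gene_treats).eq(1)]
        pva = ct.power_vs_absence(single, n=sim.n_strains,
                                  threshold=threshold,
                                  treatments=list(sim.treatments),
                                  noise_sd=sim.noise_sd)
        results.update(overlap=overlap, marker_lookup=lookup,
                       plasticity=plasticity, power_vs_absence=pva)
    except Exception as exc:
        raise RuntimeError(f"stage 'cross_treatment' failed: {exc}") from exc

    try:
        stage("power")
        rng = substream(config.seed, "power")
        subset = list(pd.Series(gmap.markers["marker"]).sample(
            n=min(12, gmap.n_markers), random_state=config.seed % 2 ** 31))
        power_table = run_power_simulation(
            gmap, levels=config.power_levels, reps=config.power_reps,
            threshold=threshold, seed=rng, markers=subset)
        io.write_table(power_table, out / "power.tsv", "power")
        results["power"] = power_table
    except Exception as exc:
        raise RuntimeError(f"stage 'power' failed: {exc}") from exc

    try:
        stage("enrichment")
        cis_genes = set(all_peaks.loc[all_peaks["qtl_type"] == "cis", "gene"])
        enrichment = en.hypergeometric_enrichment(cis_genes, annotation_table)
        io.write_table(enrichment, out / "enrichment_cis.tsv", "enrichment")
        io.write_table(annotation_table, out / "annotation.tsv", "annotation")
        results["enrichment"] = enrichment
    except Exception as exc:
        raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc

    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "threshold": float(threshold),
                "thresholds_by_treatment": {
                    t: (None if v is None else float(v))
                    for t, v in thresholds.items()},
                "row_counts": counts}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
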