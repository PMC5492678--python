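"""Shared study configuration for the numbered analysis scripts.

One seed, one synthetic cross: 48 RILs, six chromosomes, three treatments
(control / heat stress / recovery), 2000 microarray spots with planted
cis effects (stable across treatments), mostly single-treatment trans
effects, two trans-band hubs and 100 ruler genes. Scripts regenerate it
deterministically instead of passing files around.
"""

from pathlib import Path

from rilqtl.config import PipelineConfig, SimConfig, TransBandSpec
from rilqtl.genmap import construct_map
from rilqtl.simulate import (simulate_expression, simulate_ril_genotypes,
                             simulate_snp_calls)

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config() -> SimConfig:
    return SimConfig(n_spots=2000, n_cis=120, n_trans_specific=120,
                     n_trans_shared=60, n_ruler_genes=100,
                     snp_noise_rate=0.0005, seed=SEED)


def study_dataset():
    cfg = study_config()
    genos = simulate_ril_genotypes(cfg)
    nm = genos.truth_map.n_markers
    cfg.trans_bands = [
        TransBandSpec(marker_index=nm // 4, treatment="heat",
                      n_targets=60, sign=1),
        TransBandSpec(marker_index=(3 * nm) // 4, treatment="recovery",
                      n_targets=40, sign=-1),
    ]
    cfg.validate()
    snps = simulate_snp_calls(genos, cfg)
    exprs, truth = simulate_expression(genos.truth_map, cfg)
    gmap = construct_map(snps, genos.truth_map.strains, cfg.chromosomes)
    RESULTS.mkdir(exist_ok=True)
    return cfg, genos, snps, exprs, truth, gmap
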