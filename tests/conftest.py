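"""Shared fixtures: one moderately sized synthetic cross with planted
cis/trans architecture and trans-band hubs, reused across the suite."""

from dataclasses import dataclass

import numpy as np
import pytest

from rilqtl.config import SimConfig, TransBandSpec
from rilqtl.genmap import construct_map
from rilqtl.simulate import (simulate_expression, simulate_ril_genotypes,
                             simulate_snp_calls)

FIXTURE_SEED = 7


@dataclass
class Dataset:
    cfg: SimConfig
    genos: object
    snps: object
    exprs: dict
    truth: object
    gmap: object         # constructed from SNP calls
    truth_map: object


def make_dataset(seed: int = FIXTURE_SEED, **overrides) -> Dataset:
    cfg = SimConfig(n_spots=400, n_cis=24, n_trans_specific=24,
                    n_trans_shared=12, n_ruler_genes=40,
                    snp_noise_rate=0.0005, seed=seed, **overrides)
    genos = simulate_ril_genotypes(cfg)
    nm = genos.truth_map.n_markers
    cfg.trans_bands = [
        TransBandSpec(marker_index=nm // 3, treatment="heat",
                      n_targets=40, sign=1),
        TransBandSpec(marker_index=(2 * nm) // 3, treatment="recovery",
                      n_targets=30, sign=-1),
    ]
    cfg.validate()
    snps = simulate_snp_calls(genos, cfg)
    exprs, truth = simulate_expression(genos.truth_map, cfg)
    gmap = construct_map(snps, genos.truth_map.strains, cfg.chromosomes)
    return Dataset(cfg, genos, snps, exprs, truth, gmap, genos.truth_map)


@pytest.fixture(scope="session")
def dataset() -> Dataset:
    return make_dataset()


@pytest.fixture(scope="session")
def null_dataset() -> Dataset:
    """No planted effects, no treatment effects: everything should be null."""
    cfg = SimConfig(n_spots=200, n_cis=0, n_trans_specific=0,
                    n_trans_shared=0, n_ruler_genes=0,
                    treatment_effect_sd=0.0, seed=11)
    genos = simulate_ril_genotypes(cfg)
    snps = simulate_snp_calls(genos, cfg)
    exprs, truth = simulate_expression(genos.truth_map, cfg)
    return Dataset(cfg, genos, snps, exprs, truth, genos.truth_map,
                   genos.truth_map)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)
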