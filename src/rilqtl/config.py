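"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

#: Chromosome names and physical lengths (bp) mimicking C. elegans I-V, X.
DEFAULT_CHROMOSOMES: list[tuple[str, int]] = [
    ("I", 15_070_000),
    ("II", 15_280_000),
    ("III", 13_780_000),
    ("IV", 17_490_000),
    ("V", 20_920_000),
    ("X", 17_720_000),
]

DEFAULT_TREATMENTS = ("control", "heat", "recovery")

BIN_SIZE = 10_000          # SNP-density bin (bp)
TRANS_BAND_BIN = 500_000   # trans-band counting bin (bp)
CIS_DISTANCE = 1_000_000   # cis call distance (bp)
CI_DROP = 1.5              # -log10(p) drop defining the confidence interval


@dataclass
class TransBandSpec:
    """A planted trans-eQTL hub: one marker regulating many genes in one treatment."""

    marker_index: int        # index into the truth map's marker list
    treatment: str
    n_targets: int
    sign: int = 1            # +1: parent-A (N2) allele raises expression of all targets


@dataclass
class SimConfig:
    """Parameters of the synthetic RIL cross and expression experiment.

    Defaults describe the study conditions the package is built around:
    48 recombinant inbred lines from a two-parent cross, six chromosomes,
    three treatments (control / heat stress / recovery), unit-scale
    log2-expression noise, treatment-stable cis effects and largely
    treatment-specific trans effects (two thirds single-treatment).
    """

    n_strains: int = 48
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: list(DEFAULT_CHROMOSOMES))
    mean_crossovers_per_chrom: float = 0.7
    min_breakpoint_spacing_bins: int = 10   # 100 kb; 0 disables enforcement
    n_spots: int = 1000
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    n_cis: int = 40
    n_trans_specific: int = 40              # single-treatment trans effects
    n_trans_shared: int = 20                # trans effects active everywhere
    trans_bands: list[TransBandSpec] = field(default_factory=list)
    effect_size_range: tuple[float, float] = (0.30, 0.60)  # variance explained
    noise_sd: float = 1.0
    treatment_effect_sd: float = 0.5
    n_ruler_genes: int = 100
    ruler_slope_range: tuple[float, float] = (0.5, 1.5)    # log2 units / hour
    ages_by_treatment: dict[str, float] = field(
        default_factory=lambda: {"control": 48.0, "heat": 49.0, "recovery": 49.3})
    age_jitter_sd: float = 0.2              # hours, per-sample
    snp_rate_per_bp: float = 1 / 2000       # SNP density inside parent-B blocks
    snp_noise_rate: float = 0.0             # per-bin false-positive SNP bins
    duplicate_spot_fraction: float = 0.0    # fraction of genes on 2 spots
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        for n in (self.n_spots, self.n_cis, self.n_trans_specific,
                  self.n_trans_shared, self.n_ruler_genes):
            if n < 0:
                raise ValueError("counts must be non-negative")
        lo, hi = self.effect_size_range
        if not (0 < lo <= hi < 1):
            raise ValueError("effect_size_range fractions must lie in (0, 1)")
        if self.noise_sd < 0 or self.treatment_effect_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        planted = (self.n_cis + self.n_trans_specific + self.n_trans_shared
                   + sum(b.n_targets for b in self.trans_bands)
                   + self.n_ruler_genes)
        if planted > self.n_spots:
            raise ValueError(
                f"planted spots ({planted}) exceed n_spots ({self.n_spots})")
        for t, _ in self.ages_by_treatment.items():
            if t not in self.treatments:
                raise ValueError(f"age given for unknown treatment {t!r}")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; all thresholds the analysis depends on."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    de_fdr: float = 0.05
    eqtl_threshold: float | None = None   # None: determine by permutation
    eqtl_fdr: float = 0.05
    n_permutations: int = 10
    ci_drop: float = CI_DROP
    cis_distance: float = CIS_DISTANCE
    map_bin_size: int = BIN_SIZE
    trans_band_bin: int = TRANS_BAND_BIN
    trans_band_p: float = 0.001
    power_levels: tuple[float, ...] = tuple(round(0.20 + 0.05 * i, 2) for i in range(13))
    power_reps: int = 10
    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        for v in (self.de_fdr, self.eqtl_fdr, self.trans_band_p, self.ci_drop,
                  self.cis_distance, self.map_bin_size, self.trans_band_bin):
            if v <= 0:
                raise ValueError("thresholds and bin sizes must be positive")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        if self.eqtl_threshold is None and self.n_permutations == 0:
            raise ValueError("need a fixed eqtl_threshold when permutations = 0")
        self.sim.validate()

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        if "sim" in raw and isinstance(raw["sim"], dict):
            sim_raw = raw.pop("sim")
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(sim_raw) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            if "trans_bands" in sim_raw:
                sim_raw["trans_bands"] = [
                    TransBandSpec(**b) for b in sim_raw["trans_bands"]]
            if "chromosomes" in sim_raw:
                sim_raw["chromosomes"] = [tuple(c) for c in sim_raw["chromosomes"]]
            raw["sim"] = SimConfig(**sim_raw)
        cfg = cls(**raw)
        cfg.validate()
        return cfg
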