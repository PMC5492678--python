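"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BIN_SIZE

#: allele codes: parent A (N2-like reference) = 1, parent B (CB4856-like) = 0
ALLELE_A, ALLELE_B = 1, 0
ALLELE_LABELS = {ALLELE_A: "A", ALLELE_B: "B"}


def marker_id(chrom: str, pos: int) -> str:
    return f"{chrom}:{int(pos)}"


@dataclass
class GeneticMap:
    """Ordered markers plus a strains x markers genotype matrix.

    ``markers`` has columns ``marker`` (id, "chrom:binstart"), ``chrom`` and
    ``pos`` (bin start, bp) and is sorted by (chromosome order, position).
    ``genotypes`` is indexed by strain with one 0/1 column per marker
    (1 = parent A / N2-like, 0 = parent B / CB4856-like).
    """

    markers: pd.DataFrame
    genotypes: pd.DataFrame
    provenance: str = "constructed"   # "truth" | "constructed"
    bin_size: int = BIN_SIZE

    def __post_init__(self) -> None:
        if list(self.genotypes.columns) != list(self.markers["marker"]):
            raise ValueError("genotype columns must match the marker table")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def strains(self) -> list[str]:
        return list(self.genotypes.index)

    def genotype_array(self) -> np.ndarray:
        """Strains x markers array of 0/1 alleles."""
        return self.genotypes.to_numpy(dtype=float)

    def marker_positions(self, chrom: str) -> pd.DataFrame:
        return self.markers[self.markers["chrom"] == chrom]

    def subset_strains(self, strains: list[str]) -> "GeneticMap":
        return GeneticMap(self.markers.copy(), self.genotypes.loc[strains],
                          self.provenance, self.bin_size)


@dataclass
class ExpressionSet:
    """Spots x samples log2 intensities with design and spot annotation.

    ``values``: spots x samples (log2 scale). ``design``: one row per sample
    with columns ``sample``, ``treatment``, ``strain``. ``annotation``: one
    row per spot with columns ``spot``, ``gene``, ``chrom``, ``start``,
    ``end`` (gene location; half-open bp interval).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        dup = self.design["sample"].duplicated()
        if dup.any():
            raise ValueError("duplicate sample ids in design")
        if set(self.values.columns) != set(self.design["sample"]):
            raise ValueError("design samples must match expression columns")

    @property
    def spots(self) -> pd.Index:
        return self.values.index

    def treatment_of(self, sample: str) -> str:
        return self.design.set_index("sample").loc[sample, "treatment"]

    def samples_for(self, treatment: str) -> list[str]:
        return list(self.design.loc[self.design["treatment"] == treatment, "sample"])

    def by_strain(self, treatment: str) -> pd.DataFrame:
        """Spots x strains matrix for one treatment (columns renamed to strain)."""
        sub = self.design[self.design["treatment"] == treatment]
        mat = self.values[list(sub["sample"])].copy()
        mat.columns = list(sub["strain"])
        return mat


@dataclass
class PlantedTruth:
    """Ground-truth record of every effect the generator planted.

    ``effects``: one row per (spot, causal marker) with columns ``spot``,
    ``gene``, ``marker``, ``chrom``, ``pos``, ``qtl_type`` (cis|trans),
    ``treatments`` (comma-joined active treatments), ``effect`` (signed,
    log2 units, parent-A minus parent-B), ``variance_explained`` and
    ``band`` (hub id or empty). ``ruler``: spot, gene, slope. ``ages``: one
    row per (treatment, sample) with the true age in hours.
    """

    effects: pd.DataFrame
    ruler: pd.DataFrame
    ages: pd.DataFrame

    def active_in(self, treatment: str) -> pd.DataFrame:
        mask = self.effects["treatments"].str.split(",").apply(
            lambda ts: treatment in ts)
        return self.effects[mask]


@dataclass
class EQTLProfiles:
    """Full scan output for one treatment: per-spot association profiles.

    ``neglogp`` and ``effect`` are spots x markers frames aligned to ``gmap``;
    the effect is mean(parent-A strains) - mean(parent-B strains), log2 units.
    """

    neglogp: pd.DataFrame
    effect: pd.DataFrame
    gmap: GeneticMap
    treatment: str = ""
    n_strains: int = 0

    def peak_scores(self) -> pd.Series:
        """Per-spot maximum -log10(p) over all markers."""
        return self.neglogp.max(axis=1, skipna=True)


@dataclass
class ThresholdResult:
    """Permutation FDR threshold bookkeeping (FDS/RDS rule)."""

    q: float
    m: int
    n_permutations: int
    variant: str                       # "printed" | "by"
    table: pd.DataFrame                # candidate t, RDS, FDS, ratio, bound
    threshold: float | None            # chosen t*; None if no t satisfies
    field_notes: dict = field(default_factory=dict)
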