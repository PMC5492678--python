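"""Genetic-map construction from per-strain SNP calls.

The builder follows a density rule: SNP counts are tallied in 10 kb bins per
strain; a recombination event is a transition between a run of >= 10
consecutive empty bins and a run of occupied bins (or the reverse), located
at the first bin of the new state; transitions closer together than 10 bins
are both suppressed (short islands are treated as noise). The marker set is
the union of event bins over strains ("informative markers"), and each
strain's genotype is read off its segment structure: a segment containing
SNPs carries the parent-B (CB4856-like) allele, an empty segment parent-A.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import BIN_SIZE
from .containers import ALLELE_A, ALLELE_B, GeneticMap, marker_id

#: rule constants: interior runs must span >= MIN_RUN bins; a run truncated by
#: a chromosome end needs only TERMINAL_MIN_RUN bins (documented relaxation).
MIN_RUN = 10
TERMINAL_MIN_RUN = 5


def bin_snp_density(snp_calls: pd.DataFrame,
                    chromosomes: list[tuple[str, int]],
                    strains: list[str] | None = None,
                    bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Per-strain, per-chromosome SNP counts in half-open ``bin_size`` bins.

    Returns a tidy frame (strain, chrom, bin, count) covering *every* bin of
    every chromosome for every strain, zeros included. Positions outside the
    chromosome bounds are rejected with the offending records.
    """
    chrom_lengths = dict(chromosomes)
    bad = snp_calls[~snp_calls["chrom"].isin(chrom_lengths)]
    if len(bad):
        raise ValueError(f"SNPs on unknown chromosomes:\n{bad.head()}")
    lengths = snp_calls["chrom"].map(chrom_lengths)
    out_of_range = snp_calls[(snp_calls["pos"] < 0) | (snp_calls["pos"] >= lengths)]
    if len(out_of_range):
        raise ValueError(
            f"SNP positions beyond chromosome length:\n{out_of_range.head()}")

    if strains is None:
        strains = sorted(snp_calls["strain"].unique())
    frames = []
    grouped = snp_calls.groupby(["strain", "chrom"])["pos"]
    for strain in strains:
        for chrom, length in chromosomes:
            n_bins = -(-length // bin_size)  # ceil; final partial bin kept
            counts = np.zeros(n_bins, dtype=np.int64)
            try:
                pos = grouped.get_group((strain, chrom)).to_numpy()
                counts = np.bincount(pos // bin_size, minlength=n_bins)
            except KeyError:
                pass
            frames.append(pd.DataFrame({
                "strain": strain, "chrom": chrom,
                "bin": np.arange(n_bins), "count": counts}))
    return pd.concat(frames, ignore_index=True)


def _runs(occ: np.ndarray) -> list[list[int]]:
    """Run-length encode a boolean occupancy vector into [state, length] runs."""
    runs: list[list[int]] = []
    for v in occ:
        if runs and runs[-1][0] == int(v):
            runs[-1][1] += 1
        else:
            runs.append([int(v), 1])
    return runs


def _merge_short_runs(runs: list[list[int]], min_run: int,
                      terminal_min_run: int) -> list[list[int]]:
    """Iteratively absorb runs too short to count as segments into their
    neighbours (flipping their state), until every interior run spans
    >= ``min_run`` bins and every terminal run >= ``terminal_min_run``."""
    runs = [r[:] for r in runs]
    while len(runs) > 1:
        limits = [terminal_min_run if i in (0, len(runs) - 1) else min_run
                  for i in range(len(runs))]
        short = [i for i, (r, lim) in enumerate(zip(runs, limits)) if r[1] < lim]
        if not short:
            break
        i = min(short, key=lambda k: (runs[k][1], k))
        runs[i][0] = 1 - runs[i][0]
        merged: list[list[int]] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][1] += r[1]
            else:
                merged.append(r)
        runs = merged
    return runs


def _events_and_phase(counts: np.ndarray, min_run: int,
                      terminal_min_run: int) -> tuple[list[int], int]:
    """Event bins (start of each new segment) and the first segment's state."""
    occ = counts > 0
    runs = _merge_short_runs(_runs(occ), min_run, terminal_min_run)
    phase = runs[0][0]
    bins, pos = [], 0
    for state, length in runs[:-1]:
        pos += length
        bins.append(pos)
    return bins, phase


def call_recombination_events(density: pd.DataFrame,
                              min_run: int = MIN_RUN,
                              terminal_min_run: int = TERMINAL_MIN_RUN,
                              bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Per-strain recombination events from binned SNP density.

    Returns a frame (strain, chrom, bin, pos, kind) where ``kind`` is "gain"
    (empty -> SNP-bearing, i.e. parent A -> B) or "loss"; ``pos`` is the bin
    start. By construction no two events of one strain lie within
    ``min_run`` bins of each other.
    """
    rows = []
    for (strain, chrom), grp in density.groupby(["strain", "chrom"], sort=False):
        counts = grp.sort_values("bin")["count"].to_numpy()
        bins, phase = _events_and_phase(counts, min_run, terminal_min_run)
        state = phase
        for b in bins:
            kind = "gain" if state == 0 else "loss"
            rows.append((strain, chrom, int(b), int(b) * bin_size, kind))
            state = 1 - state
    return pd.DataFrame(rows, columns=["strain", "chrom", "bin", "pos", "kind"])


def segment_phases(density: pd.DataFrame, min_run: int = MIN_RUN,
                   terminal_min_run: int = TERMINAL_MIN_RUN) -> pd.DataFrame:
    """First-segment occupancy per (strain, chrom): 1 = SNP-bearing (parent B).

    A leading island shorter than the rule's window is ignored for phasing.
    """
    rows = []
    for (strain, chrom), grp in density.groupby(["strain", "chrom"], sort=False):
        counts = grp.sort_values("bin")["count"].to_numpy()
        _, phase = _events_and_phase(counts, min_run, terminal_min_run)
        rows.append((strain, chrom, int(phase)))
    return pd.DataFrame(rows, columns=["strain", "chrom", "occupied"])


def build_genetic_map(events: pd.DataFrame, phases: pd.DataFrame,
                      strains: list[str],
                      chromosomes: list[tuple[str, int]],
                      bin_size: int = BIN_SIZE) -> GeneticMap:
    """Assemble the informative-marker map from events and segment phases.

    Marker set = union of event bins over strains; a strain's genotype at a
    marker is the allele of the segment covering that bin (segments switch
    allele at the strain's own event bins; the first segment's allele comes
    from its SNP occupancy: occupied = parent B). Markers at which no strain
    recombines are dropped (cannot arise from union construction).
    """
    phase_idx = phases.set_index(["strain", "chrom"])["occupied"]
    missing = {(s, c) for s, c in zip(events["strain"], events["chrom"])} \
        - set(phase_idx.index)
    if missing:
        raise ValueError(f"events without a phase (inconsistent input): {missing}")

    chrom_order = [c for c, _ in chromosomes]
    rows = []
    for chrom in chrom_order:
        for b in sorted(events.loc[events["chrom"] == chrom, "bin"].unique()):
            rows.append((marker_id(chrom, b * bin_size), chrom, b * bin_size))
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos"])

    ev_by = {k: np.sort(g["bin"].to_numpy())
             for k, g in events.groupby(["strain", "chrom"])}
    geno = np.zeros((len(strains), len(markers)), dtype=np.int8)
    for i, strain in enumerate(strains):
        for j, (chrom, pos) in enumerate(zip(markers["chrom"], markers["pos"])):
            b = pos // bin_size
            ev = ev_by.get((strain, chrom), np.array([], dtype=int))
            occupied0 = int(phase_idx.get((strain, chrom), 0))
            flips = int(np.searchsorted(ev, b, side="right"))
            occupied = occupied0 ^ (flips % 2)
            geno[i, j] = ALLELE_B if occupied else ALLELE_A

    genotypes = pd.DataFrame(geno, index=strains, columns=list(markers["marker"]))
    # informative = a recombination event in >= 1 strain; union construction
    # guarantees it, so this is a defensive no-op for well-formed input
    event_bins = {(c, b) for c, b in zip(events["chrom"], events["bin"])}
    keep = [m for m, c, p in markers.itertuples(index=False)
            if (c, p // bin_size) in event_bins]
    markers = markers[markers["marker"].isin(keep)].reset_index(drop=True)
    return GeneticMap(markers, genotypes[keep], provenance="constructed",
                      bin_size=bin_size)


def construct_map(snp_calls: pd.DataFrame, strains: list[str],
                  chromosomes: list[tuple[str, int]],
                  bin_size: int = BIN_SIZE, min_run: int = MIN_RUN,
                  terminal_min_run: int = TERMINAL_MIN_RUN) -> GeneticMap:
    """SNP calls -> density -> events -> informative-marker genetic map."""
    density = bin_snp_density(snp_calls, chromosomes, strains, bin_size)
    events = call_recombination_events(density, min_run, terminal_min_run, bin_size)
    phases = segment_phases(density, min_run, terminal_min_run)
    return build_genetic_map(events, phases, strains, chromosomes, bin_size)


def marker_correlation(gmap: GeneticMap) -> pd.DataFrame:
    """Pearson correlation between numerically coded marker genotypes.

    Monomorphic markers (impossible after the informative filter) yield NaN.
    """
    if len(gmap.strains) < 2:
        raise ValueError("need >= 2 strains for marker correlation")
    G = gmap.genotype_array()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(G, rowvar=False)
    ids = list(gmap.markers["marker"])
    return pd.DataFrame(corr, index=ids, columns=ids)
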