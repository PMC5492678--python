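"""Map construction: density binning, the 10-consecutive-bin recombination
rule, island suppression, informative-marker filtering, marker linkage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rilqtl.containers import ALLELE_A, ALLELE_B
from rilqtl.genmap import (bin_snp_density, build_genetic_map,
                           call_recombination_events, construct_map,
                           marker_correlation, segment_phases)

CHROMS = [("I", 1_200_000)]  # 120 bins


def density_from_counts(counts, strain="s1", chrom="I"):
    return pd.DataFrame({"strain": strain, "chrom": chrom,
                         "bin": np.arange(len(counts)),
                         "count": np.asarray(counts)})


class TestBinDensity:
    def test_empty_table_all_zero(self):
        snps = pd.DataFrame(columns=["strain", "chrom", "pos"])
        dens = bin_snp_density(snps, CHROMS, strains=["s1"])
        assert len(dens) == 120
        assert (dens["count"] == 0).all()

    def test_counts_match_brute_force_tally(self):
        positions = [0, 5_000, 9_999, 10_000, 25_000, 25_001, 1_199_999]
        snps = pd.DataFrame({"strain": "s1", "chrom": "I", "pos": positions})
        dens = bin_snp_density(snps, CHROMS).set_index("bin")["count"]
        brute = {}
        for p in positions:
            brute[p // 10_000] = brute.get(p // 10_000, 0) + 1
        for b in range(120):
            assert dens[b] == brute.get(b, 0)

    def test_boundary_position_goes_to_upper_bin(self):
        snps = pd.DataFrame({"strain": ["s1"], "chrom": ["I"], "pos": [20_000]})
        dens = bin_snp_density(snps, CHROMS)
        assert dens.loc[dens["count"] > 0, "bin"].tolist() == [2]

    def test_position_beyond_chromosome_rejected(self):
        snps = pd.DataFrame({"strain": ["s1"], "chrom": ["I"],
                             "pos": [1_200_000]})
        with pytest.raises(ValueError, match="beyond chromosome"):
            bin_snp_density(snps, CHROMS)


class TestRecombinationEvents:
    def test_all_zero_chromosome_no_events(self):
        events = call_recombination_events(density_from_counts(np.zeros(120)))
        assert events.empty

    def test_single_clean_transition(self):
        counts = np.r_[np.zeros(60), np.ones(60)]
        events = call_recombination_events(density_from_counts(counts))
        assert len(events) == 1
        assert events.iloc[0]["bin"] == 60
        assert events.iloc[0]["kind"] == "gain"

    def test_isolated_island_suppressed(self):
        """One occupied bin flanked by >= 10 empty bins each side is noise:
        its two transitions are < 10 bins apart, so both are dropped."""
        counts = np.zeros(120)
        counts[50] = 3
        events = call_recombination_events(density_from_counts(counts))
        assert events.empty

    def test_short_gap_inside_occupied_run_suppressed(self):
        counts = np.ones(120)
        counts[40:44] = 0
        events = call_recombination_events(density_from_counts(counts))
        assert events.empty

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.integers(10, 30), min_size=2, max_size=6),
           st.booleans())
    def test_recovers_planted_run_boundaries(self, run_lengths, start_occupied):
        """Occupancy built from alternating runs of >= 10 bins yields events
        at exactly the planted run boundaries."""
        state0 = int(start_occupied)
        counts, state, boundaries, pos = [], state0, [], 0
        for L in run_lengths:
            counts += [state] * L
            pos += L
            boundaries.append(pos)
            state = 1 - state
        boundaries = boundaries[:-1]
        counts = np.array(counts, dtype=float)
        events = call_recombination_events(density_from_counts(counts))
        assert events["bin"].tolist() == boundaries
        if len(events) > 1:
            assert np.diff(events["bin"]).min() >= 10

    def test_events_never_closer_than_ten_bins(self, dataset):
        dens = bin_snp_density(dataset.snps, dataset.cfg.chromosomes,
                               dataset.truth_map.strains)
        events = call_recombination_events(dens)
        for _, grp in events.groupby(["strain", "chrom"]):
            b = np.sort(grp["bin"].to_numpy())
            if len(b) > 1:
                assert np.diff(b).min() >= 10


class TestBuildMap:
    def toy_events(self):
        events = pd.DataFrame({
            "strain": ["s1", "s2", "s2"], "chrom": ["I", "I", "I"],
            "bin": [30, 30, 70], "pos": [300_000, 300_000, 700_000],
            "kind": ["gain", "gain", "loss"]})
        phases = pd.DataFrame({"strain": ["s1", "s2"], "chrom": ["I", "I"],
                               "occupied": [0, 0]})
        return events, phases

    def test_no_events_empty_map(self):
        events = pd.DataFrame(columns=["strain", "chrom", "bin", "pos", "kind"])
        phases = pd.DataFrame(columns=["strain", "chrom", "occupied"])
        gmap = build_genetic_map(events, phases, ["s1"], CHROMS)
        assert gmap.n_markers == 0

    def test_shared_bin_yields_single_marker(self):
        events, phases = self.toy_events()
        gmap = build_genetic_map(events, phases, ["s1", "s2"], CHROMS)
        assert gmap.n_markers == 2          # bins 30 and 70, not three
        # both strains switch A -> B at bin 30; s2 switches back at 70
        g = gmap.genotypes
        assert g.loc["s1", "I:300000"] == ALLELE_B
        assert g.loc["s2", "I:700000"] == ALLELE_A
        assert g.loc["s1", "I:700000"] == ALLELE_B

    def test_missing_phase_rejected(self):
        events, phases = self.toy_events()
        with pytest.raises(ValueError, match="phase"):
            build_genetic_map(events, phases.iloc[:1], ["s1", "s2"], CHROMS)

    def test_constructed_map_matches_truth(self, dataset):
        """Round-trip through SNP calls recovers >= 95% of true breakpoints
        to within one bin and >= 99% of genotype cells at shared markers."""
        truth, built = dataset.truth_map, dataset.gmap
        true_bins = {(c, p // 10_000)
                     for c, p in zip(truth.markers["chrom"],
                                     truth.markers["pos"])}
        built_bins = {(c, p // 10_000)
                      for c, p in zip(built.markers["chrom"],
                                      built.markers["pos"])}
        recovered = sum(
            any((c, b + d) in built_bins for d in (-1, 0, 1))
            for c, b in true_bins)
        assert recovered / len(true_bins) >= 0.95
        shared = [m for m in built.markers["marker"]
                  if m in set(truth.markers["marker"])]
        agree = (built.genotypes[shared].to_numpy()
                 == truth.genotypes[shared].to_numpy()).mean()
        assert agree >= 0.99

    def test_idempotence_of_construction(self, dataset):
        """Rebuilding the map from its own implied SNP calls reproduces it."""
        from rilqtl.simulate import simulate_snp_calls
        import dataclasses
        cfg = dataclasses.replace(dataset.cfg, snp_noise_rate=0.0)
        snps = simulate_snp_calls(dataset.genos, cfg)
        rebuilt = construct_map(snps, dataset.truth_map.strains,
                                cfg.chromosomes)
        shared = [m for m in rebuilt.markers["marker"]
                  if m in set(dataset.gmap.markers["marker"])]
        assert len(shared) / dataset.gmap.n_markers >= 0.95
        agree = (rebuilt.genotypes[shared].to_numpy()
                 == dataset.gmap.genotypes[shared].to_numpy()).mean()
        assert agree >= 0.99

    def test_noise_robustness(self, dataset):
        """snp_noise_rate 0 -> 0.001 changes < 5% of recovered breakpoints."""
        import dataclasses
        from rilqtl.simulate import simulate_snp_calls
        bins = {}
        for rate in (0.0, 0.001):
            cfg = dataclasses.replace(dataset.cfg, snp_noise_rate=rate)
            snps = simulate_snp_calls(dataset.genos, cfg)
            built = construct_map(snps, dataset.truth_map.strains,
                                  cfg.chromosomes)
            bins[rate] = set(built.markers["marker"])
        diff = bins[0.0] ^ bins[0.001]
        assert len(diff) / max(1, len(bins[0.0])) < 0.05


class TestMarkerCorrelation:
    def test_identical_columns_r_one(self):
        geno = pd.DataFrame({"I:0": [1, 0, 1, 0], "I:10000": [1, 0, 1, 0]},
                            index=[f"s{i}" for i in range(4)])
        markers = pd.DataFrame({"marker": ["I:0", "I:10000"],
                                "chrom": "I", "pos": [0, 10_000]})
        from rilqtl.containers import GeneticMap
        corr = marker_correlation(GeneticMap(markers, geno))
        assert corr.loc["I:0", "I:10000"] == pytest.approx(1.0)

    def test_matches_brute_force_pearson(self, dataset):
        from scipy import stats
        gmap = dataset.gmap
        corr = marker_correlation(gmap)
        rng = np.random.default_rng(0)
        ids = list(gmap.markers["marker"])
        for _ in range(20):
            a, b = rng.choice(ids, 2, replace=False)
            x = gmap.genotypes[a].to_numpy(float)
            y = gmap.genotypes[b].to_numpy(float)
            r = stats.pearsonr(x, y)[0]
            assert corr.loc[a, b] == pytest.approx(r, abs=1e-12)

    def test_linkage_within_exceeds_between_chromosomes(self, dataset):
        corr = marker_correlation(dataset.gmap)
        markers = dataset.gmap.markers
        within = []
        for _, grp in markers.groupby("chrom"):
            ids = list(grp["marker"])
            within += [corr.loc[a, b] for a, b in zip(ids[:-1], ids[1:])]
        between = []
        by_chrom = {c: list(g["marker"]) for c, g in markers.groupby("chrom")}
        chroms = list(by_chrom)
        rng = np.random.default_rng(1)
        for _ in range(200):
            c1, c2 = rng.choice(chroms, 2, replace=False)
            a = rng.choice(by_chrom[c1])
            b = rng.choice(by_chrom[c2])
            between.append(abs(corr.loc[a, b]))
        assert np.mean(within) > np.mean(between)
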