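"""Cross-treatment eQTL comparison: gene overlap, same-marker lookup, effect
correlation, plasticity, power-vs-absence attribution, band overlap tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rilqtl.classify import classify_cis_trans
from rilqtl.crosstreat import (effect_correlation, genotypic_plasticity,
                               overlap_at_marker, overlap_by_gene,
                               power_vs_absence, transband_overlap_test)
from rilqtl.mapping import map_eqtl, scan
from rilqtl.power import analytic_power, effect_for_variance


def toy_peaks(genes, treatment, qtl_type="cis", effects=None):
    effects = effects if effects is not None else [1.0] * len(genes)
    return pd.DataFrame({
        "spot": [f"sp_{g}" for g in genes], "gene": genes,
        "treatment": treatment, "qtl_type": qtl_type,
        "chrom": "I", "marker": "I:0", "pos": 0, "neglogp": 5.0,
        "effect": effects, "ci_left": 0, "ci_right": 100_000})


@pytest.fixture(scope="module")
def fixture_peaks(dataset):
    peaks, profiles = {}, {}
    for t in dataset.cfg.treatments:
        mat = dataset.exprs[t].by_strain(t)
        pk, prof = map_eqtl(mat, dataset.truth_map, 3.9,
                            dataset.exprs[t].annotation, t)
        peaks[t] = classify_cis_trans(pk)
        profiles[t] = prof
    return peaks, profiles


class TestOverlapByGene:
    def test_identical_tables_triple_overlap(self):
        tables = {t: toy_peaks(["g1", "g2"], t) for t in ("a", "b", "c")}
        rep = overlap_by_gene(tables, "cis")
        assert rep.venn == {frozenset({"a", "b", "c"}): 2}

    def test_counts_match_enumeration(self):
        membership = {"g1": "abc", "g2": "ab", "g3": "a", "g4": "c",
                      "g5": "bc", "g6": "b"}
        tables = {t: toy_peaks([g for g, m in membership.items() if t in m], t)
                  for t in "abc"}
        rep = overlap_by_gene(tables, "cis")
        for key, count in rep.venn.items():
            want = sum(1 for m in membership.values()
                       if frozenset(m) == key)
            assert count == want
        assert sum(rep.venn.values()) == len(membership)
        for (a, b), n in rep.pair_shared.items():
            assert n == sum(1 for m in membership.values()
                            if a in m and b in m)

    def test_cis_more_stable_than_trans(self, dataset, fixture_peaks):
        """Planted architecture: cis effects active everywhere, most trans
        single-treatment, so the cis triple-overlap fraction dominates."""
        peaks, _ = fixture_peaks
        def triple_fraction(cls):
            rep = overlap_by_gene(peaks, cls)
            total = sum(rep.venn.values())
            return rep.venn.get(frozenset(dataset.cfg.treatments), 0) / total
        assert triple_fraction("cis") > 3 * triple_fraction("trans")


class TestOverlapAtMarker:
    def test_lookup_equals_direct_indexing(self, fixture_peaks):
        peaks, profiles = fixture_peaks
        table = overlap_at_marker(peaks["control"].head(10), profiles)
        for r in table.itertuples():
            for t, prof in profiles.items():
                assert getattr(r, f"neglogp_{t}") == pytest.approx(
                    prof.neglogp.at[r.spot, r.marker])
                assert getattr(r, f"effect_{t}") == pytest.approx(
                    prof.effect.at[r.spot, r.marker])

    def test_shared_planted_eqtl_significant_everywhere(self, dataset,
                                                        fixture_peaks):
        peaks, profiles = fixture_peaks
        shared = dataset.truth.effects[
            (dataset.truth.effects["qtl_type"] == "cis")
            & (dataset.truth.effects["variance_explained"] >= 0.45)]
        found = peaks["control"][peaks["control"]["spot"].isin(shared["spot"])]
        table = overlap_at_marker(found, profiles)
        for t in dataset.cfg.treatments:
            assert (table[f"neglogp_{t}"] > 3.9).mean() > 0.8
        # same-sign effects across treatments
        signs = np.sign(table[[f"effect_{t}" for t in
                               dataset.cfg.treatments]].to_numpy())
        assert (signs == signs[:, :1]).all()

    def test_specific_trans_effect_absent_elsewhere(self, dataset,
                                                    fixture_peaks):
        peaks, profiles = fixture_peaks
        eff = dataset.truth.effects
        spec = eff[(eff["qtl_type"] == "trans")
                   & (eff["treatments"] == "heat")]
        found = peaks["heat"][peaks["heat"]["spot"].isin(spec["spot"])]
        table = overlap_at_marker(found, profiles)
        for t in ("control", "recovery"):
            assert table[f"effect_{t}"].abs().mean() < 0.4
            assert (table[f"neglogp_{t}"] > 3.9).mean() < 0.1

    def test_marker_lookup_recovers_at_least_table_overlap(self, fixture_peaks):
        """Same-marker lookup can only add detections: every gene shared by
        table comparison is also significant at the peak marker."""
        peaks, profiles = fixture_peaks
        pair = ("control", "heat")
        shared_genes = set(peaks[pair[0]]["gene"]) & set(peaks[pair[1]]["gene"])
        table = overlap_at_marker(
            peaks[pair[0]][peaks[pair[0]]["gene"].isin(shared_genes)],
            profiles)
        assert (table[f"neglogp_{pair[0]}"] >= 3.9).all()


class TestEffectCorrelation:
    def test_identical_effects_r_one(self):
        a = toy_peaks(list("abcde"), "x", effects=[1, 2, 3, 4, 5])
        r, n = effect_correlation(a, a, "cis")
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_matches_brute_force_pearson(self, rng):
        ea, eb = rng.normal(size=5), rng.normal(size=5)
        a = toy_peaks(list("abcde"), "x", effects=ea)
        b = toy_peaks(list("abcde"), "y", effects=eb)
        r, _ = effect_correlation(a, b, "cis")
        assert r == pytest.approx(stats.pearsonr(ea, eb)[0])

    def test_too_few_pairs_undefined(self):
        a = toy_peaks(["g1", "g2"], "x")
        r, n = effect_correlation(a, a, "trans")
        assert np.isnan(r) and n == 0

    def test_shared_cis_effects_highly_correlated(self, dataset,
                                                  fixture_peaks):
        peaks, _ = fixture_peaks
        for a, b in combinations(dataset.cfg.treatments, 2):
            r, n = effect_correlation(peaks[a], peaks[b], "cis")
            assert n >= 10
            assert r > 0.9


class TestGenotypicPlasticity:
    def plasticity_table(self, e_a, e_b, s_a, s_b):
        return pd.DataFrame([{
            "spot": "sp0", "gene": "g0", "treatment": "a", "marker": "I:0",
            "chrom": "I", "pos": 0, "qtl_type": "cis",
            "neglogp_a": s_a, "effect_a": e_a,
            "neglogp_b": s_b, "effect_b": e_b}])

    def test_no_flip_empty(self):
        out = genotypic_plasticity(self.plasticity_table(1.0, 1.2, 5, 5),
                                   3.9, ["a", "b"])
        assert out.empty

    def test_significant_flip_detected(self):
        out = genotypic_plasticity(self.plasticity_table(1.0, -1.0, 5, 5),
                                   3.9, ["a", "b"])
        assert list(out["gene"]) == ["g0"]

    def test_subthreshold_flip_ignored(self):
        out = genotypic_plasticity(self.plasticity_table(1.0, -1.0, 5, 2.0),
                                   3.9, ["a", "b"])
        assert out.empty

    def test_planted_opposite_effects_recovered(self, dataset):
        """A trait built with opposite allelic effects in two treatments is
        flagged; scans supply the lookups."""
        gmap = dataset.truth_map
        m = gmap.markers["marker"].iloc[10]
        g = gmap.genotypes[m].to_numpy(float)
        rng = np.random.default_rng(3)
        profiles = {}
        for t, sign in (("heat", 1.0), ("recovery", -1.0)):
            mat = pd.DataFrame([sign * 2.0 * g + rng.normal(0, 1, g.size)],
                               index=["flip"], columns=gmap.strains)
            profiles[t] = scan(mat, gmap, t)
        peaks = pd.DataFrame([{"spot": "flip", "gene": "flipgene",
                               "treatment": "heat", "marker": m,
                               "chrom": "I", "pos": 0, "qtl_type": "trans"}])
        lookup = overlap_at_marker(peaks, profiles)
        out = genotypic_plasticity(lookup, 3.9, ["heat", "recovery"])
        assert list(out["gene"]) == ["flipgene"]


class TestPowerVsAbsence:
    def lookup(self, effects, treatment="heat",
               others=("control", "recovery")):
        rows = []
        for i, eff in enumerate(effects):
            row = {"spot": f"sp{i}", "gene": f"g{i}", "treatment": treatment,
                   "marker": "I:0", "chrom": "I", "pos": 0,
                   "qtl_type": "trans", f"neglogp_{treatment}": 5.0,
                   f"effect_{treatment}": 1.5}
            for t in others:
                row[f"neglogp_{t}"] = 0.5
                row[f"effect_{t}"] = eff
            rows.append(row)
        return pd.DataFrame(rows)

    def test_zero_cross_effects_fully_cryptic(self):
        out = power_vs_absence(self.lookup([0.0] * 20), 48, 3.9,
                               ["control", "heat", "recovery"])
        assert out["attributable_fraction"] == pytest.approx(0.0, abs=1e-3)
        assert out["cryptic_fraction"] == pytest.approx(1.0, abs=1e-3)

    def test_closed_form_at_planted_effects(self):
        """Cross effects equal to in-treatment effects: the attributable
        fraction is the mean analytic power at those effect sizes."""
        effects = [0.8, 1.0, 1.2, 1.5, 2.0]
        out = power_vs_absence(self.lookup(effects), 48, 3.9,
                               ["control", "heat", "recovery"])
        want = np.mean([analytic_power((b * b / 4) / (b * b / 4 + 1), 48, 3.9)
                        for b in effects])
        assert out["attributable_fraction"] == pytest.approx(want, rel=1e-9)

    def test_recovers_absent_fraction(self, rng):
        """70% truly absent / 30% present-but-underpowered cross effects:
        the recovered cryptic fraction lands within 10 points of 70%."""
        n, se = 48, 2.0 / np.sqrt(48)
        n_absent, n_present = 140, 60
        b_present = effect_for_variance(0.35)
        observed = np.r_[rng.normal(0.0, se, n_absent),
                         rng.normal(b_present, se, n_present)]
        out = power_vs_absence(self.lookup(observed), n, 3.9,
                               ["control", "heat", "recovery"])
        assert out["cryptic_fraction"] == pytest.approx(0.70, abs=0.10)

    def test_empty_input(self):
        out = power_vs_absence(self.lookup([]), 48, 3.9, ["a", "b", "c"])
        assert out["n"] == 0


class TestTransbandOverlap:
    def test_reported_band_pair_significant(self):
        """Sets of 244 and 31 genes overlapping in 22, universe 20,000:
        far beyond chance."""
        a = {f"g{i}" for i in range(244)}
        b = {f"g{i}" for i in range(222, 253)}
        assert len(a & b) == 22
        p = transband_overlap_test(a, b, 20_000)
        assert p < 1e-4

    def test_disjoint_sets_p_one(self):
        p = transband_overlap_test({"a", "b"}, {"c", "d"}, 10_000)
        assert p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        from itertools import combinations as combos
        universe = [f"g{i}" for i in range(10)]
        a = set(universe[:4])
        b = set(universe[2:5])
        observed = len(a & b)
        total = hits = 0
        for draw in combos(universe, len(b)):
            total += 1
            hits += len(a & set(draw)) >= observed
        assert transband_overlap_test(a, b, 10) == pytest.approx(hits / total)

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            transband_overlap_test({"a"}, {"b"}, 0)
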