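"""Compare eQTL across treatments: gene-level Venn overlap per class,
same-marker lookups, effect correlations, genotypic plasticity and the
power-versus-absence attribution of single-treatment trans eQTL.
"""

from itertools import combinations

import pandas as pd
from common import RESULTS, study_dataset

from rilqtl import io
from rilqtl.crosstreat import (effect_correlation, genotypic_plasticity,
                               overlap_at_marker, overlap_by_gene,
                               power_vs_absence)
from rilqtl.mapping import scan


def main():
    cfg, genos, snps, exprs, truth, gmap = study_dataset()
    all_peaks = io.read_table(RESULTS / "eqtl.tsv", "eqtl")
    peaks = {t: g for t, g in all_peaks.groupby("treatment")}
    profiles = {t: scan(exprs[t].by_strain(t), gmap, t)
                for t in cfg.treatments}

    rows = []
    for cls in ("cis", "trans"):
        rep = overlap_by_gene(peaks, cls)
        total = sum(rep.venn.values())
        triple = rep.venn.get(frozenset(cfg.treatments), 0)
        print(f"{cls}: {total} genes with an eQTL in >= 1 treatment; "
              f"{triple} ({triple / total:.0%}) in all three")
        for key, n in sorted(rep.venn.items(), key=lambda kv: sorted(kv[0])):
            rows.append((cls, "+".join(sorted(key)), n))
    pd.DataFrame(rows, columns=["class", "treatments", "genes"]) \
        .to_csv(RESULTS / "overlap_venn.tsv", sep="\t", index=False)

    for cls in ("cis", "trans"):
        for a, b in combinations(cfg.treatments, 2):
            r, n = effect_correlation(peaks[a], peaks[b], cls)
            print(f"  effect correlation {cls} {a}/{b}: "
                  f"r = {r:.3f} over {n} shared genes")

    lookup = overlap_at_marker(all_peaks, profiles)
    threshold = all_peaks["neglogp"].min()   # the scan threshold used
    plast = genotypic_plasticity(lookup, 3.9, list(cfg.treatments))
    print(f"genotypic plasticity (significant sign flips): {len(plast)} genes")

    trans_treatments = all_peaks[all_peaks["qtl_type"] == "trans"] \
        .groupby("gene")["treatment"].nunique()
    single = lookup[(lookup["qtl_type"] == "trans")
                    & lookup["gene"].map(trans_treatments).eq(1)]
    pva = power_vs_absence(single, n=cfg.n_strains, threshold=3.9,
                           treatments=list(cfg.treatments),
                           noise_sd=cfg.noise_sd)
    print(f"single-treatment trans eQTL: {pva['n']}")
    print(f"  attributable to limited power: "
          f"{pva['attributable_fraction']:.1%}")
    print(f"  cryptic (treatment-specific):  {pva['cryptic_fraction']:.1%}")
    truly_single = (truth.effects["qtl_type"] == "trans") \
        & (~truth.effects["treatments"].str.contains(","))
    print(f"  (planted: {truly_single.sum()} of "
          f"{(truth.effects['qtl_type'] == 'trans').sum()} trans effects "
          "are single-treatment)")
    pva["per_eqtl"].to_csv(RESULTS / "power_vs_absence.tsv", sep="\t",
                           index=False)


if __name__ == "__main__":
    main()
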