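"""Per-treatment eQTL scans: permutation FDS/RDS thresholds, then peaks at
the most conservative threshold, with variance explained.
"""

import pandas as pd
from common import RESULTS, SEED, study_dataset

from rilqtl import io
from rilqtl.classify import classify_cis_trans
from rilqtl.mapping import map_eqtl, permutation_threshold
from rilqtl.simulate import substream


def main():
    cfg, genos, snps, exprs, truth, gmap = study_dataset()

    thresholds = {}
    for t in cfg.treatments:
        mat = exprs[t].by_strain(t)
        res = permutation_threshold(mat, gmap, q=0.05, n_perm=10,
                                    seed=substream(SEED, f"perm_{t}"))
        thresholds[t] = res.threshold
        print(f"{t}: permutation threshold -log10(p) > {res.threshold:.2f} "
              f"(m = {res.m} spots, 10 permutations)")
    threshold = max(thresholds.values())
    print(f"using the most conservative threshold, {threshold:.2f}, "
          "for all treatments")

    tables = []
    for t in cfg.treatments:
        peaks, _ = map_eqtl(exprs[t].by_strain(t), gmap, threshold,
                            exprs[t].annotation, t)
        peaks = classify_cis_trans(peaks)
        tables.append(peaks)
        print(f"  {t}: {len(peaks)} eQTL peaks "
              f"({(peaks['qtl_type'] == 'cis').sum()} cis / "
              f"{(peaks['qtl_type'] == 'trans').sum()} trans); "
              f"median R^2 {peaks['r2'].median():.2f}")
    all_peaks = pd.concat(tables, ignore_index=True)
    io.write_table(all_peaks.drop(columns=["untyped"]),
                   RESULTS / "eqtl.tsv", "eqtl")


if __name__ == "__main__":
    main()
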