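"""Trans-band detection and allelic-direction summary on the mapped eQTL.

Reads results/eqtl.tsv (script 04); writes trans-band table and direction
summary; checks band calls against the planted hubs.
"""

import pandas as pd
from common import RESULTS, study_dataset

from rilqtl import io
from rilqtl.classify import allelic_direction_summary, detect_trans_bands


def main():
    cfg, genos, snps, exprs, truth, gmap = study_dataset()
    peaks = io.read_table(RESULTS / "eqtl.tsv", "eqtl")

    bands = []
    for t, grp in peaks.groupby("treatment"):
        trans = grp[grp["qtl_type"] == "trans"]
        if len(trans):
            b = detect_trans_bands(trans)
            bands.append(b)
            for r in b.itertuples():
                print(f"{t}: trans-band {r.chrom}:{r.start / 1e6:.1f}-"
                      f"{r.end / 1e6:.1f} Mb, {r.spots} spots / {r.genes} "
                      f"genes (rate {r.rate:.2f}, minimal count {r.k_min})")
    table = pd.concat(bands, ignore_index=True)
    io.write_table(table, RESULTS / "trans_bands.tsv", "transband")

    hubs = truth.effects[truth.effects["band"] != ""]
    for band_id, grp in hubs.groupby("band"):
        pos = grp["pos"].iloc[0]
        chrom = grp["chrom"].iloc[0]
        t = grp["treatments"].iloc[0]
        hit = table[(table["treatment"] == t) & (table["chrom"] == chrom)
                    & (table["start"] <= pos) & (table["end"] > pos)]
        print(f"planted hub {band_id} ({chrom}:{pos / 1e6:.1f} Mb, {t}, "
              f"{len(grp)} targets): {'recovered' if len(hit) else 'MISSED'}")

    direction = allelic_direction_summary(peaks)
    print(direction.to_string(index=False))


if __name__ == "__main__":
    main()
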