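"""Generate the study's synthetic cross and write its raw inputs.

Outputs under results/data/: per-strain SNP calls, truth genotype matrix,
per-treatment expression/design/gene-location tables, planted-truth record.
"""

import json

from common import RESULTS, study_dataset

from rilqtl import io


def main():
    cfg, genos, snps, exprs, truth, gmap = study_dataset()
    out = RESULTS / "data"
    out.mkdir(parents=True, exist_ok=True)
    io.write_table(snps, out / "snp_calls.tsv", "snp_calls")
    io.write_genetic_map(genos.truth_map, out / "genotypes_truth.tsv")
    for t, e in exprs.items():
        io.write_expression(e, out / t)
    with open(out / "truth.json", "w") as fh:
        json.dump({"effects": truth.effects.to_dict("records"),
                   "ruler": truth.ruler.to_dict("records"),
                   "ages": truth.ages.to_dict("records")}, fh)
    print(f"strains: {cfg.n_strains}, spots: {cfg.n_spots}, "
          f"treatments: {', '.join(cfg.treatments)}")
    print(f"SNP calls: {len(snps):,}; truth markers: "
          f"{genos.truth_map.n_markers}")
    print(f"planted effects: {len(truth.effects)} "
          f"({(truth.effects['qtl_type'] == 'cis').sum()} cis, "
          f"{(truth.effects['qtl_type'] == 'trans').sum()} trans)")


if __name__ == "__main__":
    main()
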