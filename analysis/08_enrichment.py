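"""Functional enrichment of eQTL gene sets on the synthetic annotation, and
the chi-squared polymorphism comparison between cis and non-cis genes.
"""

import numpy as np
from common import RESULTS, SEED, study_dataset

from rilqtl import io
from rilqtl.enrich import hypergeometric_enrichment, polymorphism_association
from rilqtl.simulate import simulate_annotation, substream


def main():
    cfg, genos, snps, exprs, truth, gmap = study_dataset()
    ann = simulate_annotation(truth, exprs["control"].annotation,
                              substream(SEED, "annotation"))
    io.write_table(ann, RESULTS / "annotation.tsv", "annotation")

    peaks = io.read_table(RESULTS / "eqtl.tsv", "eqtl")
    cis_genes = set(peaks.loc[peaks["qtl_type"] == "cis", "gene"])
    table = hypergeometric_enrichment(cis_genes, ann)
    io.write_table(table, RESULTS / "enrichment_cis.tsv", "enrichment")
    print(f"{len(table)} categories tested for {len(cis_genes)} cis genes; "
          f"{(table['p_bonferroni'] < 0.05).sum()} significant "
          "after Bonferroni:")
    for r in table[table["p_bonferroni"] < 0.05].itertuples():
        print(f"  {r.database}/{r.category}: overlap {r.overlap}/"
              f"{r.category_size}, corrected p = {r.p_bonferroni:.2e}")

    poly = set(ann.query("category == 'high_polymorphism'")["gene"])
    genes = list(dict.fromkeys(exprs["control"].annotation["gene"]))
    counts = np.zeros((2, 2), dtype=int)
    for g in genes:
        counts[int(g in cis_genes), int(g in poly)] += 1
    stat, p, df = polymorphism_association(counts)
    frac_cis = counts[1, 1] / counts[1].sum()
    frac_other = counts[0, 1] / counts[0].sum()
    print(f"high-polymorphism label: {frac_cis:.1%} of cis-eQTL genes vs "
          f"{frac_other:.1%} of other genes "
          f"(chi^2 = {stat:.1f}, df = {df}, p = {p:.2e})")


if __name__ == "__main__":
    main()
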