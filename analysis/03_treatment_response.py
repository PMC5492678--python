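"""Treatment effects on expression: pairwise DE under BY control, Venn
groups, PCA of log2 ratios, and ruler-based developmental age.
"""

from common import RESULTS, study_dataset

from rilqtl import io
from rilqtl.pipeline import combine_treatments
from rilqtl.treatment import (estimate_age, log2_ratio_transform, pairwise_de,
                              pca_treatments, venn_groups)


def main():
    cfg, genos, snps, exprs, truth, gmap = study_dataset()
    combined = combine_treatments(exprs)

    de = pairwise_de(combined, fdr=0.05)
    io.write_table(de.table, RESULTS / "de.tsv", "de")
    print("differential expression (BY, FDR 0.05):")
    for comp, grp in de.table.groupby("comparison"):
        thr = de.thresholds[comp]
        print(f"  {comp}: {grp['significant'].sum()} significant spots, "
              f"realized -log10(p) threshold {thr:.2f}")

    venn = venn_groups(de, combined.annotation)
    venn.to_csv(RESULTS / "venn_groups.tsv", sep="\t", index=False)
    print("Venn groups over DE genes:")
    for cat, n in venn["category"].value_counts().items():
        print(f"  {cat}: {n}")

    pca = pca_treatments(log2_ratio_transform(combined))
    print("PCA variance fractions (first six axes):",
          " ".join(f"{v:.3f}" for v in pca.variance_fraction))

    ages = estimate_age(combined, truth.ruler, anchor_group="control")
    ages.rename("age").to_csv(RESULTS / "ages.tsv", sep="\t",
                              index_label="sample")
    for t in cfg.treatments:
        samples = combined.samples_for(t)
        true_m = truth.ages.set_index("sample").loc[samples, "age"].mean()
        print(f"  {t}: estimated mean age {ages[samples].mean():.2f} h "
              f"(true {true_m:.2f} h)")


if __name__ == "__main__":
    main()
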