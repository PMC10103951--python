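"""Characterize circRNAs against the annotation: circles per gene vs exon
count, circularized exon and flanking intron lengths, and SNP proximity to
the synthetic GWAS positions.
"""

import pandas as pd

from _common import RESULTS, SCRATCH, load_or_simulate

from braincirc import features


def main() -> None:
    data = load_or_simulate()
    records, models = data["records"], data["models"]

    per_gene, r, _ = features.circ_per_gene_vs_exons(records, models)
    print(f"circles per gene vs exon count: Pearson r = {r:.2f} "
          f"({len(per_gene)} genes)")

    table = features.feature_summary(records, models)
    exonic = table[table["circ_class"] == "exonic"]
    print(f"circularized exons: mean length "
          f"{exonic['mean_exon_length'].mean():.0f} bp; flanking introns: "
          f"median up {exonic['upstream_intron_length'].median():.0f} bp, "
          f"down {exonic['downstream_intron_length'].median():.0f} bp")

    frac = features.snp_proximity_fraction(data["snps"], records)
    print(f"SNPs within 1 Mb of a circRNA: "
          f"{features.proportion_percent(round(frac * len(data['snps'])), len(data['snps']), 0):.0f}% "
          f"(designed: half near, half far)")

    table.to_csv(SCRATCH / "05_feature_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{
            "circ_per_gene_exon_pearson_r": r,
            "mean_circ_exon_length": exonic["mean_exon_length"].mean(),
            "snp_proximity_fraction": frac,
        }]
    ).to_csv(RESULTS / "05_features_summary.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / '05_features_summary.tsv'}")


if __name__ == "__main__":
    main()
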