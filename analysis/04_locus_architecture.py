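"""Classify host loci as exclusive producers vs super-hosts of cell-type-
specific circRNAs, and compare circular-to-linear ratios between neurons and
non-neuronal cells.
"""

from _common import RESULTS, load_or_simulate

from braincirc import loci, specificity


def main() -> None:
    data = load_or_simulate()
    rpm = specificity.rpm_normalize(
        data["bsj_counts"], data["samples"].set_index("sample_id")["library_size"]
    )
    spec = specificity.classify_specific(rpm, data["samples"])
    host_map = {r.circ_id: r.host_gene for r in data["records"]}
    locus_table = loci.classify_loci(spec, host_map)
    arch = loci.architecture_summary(locus_table)
    print("locus architecture:", arch.to_dict())

    ratios = loci.ratios_by_group(
        data["bsj_counts"], data["linear_counts"], data["samples"]
    )
    neuron = ratios["group"].isin(["DA", "PY"]).map({True: "neuron", False: "NN"})
    res = loci.compare_ratio_groups(ratios["ratio"], neuron, "neuron", "NN")
    med = ratios.groupby(neuron)["ratio"].median()
    print(f"circular-to-linear ratio medians: neuron {med['neuron']:.2f} vs "
          f"non-neuron {med['NN']:.2f}; Mann-Whitney p = {res.pvalue:.2e} "
          f"({res.method})")

    locus_table.to_csv(RESULTS / "04_locus_architecture.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / '04_locus_architecture.tsv'}")


if __name__ == "__main__":
    main()
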