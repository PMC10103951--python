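"""Apply the two-stage filter: expression support (>= 2 BSJ reads overall),
then RNase-R validation (>= 20 raw treated reads and >= 2-fold library-scaled
enrichment within one treated/mock pair).

Prints filter performance against the designed truth and the validation-rate
arithmetic on published-scale counts; writes the per-circle validation table.
"""

import pandas as pd

from _common import RESULTS, SCRATCH, load_or_simulate

from braincirc import features, filtering


def main() -> None:
    data = load_or_simulate()
    truth = data["truth"]
    expressed = filtering.filter_expressed(data["bsj_counts"])
    results = filtering.rnase_validate(data["rnase_counts"], data["rnase_meta"])
    validated = filtering.validated_set(results) & expressed
    true_ids = {c for c, v in truth.is_true_circle.items() if v}
    artifacts = set(truth.is_true_circle) - true_ids

    print(f"expressed: {len(expressed)}/{len(data['bsj_counts'])}")
    print(f"validated: {len(validated)} "
          f"({filtering.validation_rate(len(validated), len(data['bsj_counts']))}%)")
    sens = features.proportion_percent(len(validated & true_ids), len(true_ids))
    fpr = features.proportion_percent(len(validated & artifacts), len(artifacts))
    print(f"true-circle sensitivity: {sens}%  artifact pass rate: {fpr}%")
    print("published-count check: 10,845/22,593 exonic ->",
          filtering.validation_rate(10_845, 22_593), "%;",
          "194/88,826 ciRNA ->",
          features.proportion_percent(194, 88_826, decimals=2), "%")

    table = filtering.results_table(results)
    table.to_csv(SCRATCH / "02_validation.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{
            "n_candidates": len(data["bsj_counts"]),
            "n_expressed": len(expressed),
            "n_validated": len(validated),
            "true_circle_sensitivity_pct": sens,
            "artifact_pass_pct": fpr,
        }]
    ).to_csv(RESULTS / "02_filter_summary.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / '02_filter_summary.tsv'}")


if __name__ == "__main__":
    main()
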