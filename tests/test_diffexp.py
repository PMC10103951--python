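import warnings

import numpy as np
import pandas as pd
import pytest

from braincirc import diffexp, io


def make_samples(n_case, n_control, seed=0, balanced_sex=True):
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    sex = (["M", "F"] * n)[:n] if balanced_sex else rng.choice(["M", "F"], n).tolist()
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "cell_type": "DA", "group": "DA",
            "condition": ["ILB"] * n_case + ["HC"] * n_control,
            "sex": sex,
            "age": rng.normal(75, 8, n),
            "pmi": rng.exponential(5, n) + 1,
            "rin": rng.uniform(6, 9, n),
            "library_size": rng.integers(5_000_000, 20_000_000, n),
            "rnase_status": "none", "pair_id": "",
        }
    )


def nb_counts(mu, dispersion, rng):
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


class TestAggregate:
    def test_sums_circles_of_a_gene(self):
        counts = pd.DataFrame({"s1": [3, 5, 2]}, index=["c1", "c2", "c3"])
        host = {"c1": "G1", "c2": "G1", "c3": "G2"}
        out = diffexp.aggregate_to_gene(counts, host)
        assert out.loc["G1", "s1"] == 8
        assert out.loc["G2", "s1"] == 2

    def test_unmapped_circ_raises_unless_lenient(self):
        counts = pd.DataFrame({"s1": [3]}, index=["c1"])
        with pytest.raises(io.ValidationError):
            diffexp.aggregate_to_gene(counts, {})
        assert diffexp.aggregate_to_gene(counts, {}, lenient=True).empty

    def test_column_sums_preserved_under_full_mapping(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(0, 50, (30, 6)),
            index=[f"c{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(6)],
        )
        host = {f"c{i}": f"G{i % 7}" for i in range(30)}
        out = diffexp.aggregate_to_gene(counts, host)
        assert (out.sum(axis=0) == counts.sum(axis=0)).all()


class TestSizeFactors:
    def test_doubled_sample_gets_sqrt_two_factors(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 40], "s2": [20, 40, 80]}, index=["a", "b", "c"]
        )
        sf = diffexp.size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"s1": [5, 9], "s2": [5, 9]}, index=["a", "b"])
        assert np.allclose(diffexp.size_factors(counts), 1.0)

    def test_single_sample_gets_unit_factor(self):
        counts = pd.DataFrame({"s1": [5, 9]}, index=["a", "b"])
        assert diffexp.size_factors(counts).tolist() == [1.0]

    def test_no_universally_expressed_gene_raises(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [4, 0]}, index=["a", "b"])
        with pytest.raises(io.ValidationError, match="pseudo-reference"):
            diffexp.size_factors(counts)


class TestDesign:
    def test_rank_deficient_design_names_columns(self):
        samples = make_samples(4, 4)
        samples["rin"] = samples["age"]  # perfectly collinear
        with pytest.raises(io.ValidationError, match="rin"):
            diffexp.build_design(samples)

    def test_too_few_samples_per_level_rejected(self):
        samples = make_samples(1, 5)
        with pytest.raises(io.ValidationError, match="ILB"):
            diffexp.build_design(samples)


class TestNbWald:
    def test_identical_groups_give_null_result(self):
        samples = make_samples(3, 3)
        counts = pd.DataFrame(
            [[7] * 6, [30] * 6], index=["G1", "G2"], columns=samples["sample_id"]
        )
        de = diffexp.nb_wald(counts, samples, covariates=())
        assert np.allclose(de["log2_fold_change"], 0.0, atol=1e-8)
        assert np.allclose(de["wald_stat"], 0.0, atol=1e-6)
        assert np.allclose(de["p"], 1.0, atol=1e-6)

    def test_all_zero_gene_flagged_na(self):
        samples = make_samples(3, 3)
        counts = pd.DataFrame(
            [[0] * 6, [10, 12, 9, 11, 10, 13]],
            index=["dead", "ok"], columns=samples["sample_id"],
        )
        de = diffexp.nb_wald(counts, samples, covariates=())
        assert de.loc["dead", "all_zero"]
        assert np.isnan(de.loc["dead", "p"])
        assert not np.isnan(de.loc["ok", "p"])

    def test_offset_invariance_under_sample_scaling(self):
        rng = np.random.default_rng(8)
        samples = make_samples(6, 6)
        counts = pd.DataFrame(
            nb_counts(100.0 * np.ones((25, 12)), 0.05, rng),
            index=[f"G{i}" for i in range(25)], columns=samples["sample_id"],
        )
        de1 = diffexp.nb_wald(counts, samples)
        scaled = counts.copy()
        scaled.iloc[:, 0] = (scaled.iloc[:, 0] * 4).astype(int)
        sf1 = diffexp.size_factors(counts)
        sf2 = diffexp.size_factors(scaled)
        # factors are defined up to a common constant: the scaled sample's
        # factor grows 4x relative to every other sample's
        rel1 = sf1.iloc[0] / sf1.iloc[1:]
        rel2 = sf2.iloc[0] / sf2.iloc[1:]
        assert np.allclose(rel2 / rel1, 4.0, rtol=1e-6)
        # the scaling is absorbed by the size factor: LFCs move only through
        # second-order dispersion/weight effects
        de2 = diffexp.nb_wald(scaled, samples)
        assert np.abs(
            de1["log2_fold_change"] - de2["log2_fold_change"]
        ).max() < 0.05

    def test_common_rescaling_of_size_factors_is_exactly_absorbed(self):
        rng = np.random.default_rng(21)
        samples = make_samples(6, 6)
        counts = pd.DataFrame(
            nb_counts(90.0 * np.ones((20, 12)), 0.05, rng),
            index=[f"G{i}" for i in range(20)], columns=samples["sample_id"],
        )
        sf = diffexp.size_factors(counts)
        de1 = diffexp.nb_wald(counts, samples, sample_size_factors=sf)
        de2 = diffexp.nb_wald(counts, samples, sample_size_factors=sf * 3.7)
        assert np.allclose(
            de1["log2_fold_change"], de2["log2_fold_change"], atol=1e-6
        )
        assert np.allclose(de1["p"], de2["p"], atol=1e-6)

    def test_swapping_condition_labels_negates_lfc(self):
        rng = np.random.default_rng(9)
        samples = make_samples(6, 6)
        mu = 80.0 * np.ones((15, 12))
        mu[:5, :6] *= 2
        counts = pd.DataFrame(
            nb_counts(mu, 0.05, rng),
            index=[f"G{i}" for i in range(15)], columns=samples["sample_id"],
        )
        fwd = diffexp.nb_wald(counts, samples, contrast=("ILB", "HC"))
        rev = diffexp.nb_wald(counts, samples, contrast=("HC", "ILB"))
        assert np.allclose(
            fwd["log2_fold_change"], -rev["log2_fold_change"], atol=1e-6
        )
        assert np.allclose(fwd["p"], rev["p"], atol=1e-8)

    def test_poisson_data_yields_near_zero_dispersion(self):
        rng = np.random.default_rng(10)
        samples = make_samples(10, 10)
        counts = pd.DataFrame(
            rng.poisson(100.0, size=(60, 20)),
            index=[f"G{i}" for i in range(60)], columns=samples["sample_id"],
        )
        unit = pd.Series(1.0, index=counts.columns)
        de = diffexp.nb_wald(counts, samples, sample_size_factors=unit)
        assert de["dispersion_hat"].median() < 0.01

    def test_lfc_estimates_match_deseq2_reference(self):
        """Cross-check against an independent NB-GLM implementation."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(12)
        samples = make_samples(15, 15)
        mu = 120.0 * np.ones((40, 30))
        mu[:12, :15] *= 2 ** rng.uniform(-2, 2, (12, 1))
        counts = pd.DataFrame(
            nb_counts(mu, 0.08, rng),
            index=[f"G{i}" for i in range(40)], columns=samples["sample_id"],
        )
        ours = diffexp.nb_wald(counts, samples, covariates=())
        meta = pd.DataFrame(
            {"condition": pd.Categorical(
                samples["condition"], categories=["HC", "ILB"]
            )},
            index=samples["sample_id"],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=counts.T, metadata=meta, design="~condition", quiet=True
            )
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "ILB", "HC"], quiet=True)
            ds.summary()
        ref = ds.results_df.loc[ours.index, "log2FoldChange"]
        r = np.corrcoef(ours["log2_fold_change"], ref)[0, 1]
        assert r > 0.98
        assert np.abs(ours["log2_fold_change"] - ref).mean() < 0.1
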