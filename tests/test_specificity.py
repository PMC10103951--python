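import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from braincirc import io, specificity


def numeric_jsd_score(means, target):
    """Independent oracle: generic numeric Jensen-Shannon distance."""
    p = np.asarray(means, float) + 1.0
    p /= p.sum()
    q = np.zeros_like(p)
    q[target] = 1.0
    return 1.0 - jensenshannon(p, q, base=2)


def make_samples(rpm_columns, groups, condition="HC"):
    return pd.DataFrame(
        {
            "sample_id": rpm_columns,
            "cell_type": groups,
            "group": groups,
            "condition": condition,
            "sex": "M", "age": 70.0, "pmi": 3.0, "rin": 7.0,
            "library_size": 10_000_000,
            "rnase_status": "none", "pair_id": "",
        }
    )


class TestRpmNormalize:
    def test_per_million_scaling(self):
        counts = pd.DataFrame({"s1": [50, 0]}, index=["a", "b"])
        libs = pd.Series({"s1": 25_000_000})
        rpm = specificity.rpm_normalize(counts, libs)
        assert rpm.loc["a", "s1"] == pytest.approx(2.0)
        assert rpm.loc["b", "s1"] == 0.0

    def test_million_library_is_identity(self):
        counts = pd.DataFrame({"s1": [7]}, index=["a"])
        rpm = specificity.rpm_normalize(counts, pd.Series({"s1": 1_000_000}))
        assert rpm.loc["a", "s1"] == 7.0

    def test_missing_library_size_raises(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(io.ValidationError):
            specificity.rpm_normalize(counts, pd.Series({"other": 1.0}))


class TestSpecificityScore:
    def test_concentrated_profile(self):
        assert specificity.specificity_score([10, 0, 0], 0) == pytest.approx(
            0.7144260756128569, abs=1e-12
        )

    def test_uniform_profile_three_groups(self):
        assert specificity.specificity_score([5, 5, 5], 0) == pytest.approx(
            0.32239545675427705, abs=1e-12
        )

    def test_concentration_limit_approaches_one(self):
        assert specificity.specificity_score([1e6, 0, 0], 0) > 0.99

    def test_target_out_of_range(self):
        with pytest.raises(io.ValidationError):
            specificity.specificity_score([1, 2, 3], 5)

    @settings(max_examples=200, deadline=None)
    @given(
        means=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=6),
        data=st.data(),
    )
    def test_closed_form_matches_numeric_oracle(self, means, data):
        target = data.draw(st.integers(0, len(means) - 1))
        ours = specificity.specificity_score(means, target)
        assert 0.0 <= ours <= 1.0
        assert ours == pytest.approx(numeric_jsd_score(means, target), abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        means=st.lists(st.floats(0, 1000, allow_nan=False), min_size=3, max_size=3),
    )
    def test_permutation_equivariance(self, means):
        perm = [2, 0, 1]
        permuted = [means[i] for i in perm]
        for new_pos, old_pos in enumerate(perm):
            assert specificity.specificity_score(
                permuted, new_pos
            ) == pytest.approx(specificity.specificity_score(means, old_pos), abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        means=st.lists(
            st.floats(0, 1000, allow_nan=False), min_size=3, max_size=3
        ).filter(lambda m: max(m) > min(m)),
    )
    def test_adding_constant_moves_score_toward_uniform(self, means):
        target = int(np.argmax(means))
        uniform = specificity.specificity_score([1.0, 1.0, 1.0], 0)
        prev = specificity.specificity_score(means, target)
        for c in (10.0, 100.0, 1000.0):
            cur = specificity.specificity_score([m + c for m in means], target)
            # shifted scores approach the uniform value from above
            assert cur <= prev + 1e-12
            assert cur >= uniform - 1e-12
            prev = cur


class TestClassify:
    def test_concentrated_circ_is_group_specific(self):
        cols = ["d1", "d2", "p1", "p2", "n1", "n2"]
        rpm = pd.DataFrame([[10, 10, 0, 0, 0, 0]], index=["c1"], columns=cols)
        samples = make_samples(cols, ["DA", "DA", "PY", "PY", "NN", "NN"])
        spec = specificity.classify_specific(rpm, samples)
        row = spec[(spec["transcript_id"] == "c1") & (spec["group"] == "DA")].iloc[0]
        assert row["score"] == pytest.approx(0.7144260756, abs=1e-9)
        assert row["overall_mean"] == pytest.approx(10 / 3)
        assert row["overall_sd"] == pytest.approx(5.163977794943222)
        assert row["is_specific"]
        assert specificity.specific_assignments(spec).to_dict() == {"c1": "DA"}

    def test_constant_profile_is_not_specific(self):
        cols = ["d1", "p1", "n1", "d2", "p2", "n2"]
        rpm = pd.DataFrame([[4.0] * 6, [0.0] * 6], index=["c1", "c2"], columns=cols)
        samples = make_samples(cols, ["DA", "PY", "NN", "DA", "PY", "NN"])
        spec = specificity.classify_specific(rpm, samples)
        assert not spec["is_specific"].any()

    def test_disease_samples_are_excluded(self):
        cols = ["d1", "d2", "p1", "p2", "n1", "n2", "x1"]
        rpm = pd.DataFrame(
            [[10, 10, 0, 0, 0, 0, 500]], index=["c1"], columns=cols
        )
        samples = make_samples(cols, ["DA", "DA", "PY", "PY", "NN", "NN", "PY"])
        samples.loc[samples["sample_id"] == "x1", "condition"] = "AD"
        spec = specificity.classify_specific(rpm, samples)
        assert specificity.specific_assignments(spec).to_dict() == {"c1": "DA"}

    def test_empty_group_raises(self):
        cols = ["d1", "p1"]
        rpm = pd.DataFrame([[1, 2]], index=["c1"], columns=cols)
        samples = make_samples(cols, ["DA", "PY"])
        with pytest.raises(io.ValidationError, match="NN"):
            specificity.classify_specific(
                rpm, samples, group_order=("DA", "PY", "NN")
            )

    def test_five_cell_type_mode(self):
        cols = ["a", "b", "c", "d", "e"]
        rpm = pd.DataFrame([[50, 0, 0, 0, 0]], index=["c1"], columns=cols)
        samples = make_samples(cols, ["DA", "TCPY", "MCPY", "PBMC", "FB"])
        samples["group"] = samples["cell_type"].map(io.DEFAULT_GROUP_MAP)
        spec = specificity.classify_specific(rpm, samples, by="cell_type")
        assert sorted(spec["group"].unique()) == ["DA", "FB", "MCPY", "PBMC", "TCPY"]
        assert specificity.specific_assignments(spec).to_dict() == {"c1": "DA"}


class TestCircVsLinear:
    def _spec_tables(self, circ_means, linear_means):
        cols = ["d1", "d2", "p1", "p2", "n1", "n2"]
        groups = ["DA", "DA", "PY", "PY", "NN", "NN"]
        samples = make_samples(cols, groups)
        circ = pd.DataFrame(circ_means, columns=cols)
        circ.index = [f"c{i}" for i in range(len(circ))]
        lin = pd.DataFrame(linear_means, columns=cols)
        lin.index = [f"g{i}" for i in range(len(lin))]
        return (
            specificity.classify_specific(circ, samples),
            specificity.classify_specific(lin, samples),
        )

    def test_identical_profiles_give_zero_delta_and_p_one(self):
        vals = [[10, 10, 0, 0, 0, 0], [0, 0, 8, 8, 0, 0]]
        spec_c, spec_l = self._spec_tables(vals, vals)
        host_map = {"c0": "g0", "c1": "g1"}
        table, _, p, excluded = specificity.compare_circ_vs_linear(
            spec_c, spec_l, host_map
        )
        assert (table["delta_s"] == 0).all()
        assert p == 1.0
        assert excluded == 0

    def test_specific_circ_with_flat_linear_shows_positive_shift(self):
        rng = np.random.default_rng(4)
        n = 200
        circ_vals = np.zeros((n, 6))
        circ_vals[:, :2] = rng.uniform(20, 40, (n, 2))  # DA-concentrated
        lin_vals = rng.uniform(9, 11, (n, 6))  # flat
        spec_c, spec_l = self._spec_tables(circ_vals, lin_vals)
        host_map = {f"c{i}": f"g{i}" for i in range(n)}
        table, _, p, _ = specificity.compare_circ_vs_linear(spec_c, spec_l, host_map)
        assert table["delta_s"].median() > 0
        assert p < 0.01

    def test_empty_host_map_raises(self):
        spec_c, spec_l = self._spec_tables([[1, 1, 1, 1, 1, 1]], [[1, 1, 1, 1, 1, 1]])
        with pytest.raises(io.ValidationError):
            specificity.compare_circ_vs_linear(spec_c, spec_l, {})

    def test_missing_host_profile_counts_as_excluded(self):
        vals = [[10, 10, 0, 0, 0, 0], [0, 0, 8, 8, 0, 0]]
        spec_c, spec_l = self._spec_tables(vals, vals)
        table, _, _, excluded = specificity.compare_circ_vs_linear(
            spec_c, spec_l, {"c0": "g0", "c1": "absent"}
        )
        assert excluded == 1 and len(table) == 1
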