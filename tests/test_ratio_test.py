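import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preservstat import (
    MetricSimParams,
    ValidationError,
    average_ratio,
    benjamini_hochberg,
    count_stratified_assignments,
    metric_ratio_summary,
    ratio_permutation_test,
    simulate_metric_table,
)
from tests.conftest import make_study


def brute_force_null(study, metric, sidedness="two_sided"):
    """Independent oracle: enumerate every stratified label assignment directly
    from the data frame and return (observed average ratio, null averages, p)."""
    df = study.data
    per_material = []
    for m in dict.fromkeys(df["material"]):
        rows = df[df["material"] == m]
        vals = rows[metric].to_numpy(dtype=float)
        k = int((rows["treatment"] == "dried").sum())
        ratios = []
        for dried_idx in itertools.combinations(range(len(vals)), k):
            dried = vals[list(dried_idx)]
            frozen = np.delete(vals, list(dried_idx))
            ratios.append(dried.mean() / frozen.mean())
        per_material.append(ratios)
    null = np.array([np.mean(combo) for combo in itertools.product(*per_material)])
    obs_parts = []
    for m in dict.fromkeys(df["material"]):
        rows = df[df["material"] == m]
        obs_parts.append(
            rows.loc[rows["treatment"] == "dried", metric].mean()
            / rows.loc[rows["treatment"] == "frozen", metric].mean()
        )
    obs = float(np.mean(obs_parts))
    if sidedness == "two_sided":
        count = (np.abs(np.log(null)) >= abs(math.log(obs)) - 1e-12).sum()
    elif sidedness == "less":
        count = (null <= obs + 1e-12).sum()
    else:
        count = (null >= obs - 1e-12).sum()
    return obs, null, count / len(null)


class TestAverageRatio:
    def test_forced_arithmetic(self):
        study = make_study(
            ["A", "A", "A", "A", "B", "B"],
            ["dried", "dried", "frozen", "frozen", "dried", "frozen"],
            [2.0, 2.0, 4.0, 4.0, 1.0, 4.0],
        )
        ratios, avg = average_ratio(study, "metric")
        assert ratios == {"A": 0.5, "B": 0.25}
        assert avg == pytest.approx(0.375, abs=1e-15)

    def test_identical_values_give_unit_ratios(self, two_material_study):
        study = make_study(
            ["A"] * 4, ["dried", "dried", "frozen", "frozen"], [3.0] * 4
        )
        ratios, avg = average_ratio(study, "metric")
        assert avg == 1.0 and all(r == 1.0 for r in ratios.values())

    def test_zero_denominator_names_material(self):
        study = make_study(
            ["A"] * 4, ["dried", "dried", "frozen", "frozen"], [1.0, 1.0, 0.0, 0.0]
        )
        with pytest.raises(ValidationError, match="A"):
            average_ratio(study, "metric")

    def test_material_missing_treatment_is_error(self):
        study = make_study(["A", "A", "B"], ["dried", "frozen", "dried"],
                           [1.0, 2.0, 3.0])
        with pytest.raises(ValidationError, match="B"):
            average_ratio(study, "metric")

    def test_missing_values_dropped(self):
        study = make_study(
            ["A"] * 5, ["dried", "dried", "dried", "frozen", "frozen"],
            [2.0, 2.0, np.nan, 4.0, 4.0],
        )
        _, avg = average_ratio(study, "metric")
        assert avg == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None)
    @given(c=st.floats(0.1, 10.0), seed=st.integers(0, 2**20))
    def test_numerator_equivariance(self, c, seed):
        """Scaling all dried values by c scales the average ratio by c."""
        rng = np.random.default_rng(seed)
        vals = rng.uniform(1.0, 5.0, size=8)
        study = make_study(["A"] * 4 + ["B"] * 4,
                           ["dried", "dried", "frozen", "frozen"] * 2, list(vals))
        scaled = vals.copy()
        dried_rows = [0, 1, 4, 5]
        scaled[dried_rows] *= c
        study_c = make_study(["A"] * 4 + ["B"] * 4,
                             ["dried", "dried", "frozen", "frozen"] * 2, list(scaled))
        _, avg = average_ratio(study, "metric")
        _, avg_c = average_ratio(study_c, "metric")
        assert avg_c == pytest.approx(c * avg, rel=1e-9)

    def test_label_swap_reciprocal_per_material(self, two_material_study):
        fwd, _ = average_ratio(two_material_study, "yield", "dried", "frozen")
        rev, _ = average_ratio(two_material_study, "yield", "frozen", "dried")
        for m in fwd:
            assert rev[m] == pytest.approx(1.0 / fwd[m], rel=1e-12)

    def test_geometric_average_symmetric_under_swap(self, two_material_study):
        _, fwd = average_ratio(two_material_study, "yield", "dried", "frozen",
                               average="geometric")
        _, rev = average_ratio(two_material_study, "yield", "frozen", "dried",
                               average="geometric")
        assert rev == pytest.approx(1.0 / fwd, rel=1e-12)


class TestCountAssignments:
    def test_closed_forms(self, two_material_study):
        assert count_stratified_assignments(two_material_study) == 36
        one = make_study(["A"] * 4, ["dried", "dried", "frozen", "frozen"],
                         [1.0] * 4)
        assert count_stratified_assignments(one) == math.comb(4, 2)

    def test_full_design(self):
        study = simulate_metric_table(MetricSimParams(seed=0))
        assert count_stratified_assignments(study) == math.comb(10, 5) ** 6

    def test_empty_study(self):
        import pandas as pd
        from preservstat import StudyTable

        empty = StudyTable(
            pd.DataFrame(columns=["sample_id", "material", "treatment"]), ()
        )
        assert count_stratified_assignments(empty) == 1


class TestRatioPermutationTest:
    def test_exhaustive_matches_frozen_oracle(self, two_material_study):
        """2 materials with dried {10,10} / frozen {1,1}: p = 2/36 two-sided."""
        res = ratio_permutation_test(two_material_study, "yield", n_perm=1)
        assert res.mode == "exhaustive"
        assert res.n_permutations == 36
        assert res.average_ratio == pytest.approx(10.0)
        assert res.p_value == pytest.approx(2 / 36, abs=1e-15)

    @pytest.mark.parametrize("sidedness", ["two_sided", "less", "greater"])
    def test_exhaustive_equals_brute_force(self, sidedness):
        rng = np.random.default_rng(7)
        study = make_study(
            ["A"] * 5 + ["B"] * 4,
            ["dried", "dried", "frozen", "frozen", "frozen"]
            + ["dried", "dried", "frozen", "frozen"],
            list(rng.uniform(0.5, 8.0, size=9)),
        )
        obs, null, p = brute_force_null(study, "metric", sidedness)
        res = ratio_permutation_test(study, "metric", sidedness=sidedness)
        assert res.mode == "exhaustive"
        assert res.average_ratio == pytest.approx(obs, rel=1e-12)
        assert res.n_permutations == len(null)
        assert res.p_value == pytest.approx(p, abs=1e-15)
        assert res.null_mean == pytest.approx(null.mean(), rel=1e-12)

    def test_monte_carlo_agrees_with_exhaustive(self, two_material_study):
        exact = ratio_permutation_test(two_material_study, "yield")
        mc = ratio_permutation_test(
            two_material_study, "yield", n_perm=100_000, seed=11, exhaustive_limit=1
        )
        assert mc.mode == "monte_carlo"
        se = math.sqrt(exact.p_value * (1 - exact.p_value) / mc.n_permutations)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 1 / mc.n_permutations

    def test_constant_data_gives_p_one(self):
        study = make_study(["A"] * 4 + ["B"] * 4,
                           ["dried", "dried", "frozen", "frozen"] * 2, [5.0] * 8)
        res = ratio_permutation_test(study, "metric")
        assert res.average_ratio == 1.0
        assert res.p_value == 1.0

    def test_sigma_zero_recovers_delta_exactly(self):
        study = simulate_metric_table(
            MetricSimParams(noise_sigma=0.0, delta=0.5, seed=3)
        )
        _, avg = average_ratio(study, "metric")
        assert avg == 0.5

    def test_unknown_metric_is_error(self, two_material_study):
        with pytest.raises(KeyError):
            ratio_permutation_test(two_material_study, "nope")


class TestNullCalibration:
    def test_type_one_error_near_nominal(self):
        """Null simulation (delta=1): rejection rate at alpha=0.05 in [0.035, 0.065]."""
        rng = np.random.default_rng(2024)
        n_reps, alpha = 1000, 0.05
        rejections = 0
        params = MetricSimParams(n_materials=3, n_replicates=3, delta=1.0,
                                 noise_sigma=0.4)
        for _ in range(n_reps):
            study = simulate_metric_table(params, seed=int(rng.integers(2**31)))
            res = ratio_permutation_test(
                study, "metric", n_perm=199,
                seed=int(rng.integers(2**31)), exhaustive_limit=1,
            )
            rejections += res.p_value <= alpha
        assert 0.035 <= rejections / n_reps <= 0.065


class TestSummaryAndBH:
    def test_summary_has_one_row_per_metric(self):
        import pandas as pd
        from preservstat import StudyTable

        df = simulate_metric_table(MetricSimParams(n_materials=2, n_replicates=3,
                                                   seed=5), "m1").data
        df["m2"] = df["m1"] * 2.0
        study = StudyTable(df, ("m1", "m2"))
        out = metric_ratio_summary(study, n_perm=99, seed=1, adjust=True)
        assert list(out["metric"]) == ["m1", "m2"]
        assert {"average_ratio", "p_value", "mode", "p_adjusted"} <= set(out.columns)

    def test_bh_matches_hand_computation(self):
        # sorted p*(n/rank) = (0.04, 0.06, 0.0533, 0.5); step-up monotone
        # from the largest gives (0.04, 0.0533, 0.0533, 0.5)
        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = benjamini_hochberg(p)
        assert adj == pytest.approx([0.04, 0.04 * 4 / 3, 0.04 * 4 / 3, 0.5],
                                    abs=1e-12)
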