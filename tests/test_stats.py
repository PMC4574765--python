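import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_stepup, welch_closed_form
from pathexpress.stats import (
    DatasetError,
    ExpressionDataset,
    bh_adjust,
    differential_expression,
    linear_ratio,
    load_dataset,
    mean_log2_fold_change,
    per_sample_fold_change,
    raw_expression,
    two_sample_t,
)
from pathexpress.synthetic import generate_dataset, write_dataset


class TestDatasetValidation:
    def test_valid_dataset(self, tiny_dataset):
        assert tiny_dataset.gene_ids == ["gA", "gB"]
        assert tiny_dataset.case_group == "high"
        assert tiny_dataset.reference_samples == ["s1", "s2"]

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda v, g: (v, {k: g[k] for k in list(g)[:-1]}), "s4"),
            (lambda v, g: (v, g | {"s3": "mid"}), "two group labels"),
            (lambda v, g: (v, {k: "low" for k in g} | {"s4": "high"}), "high"),
            (lambda v, g: (v.set_axis(["gA", "gA"]), g), "duplicate gene"),
        ],
    )
    def test_invalid_datasets_name_the_offender(self, tiny_dataset, mutate, match):
        values, groups = mutate(tiny_dataset.values, dict(tiny_dataset.groups))
        with pytest.raises(DatasetError, match=match):
            ExpressionDataset(values=values, groups=groups, reference_group="low")

    def test_load_round_trip_matches_generated(self, tmp_path):
        ds, truth = generate_dataset(20, 4, 3, seed=7)
        matrix, design, _ = write_dataset(ds, truth, tmp_path)
        reloaded = load_dataset(matrix, design, ds.reference_group)
        assert reloaded.gene_ids == ds.gene_ids
        assert reloaded.sample_ids == ds.sample_ids
        assert reloaded.groups == ds.groups
        np.testing.assert_allclose(reloaded.values.values, ds.values.values, rtol=1e-9)

    def test_load_design_missing_sample_names_it(self, tmp_path):
        ds, truth = generate_dataset(5, 3, 0, seed=7)
        matrix, design, _ = write_dataset(ds, truth, tmp_path)
        trimmed = pd.read_csv(design, sep="\t").iloc[:-1]
        trimmed.to_csv(design, sep="\t", index=False)
        with pytest.raises(DatasetError, match="high_002"):
            load_dataset(matrix, design, ds.reference_group)


class TestFoldChange:
    def test_identical_groups_give_zero(self, tiny_dataset):
        assert mean_log2_fold_change(tiny_dataset, ["gB"])["gB"] == pytest.approx(0.0)

    def test_exact_unit_shift(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 2.0, 3.0]], index=["g"], columns=list("abcd")
        )
        ds = ExpressionDataset(
            values=values,
            groups={"a": "low", "b": "low", "c": "high", "d": "high"},
            reference_group="low",
        )
        assert mean_log2_fold_change(ds, ["g"])["g"] == pytest.approx(1.0)

    def test_absent_gene_is_null_not_error(self, tiny_dataset):
        out = mean_log2_fold_change(tiny_dataset, ["gA", "nope"])
        assert out["nope"] is None and out["gA"] is not None

    def test_empty_query_gives_empty_mapping(self, tiny_dataset):
        assert mean_log2_fold_change(tiny_dataset, []) == {}

    def test_planted_effect_recovered_within_sampling_error(self):
        delta, sd, n = 1.5, 1.0, 20
        ds, truth = generate_dataset(200, n, 200, effect_size=delta, noise_sd=sd, seed=3)
        fc = mean_log2_fold_change(ds, ds.gene_ids)
        se = sd * np.sqrt(2 / n) / np.sqrt(200)  # SE of the mean over 200 genes
        assert np.mean(list(fc.values())) == pytest.approx(delta, abs=4 * se)

    def test_linear_ratio_conversion(self):
        assert linear_ratio(1.0) == pytest.approx(2.0)
        assert linear_ratio(None) is None


class TestPerSampleFoldChange:
    def test_all_equal_gives_zero_vector(self, tiny_dataset):
        out = per_sample_fold_change(tiny_dataset, "gB")
        assert [v for _, v in out] == [0.0] * 4

    def test_hand_arithmetic_reference_mean_two(self):
        values = pd.DataFrame([[1.0, 3.0, 5.0, 7.0]], index=["g"], columns=list("abcd"))
        ds = ExpressionDataset(
            values=values,
            groups={"a": "low", "b": "low", "c": "high", "d": "high"},
            reference_group="low",
        )
        out = per_sample_fold_change(ds, "g")
        assert [v for _, v in out] == pytest.approx([-1.0, 1.0, 3.0, 5.0])

    def test_sample_order_and_reference_mean_zero(self, tiny_dataset):
        out = per_sample_fold_change(tiny_dataset, "gA")
        assert [s for s, _ in out] == tiny_dataset.sample_ids
        ref = [v for s, v in out if tiny_dataset.groups[s] == "low"]
        assert np.mean(ref) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_gene_raises(self, tiny_dataset):
        with pytest.raises(KeyError, match="nope"):
            per_sample_fold_change(tiny_dataset, "nope")


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_matches_closed_form_welch(self):
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        t_ref, p_ref = welch_closed_form([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_swap_antisymmetry(self, rng):
        x, y = rng.normal(size=6), rng.normal(1, 2, size=9)
        t1, p1 = two_sample_t(x, y)
        t2, p2 = two_sample_t(y, x)
        assert t1 == -t2 and p1 == p2

    def test_degenerate_zero_variance_different_means(self):
        t, p = two_sample_t([0, 0], [1, 1])
        assert p == 0.0 and t == -np.inf

    def test_degenerate_zero_variance_equal_means(self):
        assert two_sample_t([2, 2], [2, 2]) == (0.0, 1.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1], [1, 2])

    def test_student_variant_pools_variance(self):
        from scipy.stats import ttest_ind

        x, y = [1.0, 2.0, 4.0], [2.0, 6.0, 7.0, 9.0]
        t, p = two_sample_t(x, y, variant="student")
        t_ref, p_ref = ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(float(t_ref)) and p == pytest.approx(float(p_ref))


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_ties_collapse(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=200)
    )
    def test_agrees_with_brute_force_stepup(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_stepup(pvals), atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=50)
    )
    def test_output_bounds_and_sorted_monotonicity(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestDifferentialExpression:
    def test_single_gene_q_equals_p(self):
        values = pd.DataFrame([[1.0, 2.0, 4.0, 5.0]], index=["g"], columns=list("abcd"))
        ds = ExpressionDataset(
            values=values,
            groups={"a": "low", "b": "low", "c": "high", "d": "high"},
            reference_group="low",
        )
        (s,) = differential_expression(ds)
        assert s.q_value == s.p_value

    def test_matches_scalar_operations_per_gene(self, synthetic_pair):
        ds, _, _ = synthetic_pair
        results = differential_expression(ds)
        fc = mean_log2_fold_change(ds, ds.gene_ids)
        case, ref = ds.case_samples, ds.reference_samples
        for s in results[:25]:
            row = ds.values.loc[s.gene_id]
            t, p = two_sample_t(row[case], row[ref])
            assert s.log2_fc == pytest.approx(fc[s.gene_id])
            assert s.t_stat == pytest.approx(t, rel=1e-10)
            assert s.p_value == pytest.approx(p, rel=1e-10)
        q = bh_adjust([s.p_value for s in results])
        np.testing.assert_allclose([s.q_value for s in results], q, atol=1e-14)

    def test_degenerate_constant_rows_use_conventions(self):
        values = pd.DataFrame(
            [[2.0, 2.0, 2.0, 2.0], [0.0, 0.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.5]],
            index=["flat_equal", "flat_shifted", "normal"],
            columns=list("abcd"),
        )
        ds = ExpressionDataset(
            values=values,
            groups={"a": "low", "b": "low", "c": "high", "d": "high"},
            reference_group="low",
        )
        by_gene = {s.gene_id: s for s in differential_expression(ds)}
        assert by_gene["flat_equal"].t_stat == 0.0
        assert by_gene["flat_equal"].p_value == 1.0
        assert by_gene["flat_shifted"].p_value == 0.0
        assert by_gene["flat_shifted"].t_stat == np.inf

    def test_gene_order_permutation_equivariance(self, synthetic_pair):
        ds, _, _ = synthetic_pair
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ds.gene_ids))
        ds_perm = ExpressionDataset(
            values=ds.values.iloc[perm],
            groups=dict(ds.groups),
            reference_group=ds.reference_group,
        )
        orig = {s.gene_id: s for s in differential_expression(ds)}
        for s in differential_expression(ds_perm):
            assert s == orig[s.gene_id]

    def test_power_increases_with_effect_size(self):
        hits = {}
        for delta in (0.5, 2.0):
            found = 0
            for seed in range(20):
                ds, truth = generate_dataset(
                    200, 10, 20, effect_size=delta, noise_sd=1.0, seed=1000 + seed
                )
                sig = {
                    s.gene_id for s in differential_expression(ds) if s.q_value <= 0.05
                }
                found += len(sig & set(truth.de_gene_ids))
            hits[delta] = found
        assert hits[2.0] > hits[0.5]


class TestRawExpression:
    def test_present_gene_full_row(self, tiny_dataset):
        out = raw_expression(tiny_dataset, ["gA"])
        assert out["gA"]["samples"] == tiny_dataset.sample_ids
        assert out["gA"]["values"] == [1.0, 3.0, 5.0, 7.0]

    def test_absent_gene_null(self, tiny_dataset):
        assert raw_expression(tiny_dataset, ["zz"])["zz"] is None
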