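import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from m6array import (
    ClassificationThresholds,
    DifferentialAnalyzer,
    MethylationProfile,
    SimulationConfig,
    TwoGroupTTest,
    classify_regulation,
    differential_table,
    fold_changes,
    generate_dataset,
    hierarchical_cluster,
    quantify,
    top_table,
    unpaired_t_test,
)


def pooled_t_oracle(x, y):
    """Textbook pooled-variance two-sample t, independent of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    return t, df, 2 * sps.t.sf(abs(t), df)


class TestUnpairedTTest:
    def test_identical_samples_null(self):
        t, df, p = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula_oracle(self):
        x, y = (1.0, 2.0, 3.0), (4.0, 5.0, 6.0)
        t, df, p = unpaired_t_test(x, y)
        t0, df0, p0 = pooled_t_oracle(x, y)
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == df0
        assert p == pytest.approx(p0, abs=1e-10)

    def test_random_fixtures_match_oracle_tightly(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 9))
            y = rng.normal(0.5, 2.0, size=rng.integers(3, 9))
            t, _, p = unpaired_t_test(x, y)
            t0, _, p0 = pooled_t_oracle(x, y)
            assert abs(t - t0) < 1e-10 and abs(p - p0) < 1e-10

    def test_constant_equal_groups_give_p_one(self):
        t, _, p = unpaired_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_unequal_groups_give_p_zero(self):
        _, _, p = unpaired_t_test([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0

    def test_welch_differs_from_student_under_variance_imbalance(self):
        x = [0.0, 0.1, 0.2, 0.1]
        y = [5.0, -5.0, 10.0, -10.0, 3.0]
        _, _, p_student = unpaired_t_test(x, y, variant="student")
        _, _, p_welch = unpaired_t_test(x, y, variant="welch")
        assert p_student != p_welch

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1.0], [2.0, 3.0])


class TestTwoGroupTTest:
    def test_matches_scalar_test_per_feature(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 6))
        y = np.array([0] * 5 + [1] * 5)
        est = TwoGroupTTest().fit(X, y)
        for j in range(6):
            t, _, p = unpaired_t_test(X[y == 1, j], X[y == 0, j])
            assert est.statistic_[j] == pytest.approx(t, abs=1e-10)
            assert est.pvalue_[j] == pytest.approx(p, abs=1e-10)

    def test_nan_cells_omitted_pairwise(self):
        X = np.array([[1.0, 1], [2, np.nan], [3, 3], [4, 4], [5, 5], [6, 6]])
        y = np.array([0, 0, 0, 1, 1, 1])
        est = TwoGroupTTest().fit(X, y)
        t, _, p = unpaired_t_test([4.0, 5, 6], [1.0, 3])
        assert est.pvalue_[1] == pytest.approx(p, abs=1e-12)

    def test_sklearn_param_interface(self):
        est = TwoGroupTTest(variant="welch")
        assert est.get_params() == {"variant": "welch"}
        est.set_params(variant="student")
        assert est.variant == "student"


def _toy_profile():
    """2 probes x (2 T + 2 N) profile with hand-computable group means."""
    samples = pd.DataFrame({"group": ["T", "T", "N", "N"]},
                           index=pd.Index(["T1", "T2", "N1", "N2"], name="sample_id"))
    idx = pd.Index(["pA", "pB"], name="probe_id")
    meth = pd.DataFrame([[0.2, 0.4, 0.6, 0.6], [0.5, 0.5, 0.5, 0.5]],
                        index=idx, columns=samples.index)
    quantity = pd.DataFrame([[2.0, 8.0, 16.0, 16.0], [4.0, 4.0, 4.0, 4.0]],
                            index=idx, columns=samples.index)
    expr = quantity / meth
    probes = pd.DataFrame(
        {"gene_symbol": ["GA", "GB"], "rna_type": ["mRNA", "mRNA"],
         "chrom": ["chr1", "chr2"], "start": [1, 1], "end": [10, 10],
         "strand": ["+", "-"]},
        index=idx,
    )
    return MethylationProfile(
        meth_level=meth, m6a_quantity=quantity, expression=expr,
        kept_probes=pd.Series(True, index=idx), probes=probes, samples=samples,
    )


class TestFoldChanges:
    def test_hand_computed_toy_values(self):
        fc = fold_changes(_toy_profile())
        # probe A: meth ratio (0.3/0.6)=0.5; m6a log2 fc = mean(1,3)-mean(4,4) = -2
        assert fc.loc["pA", "fc_meth_ratio"] == pytest.approx(0.5)
        assert fc.loc["pA", "fc_m6a_log2"] == pytest.approx(-2.0)
        # probe B: identical groups
        assert fc.loc["pB", "fc_meth_ratio"] == pytest.approx(1.0)
        assert fc.loc["pB", "fc_m6a_log2"] == pytest.approx(0.0)
        assert fc.loc["pB", "fc_ge_log2"] == pytest.approx(0.0)

    def test_planted_ip_shift_recovered_exactly_without_quantile_step(self):
        cfg = SimulationConfig(
            n_probes=100, noise_log2_sd=0.0, flag_absent_rate=0.0,
            frac_diff_meth=0.2, meth_effect_log2=-3.0, frac_diff_expr=0.0, seed=6,
        )
        dataset, truth = generate_dataset(cfg)
        fc = fold_changes(quantify(dataset, quantile_norm=False))
        planted = truth.diff_meth_probes
        rest = fc.index.difference(planted)
        assert np.allclose(fc.loc[planted, "fc_m6a_log2"], -3.0, atol=1e-8)
        assert np.allclose(fc.loc[rest, "fc_m6a_log2"], 0.0, atol=1e-8)
        # IP contributes to IP+Sup: expression dips a little, but less than m6A
        ge = fc.loc[planted, "fc_ge_log2"]
        assert (ge < 0).all() and (ge > -3.0).all()

    def test_quantile_step_attenuates_but_preserves_planted_shift(self):
        # between-sample quantile normalization assumes most probes are
        # unchanged; with 20% planted it compresses the fold change a little
        cfg = SimulationConfig(
            n_probes=100, noise_log2_sd=0.0, flag_absent_rate=0.0,
            frac_diff_meth=0.2, meth_effect_log2=-3.0, frac_diff_expr=0.0, seed=6,
        )
        dataset, truth = generate_dataset(cfg)
        fc = fold_changes(quantify(dataset))
        planted = truth.diff_meth_probes
        got = fc.loc[planted, "fc_m6a_log2"]
        assert ((got > -3.2) & (got < -2.0)).all()

    def test_group_swap_negates_log2_fcs_and_inverts_ratio(self, small_profile):
        swapped = dataclasses.replace(
            small_profile,
            samples=small_profile.samples.assign(
                group=small_profile.samples["group"].map({"T": "N", "N": "T"})
            ),
        )
        fc = fold_changes(small_profile)
        fc_sw = fold_changes(swapped)
        np.testing.assert_allclose(fc_sw["fc_m6a_log2"], -fc["fc_m6a_log2"], atol=1e-9)
        np.testing.assert_allclose(fc_sw["fc_ge_log2"], -fc["fc_ge_log2"], atol=1e-9)
        np.testing.assert_allclose(
            fc_sw["fc_meth_ratio"], 1.0 / fc["fc_meth_ratio"], rtol=1e-9
        )

    def test_group_swap_leaves_pvalues_unchanged(self, small_profile):
        swapped = dataclasses.replace(
            small_profile,
            samples=small_profile.samples.assign(
                group=small_profile.samples["group"].map({"T": "N", "N": "T"})
            ),
        )
        res = DifferentialAnalyzer().fit(small_profile).results_
        res_sw = DifferentialAnalyzer().fit(swapped).results_
        for col in ("p_meth", "p_m6a", "p_ge"):
            np.testing.assert_allclose(res_sw[col], res[col], atol=1e-12)


class TestClassification:
    def test_published_rows_classified_as_printed(self, table3_records):
        labels = classify_regulation(table3_records)
        assert (labels == table3_records["regulation"]).all()
        assert labels.value_counts().to_dict() == {"Hypo-down": 10, "Hypo-up": 10}

    def test_null_record_is_ns(self):
        rec = pd.DataFrame(
            {"fc_m6a_log2": [0.0], "fc_ge_log2": [0.0], "fc_meth_ratio": [1.0],
             "p_m6a": [1.0], "p_ge": [1.0], "p_meth": [1.0]}
        )
        assert classify_regulation(rec).iloc[0] == "ns"

    def test_one_significant_axis_alone_is_ns(self):
        rec = pd.DataFrame(
            {"fc_m6a_log2": [-2.0], "fc_ge_log2": [-2.0], "fc_meth_ratio": [0.5],
             "p_m6a": [0.001], "p_ge": [0.5], "p_meth": [0.001]}
        )
        assert classify_regulation(rec).iloc[0] == "ns"

    def test_labels_partition_records(self, small_profile):
        res = differential_table(small_profile)
        assert res["regulation"].notna().all()
        assert res["regulation"].isin(
            ["Hyper-up", "Hyper-down", "Hypo-up", "Hypo-down", "ns"]
        ).all()

    def test_meth_level_basis_uses_ratio_bounds(self, table3_records):
        labels = classify_regulation(
            table3_records,
            ClassificationThresholds(meth_ratio_bounds=(0.8, 1.25)),
            fc_basis="meth_level",
        )
        # every published row has ratio 2**fc < 0.8, all significant
        assert labels.str.startswith("Hypo").all()

    def test_fc_threshold_suppresses_weak_calls(self):
        rec = pd.DataFrame(
            {"fc_m6a_log2": [-0.5], "fc_ge_log2": [-2.0], "fc_meth_ratio": [0.9],
             "p_m6a": [0.01], "p_ge": [0.01], "p_meth": [0.01]}
        )
        thr = ClassificationThresholds(fc_log2_min=1.0)
        assert classify_regulation(rec, thr).iloc[0] == "ns"
        assert classify_regulation(rec).iloc[0] == "Hypo-down"


class TestTopTable:
    def test_n_larger_than_table_returns_all(self, table3_records):
        res = differential_table(_toy_profile())
        assert len(top_table(res, 100)) == len(res)

    def test_first_hypo_down_mrna_by_ascending_m6a_fc(self, table3_records):
        top = top_table(table3_records, 10, key="m6a_fc_asc",
                        regulation_filter={"Hypo-down"})
        assert top.iloc[0]["gene_symbol"] == "BCL2A1"
        assert list(top["gene_symbol"][:3]) == ["BCL2A1", "CD93", "ARHGAP4"]

    def test_random_records_match_brute_force_sort(self):
        rng = np.random.default_rng(5)
        n = 30
        rec = pd.DataFrame(
            {
                "fc_m6a_log2": rng.choice([-2.0, -1.0, 1.0], size=n),  # many ties
                "regulation": rng.choice(["Hypo-down", "ns"], size=n),
            },
            index=pd.Index([f"p{i:02d}" for i in rng.permutation(n)], name="probe_id"),
        )
        got = top_table(rec, 10, key="m6a_fc_asc")
        expected = sorted(
            ((rec.loc[i, "fc_m6a_log2"], i) for i in rec.index)
        )[:10]
        assert list(got.index) == [i for _, i in expected]

    def test_bad_key_and_bad_n_rejected(self, table3_records):
        with pytest.raises(ValueError):
            top_table(table3_records, 0)
        with pytest.raises(ValueError):
            top_table(table3_records, 5, key="nope")


class TestHierarchicalCluster:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame(
            [[0.0, 0], [5, 5], [0, 0], [9, 9]],
            index=["a", "b", "c", "d"],
        )
        result = hierarchical_cluster(m)
        first = result.linkage_matrix[0]
        assert first[2] == 0.0  # zero distance merge
        merged = {result.labels[int(first[0])], result.labels[int(first[1])]}
        assert merged == {"a", "c"}

    def test_two_tight_pairs_merge_before_final_join(self):
        m = pd.DataFrame([[0.0], [1.0], [10.0], [11.0]], index=list("wxyz"))
        result = hierarchical_cluster(m)
        z = result.linkage_matrix
        # first two merges are (0,1) and (10,11) at distance 1 each
        assert z[0][2] == pytest.approx(1.0)
        assert z[1][2] == pytest.approx(1.0)
        assert z[2][2] > 5.0
        order = result.leaf_order
        assert set(order[:2]) in ({"w", "x"}, {"y", "z"})
        assert set(order[2:]) in ({"w", "x"}, {"y", "z"})

    def test_topology_invariant_under_input_permutation(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"))
        shuffled = m.sample(frac=1.0, random_state=1)
        r1 = hierarchical_cluster(m)
        r2 = hierarchical_cluster(shuffled)
        np.testing.assert_allclose(r1.linkage_matrix, r2.linkage_matrix)
        assert r1.newick == r2.newick

    def test_newick_parses_with_all_leaves(self):
        import io

        from Bio import Phylo

        m = pd.DataFrame(np.arange(10.0).reshape(5, 2), index=list("abcde"))
        result = hierarchical_cluster(m)
        tree = Phylo.read(io.StringIO(result.newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("abcde")

    def test_non_finite_values_rejected(self):
        m = pd.DataFrame([[np.nan, 1.0], [2.0, 3.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            hierarchical_cluster(m)
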