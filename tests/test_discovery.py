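"""Discovery screen: fold change, filtering, bagged OOB accuracy and the
step-down maxT permutation adjustment, checked against loop-based oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pressc as pc
from pressc.discovery import _all_label_permutations
from oracles import oracle_bag_accuracy, oracle_westfall_young


def _toy_matrix(case_vals, ctrl_vals, protein="P1"):
    vals = list(case_vals) + list(ctrl_vals)
    idx = [f"c{i}" for i in range(len(case_vals))] + [f"h{i}" for i in range(len(ctrl_vals))]
    m = pd.DataFrame({protein: vals}, index=pd.Index(idx, name="sample_id"))
    meta = pd.DataFrame(
        {
            "sample_id": idx,
            "group": ["case"] * len(case_vals) + ["control"] * len(ctrl_vals),
            "outcome": ["progressor"] * len(case_vals) + ["not_applicable"] * len(ctrl_vals),
        }
    )
    return m, meta


class TestFoldChange:
    @pytest.mark.parametrize(
        "cases,controls,expected",
        [
            ([4.0, 4.0, 4.0], [4.0, 4.0], 0.0),  # identical distributions
            ([8.0, 8.0], [4.0, 4.0], 1.0),  # exact doubling
            ([3.0, 3.0, 3.0], [2.0, 2.0], math.log2(1.5)),  # the 1.5-fold boundary
        ],
    )
    def test_closed_forms(self, cases, controls, expected):
        m, meta = _toy_matrix(cases, controls)
        assert pc.log_fold_change(m, meta)["P1"] == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_values(self):
        m, meta = _toy_matrix([1.0, -2.0], [1.0])
        with pytest.raises(ValueError, match="non-positive"):
            pc.log_fold_change(m, meta)

    def test_filter_is_two_sided_and_inclusive(self):
        fc = pd.Series({"a": 0.6, "b": -0.7, "c": 0.2, "d": 0.585, "e": -0.3})
        kept = pc.filter_by_fc(fc, 0.585)
        assert set(kept) == {"a", "b", "d"}
        assert len(pc.filter_by_fc(fc * 0.0, 0.585)) == 0


class TestBaggingAccuracy:
    def test_matches_loop_oracle_on_separated_marker(self, rng):
        y = np.array([True] * 7 + [False] * 6)
        values = np.where(y, 10.0, 1.0) + rng.normal(0, 0.01, 13)
        boot = rng.integers(0, 13, size=(100, 13))
        fast = pc.bagging_accuracy(values, y, bootstrap_indices=boot)
        slow = oracle_bag_accuracy(values, y, boot)
        assert fast == pytest.approx(slow, abs=1e-12)
        # a cleanly separated marker scores high, but the in-bag median is an
        # order statistic inside one class, so OOB accuracy stays below 1
        assert fast > 0.85

    def test_matches_loop_oracle_on_constant_marker(self, rng):
        y = np.array([True] * 7 + [False] * 6)
        values = np.full(13, 5.0)
        boot = rng.integers(0, 13, size=(500, 13))
        fast = pc.bagging_accuracy(values, y, bootstrap_indices=boot)
        slow = oracle_bag_accuracy(values, y, boot)
        assert fast == pytest.approx(slow, abs=1e-12)
        # tie rule: every value sits at the median, so the in-bag majority
        # class is predicted throughout; because bag and OOB compositions are
        # negatively correlated, accuracy lands below the 7/13 prevalence
        assert 0.30 < fast < 0.55

    def test_label_permutation_distribution_near_chance(self, rng):
        y = np.array([True] * 7 + [False] * 6)
        values = rng.normal(size=13)
        accs = [
            pc.bagging_accuracy(values, rng.permutation(y),
                                pc.BaggingConfig(seed=s))
            for s in range(60)
        ]
        assert 0.45 < np.mean(accs) < 0.65

    def test_single_class_outcome_rejected(self, rng):
        with pytest.raises(ValueError):
            pc.bagging_accuracy(rng.normal(size=5), np.ones(5, bool))


class TestStepdownMaxT:
    def test_exhaustive_permutations_match_westfall_young_oracle(self, rng):
        n, K = 6, 3
        y = np.array([True, True, True, False, False, False])
        values = rng.normal(size=(n, K))
        values[:, 0] += np.where(y, 2.0, 0.0)  # one informative protein
        boot = rng.integers(0, n, size=(25, n))
        perms = _all_label_permutations(y)  # C(6,3) = 20 labelings
        matrix = pd.DataFrame(values, columns=["A", "B", "C"])
        table = pc.stepdown_maxt(matrix, y, pc.BaggingConfig(n_resamples=25, seed=0),
                                 permutations=perms, bootstrap_indices=boot)
        order, p_oracle = oracle_westfall_young(values, y, boot, perms)
        assert list(table["protein_id"]) == [matrix.columns[k] for k in order]
        np.testing.assert_allclose(table["p_adj"].to_numpy(), p_oracle, atol=1e-12)

    def test_single_protein_reduces_to_unadjusted_permutation_p(self, rng):
        n = 8
        y = np.array([True] * 4 + [False] * 4)
        values = rng.normal(size=(n, 1))
        boot = rng.integers(0, n, size=(30, n))
        perms = _all_label_permutations(y)
        matrix = pd.DataFrame(values, columns=["only"])
        table = pc.stepdown_maxt(matrix, y, pc.BaggingConfig(n_resamples=30, seed=1),
                                 permutations=perms, bootstrap_indices=boot)
        obs = oracle_bag_accuracy(values[:, 0], y, boot)
        count = sum(
            oracle_bag_accuracy(values[:, 0], lab, boot) >= obs - 1e-9 for lab in perms
        )
        assert table["p_adj"].iloc[0] == pytest.approx((1 + count) / (len(perms) + 1))

    def test_identical_columns_share_p_adj(self, rng):
        y = np.array([True] * 5 + [False] * 5)
        col = rng.normal(size=10)
        matrix = pd.DataFrame({"a": col, "b": col, "c": col})
        table = pc.stepdown_maxt(matrix, y, pc.BaggingConfig(n_resamples=40,
                                                             n_permutations=200, seed=3))
        assert table["p_adj"].nunique() == 1

    def test_p_adj_range_and_monotonicity(self, rng):
        y = np.array([True] * 7 + [False] * 6)
        matrix = pd.DataFrame(rng.normal(size=(13, 8)),
                              columns=[f"p{i}" for i in range(8)])
        cfg = pc.BaggingConfig(n_resamples=50, n_permutations=150, seed=5)
        table = pc.stepdown_maxt(matrix, y, cfg)
        p = table["p_adj"].to_numpy()
        assert (p >= 1 / 151).all() and (p <= 1.0).all()
        assert (np.diff(p) >= 0).all()  # step-down monotone along accuracy order

    def test_column_order_invariance(self, rng):
        y = np.array([True] * 7 + [False] * 6)
        matrix = pd.DataFrame(rng.normal(size=(13, 5)),
                              columns=[f"p{i}" for i in range(5)])
        cfg = pc.BaggingConfig(n_resamples=40, n_permutations=100, seed=7)
        t1 = pc.stepdown_maxt(matrix, y, cfg).set_index("protein_id")
        t2 = pc.stepdown_maxt(matrix[matrix.columns[::-1]], y, cfg).set_index("protein_id")
        # same bootstrap/permutation draws, so results agree protein-by-protein
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())


class TestRunDiscovery:
    def test_planted_markers_rank_top_and_reach_significance(self):
        design = pc.DiscoveryDesign(n_proteins=100, seed=42)
        planted = [
            pc.EffectSpec("P0001", log2_fc=1.0, log_hr=3.0),
            pc.EffectSpec("P0002", log2_fc=-1.0, log_hr=-3.0),
            pc.EffectSpec("P0003", log2_fc=0.8, log_hr=3.0),
        ]
        m, meta = pc.generate_discovery_cohort(design, planted)
        cfg = pc.BaggingConfig(n_permutations=2000, seed=0)
        table = pc.run_discovery(m, meta, cfg)
        top3 = set(table["protein_id"].iloc[:3])
        assert top3 == {"P0001", "P0002", "P0003"}
        assert (table.set_index("protein_id").loc[list(top3), "p_adj"] <= 0.05).all()

    def test_empty_post_filter_set_yields_empty_table(self):
        design = pc.DiscoveryDesign(n_proteins=10, sigma=0.05, seed=0)
        m, meta = pc.generate_discovery_cohort(design)
        table = pc.run_discovery(m, meta, pc.BaggingConfig(n_permutations=50, seed=0))
        assert table.empty
        assert list(table.columns) == ["protein_id", "log2_fc", "bag_accuracy",
                                       "p_adj", "significant"]

    def test_deterministic_given_seed(self):
        design = pc.DiscoveryDesign(n_proteins=30, seed=10)
        m, meta = pc.generate_discovery_cohort(design, pc.default_discovery_effects(
            ["P0001", "P0002", "P0003"]))
        cfg = pc.BaggingConfig(n_permutations=200, seed=11)
        pd.testing.assert_frame_equal(pc.run_discovery(m, meta, cfg),
                                      pc.run_discovery(m, meta, cfg))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_bag_accuracy_bounded_for_random_markers(seed):
    rng = np.random.default_rng(seed)
    y = np.zeros(13, bool)
    y[rng.choice(13, 7, replace=False)] = True
    acc = pc.bagging_accuracy(rng.normal(size=13), y, pc.BaggingConfig(seed=seed % 1000))
    assert 0.0 <= acc <= 1.0
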