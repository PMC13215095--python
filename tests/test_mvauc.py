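import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from balanceselect.mvauc_select import (MvAUCSelector, feature_auc,
                                        macfc_main, macfc_v2, mvauc)

from conftest import make_matrix, random_matrix
from oracles import oracle_auc, oracle_best_subset, oracle_mvauc


class TestFeatureAuc:
    @pytest.mark.parametrize("case,ctrl,auc,orient", [
        ([3, 4], [1, 2], 1.0, "up-in-case"),     # perfect separation
        ([1, 2], [3, 4], 1.0, "down-in-case"),   # symmetric reversal
        ([1, 2], [2, 3], 0.875, "down-in-case"), # raw (0 + 0.5)/4 = 0.125
        ([5, 5], [5, 5], 0.5, "up-in-case"),     # constant gene, convention
    ])
    def test_hand_examples(self, case, ctrl, auc, orient):
        m = make_matrix({"g": case + ctrl}, len(case), len(ctrl))
        f = feature_auc(m, "g")
        assert f.auc == pytest.approx(auc)
        assert f.orientation == orient

    def test_missing_gene(self):
        m = make_matrix({"g": [1, 2, 3, 4]}, 2, 2)
        with pytest.raises(KeyError):
            feature_auc(m, "nope")


class TestMvauc:
    def test_singleton_reduces_to_oriented_auc(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 5, 3, 3)
        for g in m.gene_ids:
            assert mvauc(m, [g]) == pytest.approx(feature_auc(m, g).auc)

    def test_duplication_idempotent(self):
        m = make_matrix({"g": [1, 2, 0, 1]}, 2, 2)
        assert mvauc(m, ["g", "g"]) == mvauc(m, ["g"])

    def test_complementary_pair_reaches_one(self, complementary_matrix):
        m = complementary_matrix
        assert feature_auc(m, "gA").auc == pytest.approx(0.75)
        assert feature_auc(m, "gB").auc == pytest.approx(0.75)
        assert mvauc(m, ["gA", "gB"]) == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        m = make_matrix({"g": [1, 2, 0, 1]}, 2, 2)
        with pytest.raises(ValueError):
            mvauc(m, [])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), size=st.integers(1, 4))
    def test_matches_pair_enumeration_oracle(self, seed, size):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 6, 3, 3)
        genes = list(rng.choice(m.gene_ids, size=size, replace=False))
        assert mvauc(m, genes) == pytest.approx(oracle_mvauc(m, genes))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_under_feature_addition(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 6, 3, 3)
        genes = m.gene_ids
        base = rng.choice(genes, size=2, replace=False).tolist()
        val = mvauc(m, base)
        for g in genes:
            assert mvauc(m, base + [g]) >= val - 1e-12

    def test_dominates_best_member_auc(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 6, 4, 3)
        genes = m.gene_ids[:4]
        assert mvauc(m, genes) >= max(feature_auc(m, g).auc for g in genes)


class TestGreedySelection:
    def test_identical_copies_select_one(self):
        row = [3, 4, 1, 2]
        m = make_matrix({f"g{i}": row for i in range(5)}, 2, 2)
        trace = macfc_main(m)
        assert len(trace.selected) == 1

    def test_complementary_fixture_selects_both(self, complementary_matrix):
        trace = macfc_main(complementary_matrix)
        assert sorted(trace.selected) == ["gA", "gB"]
        assert trace.cumulative_mvauc[-1] == pytest.approx(1.0)
        assert trace.weights[0] == pytest.approx(0.25)  # 0.75 - 0.5
        assert trace.weights[1] == pytest.approx(0.25)  # 1.0 - 0.75

    def test_first_weight_is_auc_minus_half(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 8, 4, 4)
        trace = macfc_main(m)
        first = trace.selected[0]
        assert trace.weights[0] == pytest.approx(
            feature_auc(m, first).auc - 0.5)

    def test_greedy_matches_exhaustive_on_separable_fixture(self):
        """On a fixture whose pair coverages are separable, the greedy pair
        attains the best exhaustive subset value of size <= 2."""
        m = make_matrix({
            "gA": [2, 1, 1, 1], "gB": [1, 2, 1, 1],
            "gC": [1, 1, 0, 1], "gD": [0, 0, 1, 1],
            "gE": [1, 1, 1, 1], "gF": [2, 2, 1, 1],
        }, 2, 2)
        trace = macfc_main(m, max_features=2)
        best_val, _ = oracle_best_subset(m, 2)
        assert trace.cumulative_mvauc[min(1, len(trace.selected) - 1)] == \
            pytest.approx(best_val)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_trace_prefixes_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 8, 3, 3)
        trace = macfc_main(m, max_features=8)
        for k in range(len(trace.selected)):
            assert trace.cumulative_mvauc[k] == pytest.approx(
                oracle_mvauc(m, trace.selected[: k + 1]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_label_swap_preserves_aucs_and_selection_values(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 6, 3, 3)
        swapped = m.swap_labels()
        for g in m.gene_ids:
            f, fs = feature_auc(m, g), feature_auc(swapped, g)
            assert f.auc == pytest.approx(fs.auc)
        # mvAUC swap invariance holds for genes with a defined direction;
        # at raw AUC exactly 0.5 the orientation is conventional and the
        # per-pair credit vector is not unique
        genes = [g for g in m.gene_ids if feature_auc(m, g).auc > 0.5][:3]
        if genes:
            assert mvauc(m, genes) == pytest.approx(mvauc(swapped, genes))

    def test_label_swap_flips_orientation(self):
        m = make_matrix({"g": [3, 4, 1, 2]}, 2, 2)
        assert feature_auc(m, "g").orientation == "up-in-case"
        assert feature_auc(m.swap_labels(), "g").orientation == "down-in-case"

    def test_empty_matrix_rejected(self):
        import pandas as pd
        from balanceselect.formats_io import ExpressionMatrix
        m = make_matrix({"g": [1, 2, 0, 1]}, 2, 2)
        empty = ExpressionMatrix(
            values=m.values.iloc[0:0], classes=m.classes,
            case_label="case", control_label="control")
        with pytest.raises(ValueError):
            macfc_main(empty)


class TestSeededVariant:
    def test_no_seed_equals_main(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 6, 3, 3)
        # threshold 1.0 is unattainable -> empty seed set
        v2 = macfc_v2(m, auc_threshold=1.0)
        main = macfc_main(m)
        assert v2.selected == main.selected
        assert v2.seed_set == []

    def test_perfect_gene_saturates(self):
        m = make_matrix({"g1": [3, 4, 1, 2], "g2": [2, 3, 1, 2]}, 2, 2)
        trace = macfc_v2(m, auc_threshold=0.9)
        assert trace.seed_set == ["g1"]
        assert trace.selected == ["g1"]   # coverage already complete
        assert trace.cumulative_mvauc[-1] == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        # 8x8 design: hi1 separates perfectly; hi2 has 3 of 64 pairs
        # inverted (AUC 61/64 ~ 0.953); lo overlaps heavily
        case = list(range(8))
        m = make_matrix({
            "hi1": [10.0] * 7 + [11.0] + [float(c) for c in case],
            "hi2": [10.0] * 7 + [4.5] + [float(c) for c in case],
            "lo": [float(c % 3) for c in case] +
                  [float((c + 1) % 3) for c in case],
        }, 8, 8)
        from balanceselect.mvauc_select import feature_auc as fa
        assert fa(m, "hi2").auc > 0.95 > fa(m, "lo").auc
        trace = macfc_v2(m, auc_threshold=0.95)
        assert set(trace.seed_set) == {"hi1", "hi2"}

    def test_cumulative_nondecreasing_with_seeds(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 10, 5, 5)
        trace = macfc_v2(m, auc_threshold=0.6)
        assert all(b >= a - 1e-12 for a, b in
                   zip(trace.cumulative_mvauc, trace.cumulative_mvauc[1:]))


class TestSklearnEstimator:
    def test_transform_selects_columns(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 8, 4, 4)
        sel = MvAUCSelector(max_features=3)
        Xt = sel.fit_transform(m.X, m.y)
        assert Xt.shape == (8, len(sel.selected_idx_))
        assert sel.get_support().sum() == len(sel.selected_idx_)

    def test_get_params_round_trip(self):
        sel = MvAUCSelector(variant="v2", max_features=7)
        params = sel.get_params()
        assert params["variant"] == "v2" and params["max_features"] == 7
        sel2 = MvAUCSelector(**params)
        assert sel2.get_params() == params
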