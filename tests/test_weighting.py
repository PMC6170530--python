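"""Entropy weights, AHP priorities and their multiplicative combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coupcoord import (
    ConsistencyError,
    IndexSystem,
    IndicatorMatrix,
    IndicatorSpec,
    PairwiseComparisonMatrix,
    WeightingError,
    ahp_priority,
    ahp_priority_geometric,
    combine_weights,
    consistent_pcm,
    entropy_weights,
)
from coupcoord.datasets import PINGSHUO_COMBINED_WEIGHTS, pingshuo_index


def _normalized(columns: dict[str, list[float]]) -> IndicatorMatrix:
    ids = tuple(columns)
    values = np.array(list(columns.values()), dtype=float).T
    plots = tuple(f"p{i}" for i in range(values.shape[0]))
    return IndicatorMatrix(plots, ids, values, scale="normalized")


class TestEntropyWeights:
    def test_maximal_variation_column_carries_all_information(self):
        e, w = entropy_weights(_normalized({"c": [0.0, 1.0]}), ["c"])
        assert e["c"] == pytest.approx(0.0, abs=1e-12)
        assert w["c"] == pytest.approx(1.0)

    def test_uniform_column_has_maximal_entropy(self):
        e, _ = entropy_weights(_normalized({"c": [0.5, 0.5]}), ["c"])
        assert e["c"] == pytest.approx(1.0, abs=1e-12)

    def test_weights_follow_one_minus_entropy(self):
        m = _normalized({"a": [0.0, 1.0], "b": [0.7, 0.7]})
        e, w = entropy_weights(m, ["a", "b"])
        assert (e["a"], e["b"]) == pytest.approx((0.0, 1.0), abs=1e-12)
        assert (w["a"], w["b"]) == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_zero_column_gets_zero_weight(self):
        m = _normalized({"a": [0.0, 0.0], "b": [0.0, 1.0]})
        e, w = entropy_weights(m, ["a", "b"])
        assert e["a"] == 1.0 and w["a"] == 0.0
        assert w["b"] == pytest.approx(1.0)

    def test_all_uninformative_falls_back_to_equal_weights(self, caplog):
        m = _normalized({"a": [0.3, 0.3], "b": [0.9, 0.9]})
        with caplog.at_level("WARNING"):
            _, w = entropy_weights(m, ["a", "b"])
        assert w == {"a": 0.5, "b": 0.5}
        assert "equal weights" in caplog.text

    def test_single_plot_is_an_error(self):
        m = IndicatorMatrix(("p0",), ("c",), np.array([[0.5]]), "normalized")
        with pytest.raises(WeightingError, match="2 plots"):
            entropy_weights(m, ["c"])

    def test_scale_invariance_of_two_plot_entropy(self):
        """For m=2, a column [0, t] has e = 0 for any t > 0: the
        proportions P are scale-free."""
        for t in (1e-6, 0.3, 1.0):
            e, _ = entropy_weights(_normalized({"c": [0.0, t]}), ["c"])
            assert e["c"] == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=3),
            min_size=2,
            max_size=4,
        )
    )
    def test_weights_sum_to_one_and_entropies_bounded(self, cols):
        ids = [f"c{i}" for i in range(len(cols))]
        m = _normalized(dict(zip(ids, cols)))
        e, w = entropy_weights(m, ids)
        assert all(0.0 <= ej <= 1.0 for ej in e.values())
        assert all(wj >= 0 for wj in w.values())
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)


class TestAhpPriority:
    def test_all_ones_matrix_is_indifference(self):
        pcm = PairwiseComparisonMatrix(("a", "b", "c"), np.ones((3, 3)))
        w, lam, ci, cr = ahp_priority(pcm)
        assert list(w.values()) == pytest.approx([1 / 3] * 3, abs=1e-12)
        assert lam == pytest.approx(3.0, abs=1e-9)
        assert cr == pytest.approx(0.0, abs=1e-9)

    def test_consistent_3x3_recovers_generating_weights(self):
        pcm = PairwiseComparisonMatrix(
            ("a", "b", "c"),
            np.array([[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1]]),
        )
        w, lam, ci, cr = ahp_priority(pcm)
        assert list(w.values()) == pytest.approx([4 / 7, 2 / 7, 1 / 7], abs=1e-8)
        assert cr == pytest.approx(0.0, abs=1e-9)

    def test_2x2_closed_form(self):
        pcm = PairwiseComparisonMatrix(("a", "b"), np.array([[1, 3], [1 / 3, 1]]))
        w, _, _, cr = ahp_priority(pcm)
        assert (w["a"], w["b"]) == pytest.approx((0.75, 0.25), abs=1e-10)
        assert cr == 0.0

    def test_matches_numpy_eigendecomposition(self):
        """Independent oracle: priorities equal the normalized Perron
        eigenvector from numpy.linalg.eig on an inconsistent matrix."""
        a = np.array([[1, 2, 5], [0.5, 1, 3], [0.2, 1 / 3, 1]])
        pcm = PairwiseComparisonMatrix(("a", "b", "c"), a)
        w, lam, _, _ = ahp_priority(pcm)
        eigvals, eigvecs = np.linalg.eig(a)
        k = np.argmax(eigvals.real)
        vec = np.abs(eigvecs[:, k].real)
        vec /= vec.sum()
        assert list(w.values()) == pytest.approx(list(vec), abs=1e-9)
        assert lam == pytest.approx(eigvals[k].real, abs=1e-9)

    def test_inconsistent_matrix_warns_by_default_raises_when_strict(self, caplog):
        # 1-9 scale intransitivity: a>b, b>c but c>a
        a = np.array([[1, 3, 1 / 3], [1 / 3, 1, 3], [3, 1 / 3, 1]])
        pcm = PairwiseComparisonMatrix(("a", "b", "c"), a)
        with caplog.at_level("WARNING"):
            _, _, _, cr = ahp_priority(pcm)
        assert cr > 0.1
        assert "consistency ratio" in caplog.text
        with pytest.raises(ConsistencyError):
            ahp_priority(pcm, strict=True)

    @pytest.mark.parametrize(
        "entries, match",
        [
            (np.array([[1.0, 2.0], [2.0, 1.0]]), "reciprocal"),
            (np.array([[2.0, 2.0], [0.5, 1.0]]), "diagonal"),
            (np.array([[1.0, -2.0], [-0.5, 1.0]]), "positive"),
        ],
    )
    def test_invalid_matrices_rejected(self, entries, match):
        with pytest.raises(WeightingError, match=match):
            PairwiseComparisonMatrix(("a", "b"), entries)

    def test_order_above_ri_table_rejected(self):
        k = 11
        with pytest.raises(WeightingError, match="order"):
            ahp_priority(consistent_pcm([f"i{j}" for j in range(k)], np.ones(k)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.05, 20.0, allow_nan=False), min_size=2, max_size=7)
    )
    def test_parameter_recovery_from_consistent_matrix(self, raw_w):
        """Any positive weight vector is recovered to 1e-8 from its
        consistent matrix a_ij = w_i/w_j, with CR = 0; geometric-mean
        priorities agree to 1e-6."""
        labels = [f"s{i}" for i in range(len(raw_w))]
        target = np.array(raw_w) / np.sum(raw_w)
        pcm = consistent_pcm(labels, raw_w)
        w, _, _, cr = ahp_priority(pcm)
        assert list(w.values()) == pytest.approx(list(target), abs=1e-8)
        assert cr == pytest.approx(0.0, abs=1e-8)
        g = ahp_priority_geometric(pcm)
        assert list(g.values()) == pytest.approx(list(w.values()), abs=1e-6)


class TestCombineWeights:
    def test_products_sum_to_one_per_system(self, toy_index):
        sub_w = {("vegetation", "tree"): 1.0, ("soil", "basic"): 1.0}
        ent_w = {"V1": 0.3, "V2": 0.7, "S1": 0.25, "S2": 0.75}
        ws = combine_weights(sub_w, ent_w, toy_index)
        assert ws.combined_weights["V1"] == pytest.approx(0.3)
        veg = ws.combined_weights["V1"] + ws.combined_weights["V2"]
        soil = ws.combined_weights["S1"] + ws.combined_weights["S2"]
        assert veg == pytest.approx(1.0) and soil == pytest.approx(1.0)

    def test_published_weight_blocks_recover_subsystem_shares(self):
        """Summing the published combined weights over each subsystem
        recovers the implied subsystem weights (the entropy layer sums
        to 1 within a subsystem, so the block sum is the AHP share)."""
        index = pingshuo_index()
        blocks = {}
        for system in index.systems:
            for sub in index.subsystems[system]:
                ids = [i.id for i in index.indicators_of_subsystem(system, sub)]
                blocks[sub] = sum(PINGSHUO_COMBINED_WEIGHTS[i] for i in ids)
        assert blocks["tree"] == pytest.approx(0.6739, abs=1e-9)
        assert blocks["herb"] == pytest.approx(0.2255, abs=1e-9)
        assert blocks["litter"] == pytest.approx(0.1007, abs=1e-9)
        assert blocks["basic"] == pytest.approx(0.2000, abs=1e-9)
        assert blocks["nutrient"] == pytest.approx(0.8001, abs=1e-9)
        veg = sum(PINGSHUO_COMBINED_WEIGHTS[f"X{i}"] for i in range(1, 10))
        soil = sum(PINGSHUO_COMBINED_WEIGHTS[f"X{i}"] for i in range(10, 19))
        assert veg == pytest.approx(1.0, abs=2e-4)
        assert soil == pytest.approx(1.0, abs=2e-4)

    def test_missing_factor_names_indicator(self, toy_index):
        sub_w = {("vegetation", "tree"): 1.0, ("soil", "basic"): 1.0}
        with pytest.raises(WeightingError, match="V2"):
            combine_weights(sub_w, {"V1": 1.0, "S1": 0.5, "S2": 0.5}, toy_index)

    def test_single_subsystem_identity(self):
        index = IndexSystem(
            systems=("s",),
            subsystems={"s": ("sub",)},
            indicators=(
                IndicatorSpec("a", "a", "s", "sub"),
                IndicatorSpec("b", "b", "s", "sub"),
            ),
        )
        ws = combine_weights({("s", "sub"): 1.0}, {"a": 0.6, "b": 0.4}, index)
        assert ws.combined_weights == {"a": 0.6, "b": 0.4}
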