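"""Unit and property tests for the TOPSIS evaluation core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from intercrop_eval import topsis
from intercrop_eval.topsis import (
    DecisionMatrix,
    Indicator,
    TopsisError,
    closeness,
    distances,
    entropy_weights,
    ideal_solutions,
    normalize_matrix,
    rank_by_closeness,
    run_topsis,
    transform_interval,
)

from _oracle import oracle_entropy_weights, oracle_interval_transform, oracle_topsis
from conftest import make_matrix, random_matrix


class TestIntervalTransform:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([6.0, 6.5, 6.8], [0.0, 0.5, 0.8]),     # hand-applied (x-6)/(7-6)
            ([5.5, 7.0, 6.0], [0.0, 1.0, 1/3]),     # min maps to 0, in-range to 1
            ([7.2, 7.9], [1.0, 1.0]),                # all inside the optimum
            ([8.5, 9.0], [0.5, 0.0]),                # symmetric above the range
        ],
    )
    def test_closed_forms(self, values, expected):
        out, _ = transform_interval(values, 7.0, 8.0)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_all_below_reduces_to_ph_formula(self):
        values = [5.2, 6.1, 6.9, 5.8]
        out, params = transform_interval(values, 7.0, 8.0)
        vmin = min(values)
        assert params.scale == pytest.approx(7.0 - vmin)
        np.testing.assert_allclose(out, (np.array(values) - vmin) / (7.0 - vmin))

    def test_all_equal_outside_has_positive_scale(self):
        out, params = transform_interval([5.0, 5.0], 7.0, 8.0)
        assert params.scale == pytest.approx(2.0)
        np.testing.assert_allclose(out, [0.0, 0.0])

    def test_empty_and_bad_bounds_error(self):
        with pytest.raises(TopsisError):
            transform_interval([], 7.0, 8.0)
        with pytest.raises(TopsisError):
            transform_interval([6.0], 8.0, 7.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=20))
    def test_output_in_unit_interval(self, values):
        out, _ = transform_interval(values, 7.0, 8.0)
        assert ((out >= -1e-12) & (out <= 1 + 1e-12)).all()
        for v, o in zip(values, out):
            if 7.0 <= v <= 8.0:
                assert o == 1.0

    def test_matches_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            values = rng.uniform(3, 11, size=rng.integers(1, 8)).tolist()
            out, _ = transform_interval(values, 7.0, 8.0)
            np.testing.assert_allclose(out, oracle_interval_transform(values, 7.0, 8.0),
                                       atol=1e-12)


class TestNormalize:
    def test_vector_column(self):
        m = make_matrix([[3.0], [4.0]])
        out = normalize_matrix(m, "vector")
        np.testing.assert_allclose(out.values["c0"], [0.6, 0.8])

    def test_vector_idempotent_on_unit_columns(self):
        m = make_matrix([[0.6], [0.8]])
        out = normalize_matrix(m, "vector")
        np.testing.assert_allclose(out.values["c0"], [0.6, 0.8])

    def test_minmax_benefit_and_cost(self):
        m = make_matrix([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]], ["benefit", "cost"])
        out = normalize_matrix(m, "minmax")
        np.testing.assert_allclose(out.values["c0"], [0, 0.5, 1])
        np.testing.assert_allclose(out.values["c1"], [1, 0.5, 0])
        assert all(ind.direction == "benefit" for ind in out.indicators)

    def test_degenerate_columns_error(self):
        with pytest.raises(TopsisError, match="c0"):
            normalize_matrix(make_matrix([[0.0], [0.0]]), "vector")
        with pytest.raises(TopsisError, match="c0"):
            normalize_matrix(make_matrix([[2.0], [2.0]]), "minmax")


class TestIdealsAndDistances:
    def test_benefit_ideals(self):
        m = make_matrix([[0.6, 0.2], [0.3, 0.4]])
        pos, neg = ideal_solutions(m)
        np.testing.assert_allclose(pos, [0.6, 0.4])
        np.testing.assert_allclose(neg, [0.3, 0.2])

    def test_cost_column_flips(self):
        m = make_matrix([[0.1], [0.5]], ["cost"])
        pos, neg = ideal_solutions(m)
        assert pos[0] == 0.1 and neg[0] == 0.5

    def test_euclidean_distances(self):
        m = make_matrix([[0.6, 0.2], [0.3, 0.4]])
        pos, neg = ideal_solutions(m)
        d_plus, d_minus = distances(m, pos, neg)
        np.testing.assert_allclose(d_plus, [0.2, 0.3])
        # row at the ideal in one coordinate still has d_minus from the other
        assert (d_plus >= 0).all() and (d_minus >= 0).all()

    def test_one_dimensional_reduces_to_abs(self):
        m = make_matrix([[0.2], [0.9]])
        pos, neg = ideal_solutions(m)
        d_plus, d_minus = distances(m, pos, neg)
        np.testing.assert_allclose(d_plus, [0.7, 0.0])
        np.testing.assert_allclose(d_minus, [0.0, 0.7])


class TestCloseness:
    def test_definition(self):
        assert closeness(0.3, 0.1) == pytest.approx(0.25)

    def test_at_positive_ideal(self):
        assert closeness(0.0, 0.5) == 1.0

    def test_both_zero_errors(self):
        with pytest.raises(TopsisError, match="undefined"):
            closeness(0.0, 0.0)


class TestRank:
    def test_strictly_ordered(self):
        np.testing.assert_array_equal(rank_by_closeness([0.821, 0.625, 0.357]), [1, 2, 3])

    def test_all_equal_stable_order(self):
        np.testing.assert_array_equal(rank_by_closeness([0.4, 0.4, 0.4]), [1, 2, 3])

    def test_ties_keep_input_order(self):
        np.testing.assert_array_equal(rank_by_closeness([0.2, 0.5, 0.5]), [3, 1, 2])


class TestEntropyWeights:
    def test_constant_column_gets_zero(self):
        m = make_matrix([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        np.testing.assert_allclose(entropy_weights(m), [1.0, 0.0])

    def test_all_constant_errors(self):
        with pytest.raises(TopsisError):
            entropy_weights(make_matrix([[1.0], [1.0]]))

    def test_matches_independent_formula(self):
        rows = [[1.0, 2.0], [2.0, 2.0], [3.0, 4.0]]
        m = make_matrix(rows, ["benefit", "cost"])
        np.testing.assert_allclose(
            entropy_weights(m), oracle_entropy_weights(rows, ["benefit", "cost"]),
            atol=1e-12,
        )

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m, *_ = random_matrix(rng)
            assert entropy_weights(m).sum() == pytest.approx(1.0)


class TestRunTopsis:
    def test_dominance_chain(self):
        """Rows (1,1) < (2,2) < (3,3) on equal-weight benefit indicators."""
        m = make_matrix([[1, 1], [2, 2], [3, 3]])
        res = run_topsis(m)
        assert res.closeness[0] < res.closeness[1] < res.closeness[2]
        np.testing.assert_array_equal(res.rank, [3, 2, 1])

    def test_identical_rows_error(self):
        m = make_matrix([[2, 3], [2, 3]])
        with pytest.raises(TopsisError, match="closeness"):
            run_topsis(m)

    def test_single_indicator_weight_orders_by_column(self):
        rows = [[5, 9], [8, 1], [2, 7], [6, 3]]
        m = make_matrix(rows)
        res = run_topsis(m, weights=[1.0, 0.0])
        col = np.array(rows)[:, 0]
        np.testing.assert_array_equal(res.rank, rank_by_closeness(col))

    def test_weight_mapping_and_missing_weight(self):
        m = make_matrix([[1, 2], [3, 4]])
        res = run_topsis(m, weights={"c0": 1.0, "c1": 1.0})
        assert res.closeness.shape == (2,)
        with pytest.raises(TopsisError, match="c1"):
            run_topsis(m, weights={"c0": 1.0})

    def test_stage_named_in_errors(self):
        with pytest.raises(TopsisError, match="normalization"):
            run_topsis(make_matrix([[0, 1], [0, 2]]))

    def test_interval_column_handled(self):
        m = make_matrix([[6.0, 10.0], [6.5, 20.0], [7.5, 30.0]],
                        ["interval", "benefit"], intervals={0: (7.0, 8.0)})
        res = run_topsis(m)
        # row 3 is inside the pH optimum and best on the benefit column
        assert res.rank[2] == 1

    def test_result_invariants(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            m, *_ = random_matrix(rng, allow_interval=True)
            try:
                res = run_topsis(m)
            except TopsisError:
                continue
            assert ((res.closeness >= 0) & (res.closeness <= 1)).all()
            assert sorted(res.rank) == list(range(1, len(res.treatments) + 1))
            np.testing.assert_allclose(
                res.closeness, res.d_minus / (res.d_plus + res.d_minus))


class TestProperties:
    def test_oracle_equivalence(self):
        """run_topsis agrees with the straight-line brute-force oracle."""
        rng = np.random.default_rng(2024)
        for norm in ("vector", "minmax"):
            for _ in range(100):
                m, rows, directions, weights, intervals = random_matrix(
                    rng, allow_interval=True)
                try:
                    res = run_topsis(m, normalization=norm)
                except TopsisError:
                    continue
                dp, dm, c, ranks = oracle_topsis(
                    rows.tolist(), directions, weights, norm, intervals)
                np.testing.assert_allclose(res.d_plus, dp, atol=1e-12)
                np.testing.assert_allclose(res.d_minus, dm, atol=1e-12)
                np.testing.assert_allclose(res.closeness, c, atol=1e-12)
                np.testing.assert_array_equal(res.rank, ranks)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        m, rows, directions, weights, _ = random_matrix(rng)
        res = run_topsis(m)
        perm = rng.permutation(len(rows))
        m2 = make_matrix(rows[perm], directions, weights,
                         labels=[f"t{i}" for i in perm])
        res2 = run_topsis(m2)
        by_label = dict(zip(res.treatments, res.closeness))
        by_label2 = dict(zip(res2.treatments, res2.closeness))
        for label in by_label:
            assert by_label[label] == pytest.approx(by_label2[label], abs=1e-12)
        rank1 = dict(zip(res.treatments, res.rank))
        rank2 = dict(zip(res2.treatments, res2.rank))
        assert rank1 == rank2

    def test_scale_invariance_under_vector_normalization(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            m, rows, directions, weights, _ = random_matrix(rng)
            res = run_topsis(m)
            scaled = rows.copy()
            j = int(rng.integers(0, rows.shape[1]))
            scaled[:, j] *= float(rng.uniform(0.1, 50))
            res2 = run_topsis(make_matrix(scaled, directions, weights))
            np.testing.assert_allclose(res.closeness, res2.closeness, atol=1e-10)

    def test_monotonicity_in_benefit_entry(self):
        """On a fixed weighted matrix, bumping one benefit entry (within
        column bounds) cannot decrease that alternative's closeness."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            n, m_ = 4, 3
            W = rng.uniform(0.0, 1.0, size=(n, m_))
            mat = make_matrix(W)
            pos, neg = ideal_solutions(mat)
            d_plus, d_minus = distances(mat, pos, neg)
            i = int(rng.integers(0, n))
            j = int(rng.integers(0, m_))
            c0 = closeness(d_plus[i], d_minus[i])
            W2 = W.copy()
            W2[i, j] = rng.uniform(W[i, j], W[:, j].max())
            mat2 = make_matrix(W2)
            pos2, neg2 = ideal_solutions(mat2)
            dp2, dm2 = distances(mat2, pos2, neg2)
            assert closeness(dp2[i], dm2[i]) >= c0 - 1e-12


class TestDecisionMatrixValidation:
    def test_rejects_nan_and_small_matrices(self):
        with pytest.raises(TopsisError):
            make_matrix([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(TopsisError):
            make_matrix([[1.0, 2.0]])

    def test_rejects_duplicate_labels(self):
        with pytest.raises(TopsisError):
            make_matrix([[1.0], [2.0]], labels=["a", "a"])

    def test_interval_requires_bounds(self):
        with pytest.raises(TopsisError):
            Indicator("x", "interval")
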