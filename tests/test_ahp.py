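"""AHP weighting: aggregation, row-geometric-mean weights, consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from htaprio.ahp import (
    SAATY_RANDOM_INDEX,
    ConsistencyReport,
    CriterionWeightVector,
    PairwiseComparisonMatrix,
    aggregate_expert_matrices,
    check_consistency,
    derive_weights,
    estimate_lambda_max,
    inconsistency_index,
    inconsistency_ratio,
)
from htaprio.errors import (
    ConfigurationError,
    DegenerateInputError,
    InvalidInputError,
)
from htaprio.synthetic import consistent_matrix

from conftest import random_reciprocal_matrix


def pcm(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"c{i}" for i in range(values.shape[0]))
    return PairwiseComparisonMatrix(labels, values)


def power_iteration_eigenvalue(a, iters=2000):
    """Independent dominant-eigenvalue oracle (plain power iteration)."""
    n = a.shape[0]
    x = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(iters):
        y = a @ x
        lam = float(np.linalg.norm(y))
        x = y / lam
    return float((x @ a @ x) / (x @ x))


positive_weights = st.lists(
    st.floats(min_value=0.05, max_value=1.0), min_size=2, max_size=7
).map(lambda ws: np.array(ws) / np.sum(ws))


class TestMatrixValidation:
    def test_rejects_non_reciprocal(self):
        with pytest.raises(InvalidInputError, match="reciprocal"):
            pcm([[1, 2], [0.4, 1]])

    def test_rejects_non_positive_entries(self):
        with pytest.raises(InvalidInputError):
            pcm([[1, -2], [-0.5, 1]])

    def test_rejects_bad_diagonal(self):
        with pytest.raises(InvalidInputError):
            pcm([[2, 1], [1, 0.5]])

    def test_repair_restores_reciprocity(self):
        repaired = PairwiseComparisonMatrix.repaired(("a", "b"), [[1, 2], [0.4, 1]])
        g = np.sqrt(2 / 0.4) * 2
        assert repaired.values[0, 1] == pytest.approx(g)
        assert repaired.values[1, 0] == pytest.approx(1 / g)


class TestAggregation:
    def test_single_matrix_unchanged(self):
        m = pcm([[1, 3], [1 / 3, 1]])
        agg = aggregate_expert_matrices([m])
        np.testing.assert_allclose(agg.values, m.values)

    def test_geometric_mean_of_entries(self):
        m1 = pcm([[1, 2], [0.5, 1]])
        m2 = pcm([[1, 8], [0.125, 1]])
        agg = aggregate_expert_matrices([m1, m2])
        assert agg.values[0, 1] == pytest.approx(4.0)  # sqrt(2 * 8)
        assert agg.values[1, 0] == pytest.approx(0.25)

    def test_idempotent_on_copies(self):
        m = pcm([[1, 5, 0.5], [0.2, 1, 3], [2, 1 / 3, 1]])
        agg = aggregate_expert_matrices([m] * 4)
        np.testing.assert_allclose(agg.values, m.values, rtol=1e-12)

    def test_label_mismatch_rejected(self):
        m1 = pcm([[1, 2], [0.5, 1]], labels=("a", "b"))
        m2 = pcm([[1, 2], [0.5, 1]], labels=("b", "a"))
        with pytest.raises(InvalidInputError, match="labels"):
            aggregate_expert_matrices([m1, m2])

    def test_empty_panel_rejected(self):
        with pytest.raises(InvalidInputError):
            aggregate_expert_matrices([])

    def test_aggregate_preserves_reciprocity_on_random_panels(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            panel = [pcm(random_reciprocal_matrix(5, rng)) for _ in range(4)]
            agg = aggregate_expert_matrices(panel)
            assert np.all(agg.values > 0)
            np.testing.assert_allclose(agg.values * agg.values.T, 1.0, atol=1e-12)


class TestWeights:
    def test_all_ones_gives_equal_weights(self):
        w = derive_weights(pcm(np.ones((4, 4))))
        np.testing.assert_allclose(w.values, 0.25)

    def test_two_by_two(self):
        w = derive_weights(pcm([[1, 4], [0.25, 1]]))
        np.testing.assert_allclose(w.values, [0.8, 0.2])

    def test_recovers_generating_weights(self):
        truth = np.array([0.5, 0.3, 0.2])
        m = consistent_matrix(CriterionWeightVector(("a", "b", "c"), truth))
        np.testing.assert_allclose(derive_weights(m).values, truth, atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(positive_weights)
    def test_consistent_matrix_recovery_property(self, truth):
        labels = tuple(f"c{i}" for i in range(truth.size))
        m = consistent_matrix(CriterionWeightVector(labels, truth))
        w = derive_weights(m)
        np.testing.assert_allclose(w.values, truth, atol=1e-12)
        assert estimate_lambda_max(m, w) == pytest.approx(truth.size, abs=1e-9)
        assert check_consistency(m, w).ir == pytest.approx(0.0, abs=1e-9)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(11)
        for n in (3, 5, 8):
            w = derive_weights(pcm(random_reciprocal_matrix(n, rng)))
            assert abs(w.values.sum() - 1.0) < 1e-12

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        m = pcm(random_reciprocal_matrix(5, rng))
        w = derive_weights(m)
        perm = rng.permutation(5)
        w_perm = derive_weights(m.permuted(perm))
        np.testing.assert_allclose(w_perm.values, w.values[perm], rtol=1e-12)

    def test_aggregation_commutes_with_weighting(self):
        # row-geometric-mean AHP: weights of the aggregate equal the
        # normalized geometric mean of per-expert weight vectors
        rng = np.random.default_rng(21)
        for _ in range(5):
            panel = [pcm(random_reciprocal_matrix(4, rng)) for _ in range(6)]
            via_aggregate = derive_weights(aggregate_expert_matrices(panel))
            logw = np.mean([np.log(derive_weights(m).values) for m in panel], axis=0)
            gm = np.exp(logw)
            np.testing.assert_allclose(
                via_aggregate.values, gm / gm.sum(), rtol=1e-10
            )


class TestLambdaMax:
    def test_consistent_matrix_gives_n(self):
        for n in (2, 4, 6):
            rng = np.random.default_rng(n)
            truth = rng.dirichlet(np.ones(n))
            labels = tuple(f"c{i}" for i in range(n))
            m = consistent_matrix(CriterionWeightVector(labels, truth))
            assert estimate_lambda_max(m, derive_weights(m)) == pytest.approx(n, abs=1e-9)

    def test_all_ones_four_by_four(self):
        m = pcm(np.ones((4, 4)))
        assert estimate_lambda_max(m, derive_weights(m)) == pytest.approx(4.0)

    def test_agrees_with_power_iteration_oracle(self):
        m = pcm([[1, 2, 4], [0.5, 1, 3], [0.25, 1 / 3, 1]])
        approx = estimate_lambda_max(m, derive_weights(m))
        assert approx == pytest.approx(power_iteration_eigenvalue(m.values), abs=0.01)

    def test_saaty_lower_bound_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(3, 8))
            m = pcm(random_reciprocal_matrix(n, rng))
            assert estimate_lambda_max(m, derive_weights(m)) >= n - 1e-9


class TestConsistency:
    @pytest.mark.parametrize(
        "lam, n, expected",
        [(3.0, 3, 0.0), (3.12, 3, 0.06), (9.24, 9, 0.03)],
    )
    def test_inconsistency_index(self, lam, n, expected):
        assert inconsistency_index(lam, n) == pytest.approx(expected)

    def test_index_defined_zero_below_two(self):
        assert inconsistency_index(1.0, 1) == 0.0

    def test_zero_index_acceptable(self):
        rep = inconsistency_ratio(0.0, 5)
        assert rep.ir == 0.0 and rep.acceptable

    def test_point_zero_three_is_acceptable(self):
        rep = inconsistency_ratio(0.03 * SAATY_RANDOM_INDEX[9], 9)
        assert rep.ir == pytest.approx(0.03, abs=1e-12)
        assert rep.acceptable

    def test_ratio_above_gate_rejected(self):
        rep = inconsistency_ratio(0.06, 3)
        assert rep.ir == pytest.approx(0.06 / 0.58)
        assert not rep.acceptable

    def test_small_matrices_always_consistent(self):
        assert inconsistency_ratio(0.0, 2).acceptable
        assert inconsistency_ratio(0.0, 1).ir == 0.0

    def test_missing_random_index_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            inconsistency_ratio(0.02, 14)

    def test_zero_weight_degenerate(self):
        m = pcm(np.ones((3, 3)))
        w = CriterionWeightVector.__new__(CriterionWeightVector)
        object.__setattr__(w, "labels", m.labels)
        object.__setattr__(w, "values", np.array([0.5, 0.5, 0.0]))
        with pytest.raises(DegenerateInputError):
            estimate_lambda_max(m, w)

    def test_full_report_on_inconsistent_matrix(self):
        m = pcm([[1, 9, 1 / 9], [1 / 9, 1, 9], [9, 1 / 9, 1]])
        rep = check_consistency(m)
        assert isinstance(rep, ConsistencyReport)
        assert rep.lambda_max > 3 and rep.ir > 0.1 and not rep.acceptable
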