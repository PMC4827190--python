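"""Group criterion weighting by the analytic hierarchy process (AHP).

Expert judgments arrive as positive reciprocal pairwise-comparison matrices
on the Saaty scale (1-9 and reciprocals; arbitrary positive reals are
accepted).  The group matrix is the element-wise geometric mean of the
expert matrices.  Weights come from the row-geometric-mean approximation:
the geometric mean of each row, normalized to sum to one.  Coherence of the
judgments is checked through an estimate of the principal eigenvalue
``lambda_max`` (mean of the element-wise ratios of A.w to w), the
inconsistency index ``II = (lambda_max - n) / (n - 1)`` and the
inconsistency ratio ``IR = II / RI(n)`` against Saaty's random index; a
matrix is acceptably consistent when ``IR <= 0.1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, InvalidInputError

__all__ = [
    "SAATY_RANDOM_INDEX",
    "PairwiseComparisonMatrix",
    "CriterionWeightVector",
    "ConsistencyReport",
    "aggregate_expert_matrices",
    "derive_weights",
    "estimate_lambda_max",
    "inconsistency_index",
    "inconsistency_ratio",
    "check_consistency",
]

#: Saaty's random inconsistency index for random reciprocal matrices of
#: dimension 1..10; overridable wherever a ``random_index_table`` is accepted.
SAATY_RANDOM_INDEX: Mapping[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
}

#: Acceptability threshold for the inconsistency ratio.
IR_ACCEPTABLE_MAX = 0.1

_RECIPROCITY_ATOL = 1e-9


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """A positive reciprocal judgment matrix over ordered criteria.

    Parameters
    ----------
    labels
        Ordered criterion identifiers (length n).
    values
        n x n array of positive comparison ratios; ``values[i, j]`` expresses
        how much more important criterion i is than criterion j.  The
        diagonal must be 1 and ``values[j, i]`` must equal
        ``1 / values[i, j]`` within 1e-9 on their product.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        n = len(self.labels)
        if vals.ndim != 2 or vals.shape != (n, n):
            raise InvalidInputError(
                f"expected a {n}x{n} matrix matching {n} labels, got shape {vals.shape}"
            )
        if n == 0:
            raise InvalidInputError("matrix must have at least one criterion")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise InvalidInputError("all pairwise entries must be finite and > 0")
        if not np.allclose(np.diag(vals), 1.0, atol=_RECIPROCITY_ATOL):
            raise InvalidInputError("diagonal entries must all equal 1")
        if not np.allclose(vals * vals.T, 1.0, atol=_RECIPROCITY_ATOL):
            i, j = np.unravel_index(
                np.argmax(np.abs(vals * vals.T - 1.0)), vals.shape
            )
            raise InvalidInputError(
                f"matrix is not reciprocal: a[{i},{j}]*a[{j},{i}] = "
                f"{vals[i, j] * vals[j, i]:.6g} != 1"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairwiseComparisonMatrix":
        if list(df.index) != list(df.columns):
            raise InvalidInputError(
                "pairwise matrix must have identical row and column labels"
            )
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def repaired(
        cls, labels: Sequence[str], values: np.ndarray
    ) -> "PairwiseComparisonMatrix":
        """Build a matrix after repairing mild reciprocity violations.

        Each upper/lower pair (a_ij, a_ji) is replaced by (g, 1/g) with
        ``g = sqrt(a_ij / a_ji) * a_ij`` -- the geometric compromise the
        ``--repair-reciprocal`` command-line flag applies.  The diagonal is
        reset to 1.  Entries must still be positive.
        """
        vals = np.asarray(values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise InvalidInputError("repair requires a square matrix")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise InvalidInputError("all pairwise entries must be finite and > 0")
        out = vals.copy()
        n = vals.shape[0]
        for i in range(n):
            out[i, i] = 1.0
            for j in range(i + 1, n):
                g = math.sqrt(vals[i, j] / vals[j, i]) * vals[i, j]
                out[i, j] = g
                out[j, i] = 1.0 / g
        return cls(tuple(labels), out)

    def permuted(self, order: Sequence[int]) -> "PairwiseComparisonMatrix":
        """Return the matrix with criteria reordered by ``order``."""
        idx = np.asarray(order)
        return PairwiseComparisonMatrix(
            tuple(self.labels[i] for i in idx), self.values[np.ix_(idx, idx)]
        )


@dataclass(frozen=True)
class CriterionWeightVector:
    """Relative criterion weights.

    ``derive_weights`` always returns a vector normalized to sum to one
    (within 1e-12).  Externally supplied vectors (e.g. published weights
    rounded to two decimals) are accepted as long as every weight is
    positive and finite; use :meth:`is_normalized` to check, or
    :meth:`normalized` to rescale.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if vals.ndim != 1 or vals.shape[0] != len(self.labels):
            raise InvalidInputError("weight vector length must match labels")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise InvalidInputError("all weights must be finite and > 0")

    @property
    def n(self) -> int:
        return len(self.labels)

    def is_normalized(self, tol: float = 1e-12) -> bool:
        return abs(float(self.values.sum()) - 1.0) <= tol

    def normalized(self) -> "CriterionWeightVector":
        return CriterionWeightVector(self.labels, self.values / self.values.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.labels, name="weight")


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics for one pairwise matrix."""

    n: int
    lambda_max: float
    ii: float
    ir: float
    random_index: float
    acceptable: bool

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "lambda_max": self.lambda_max,
            "inconsistency_index": self.ii,
            "inconsistency_ratio": self.ir,
            "random_index": self.random_index,
            "acceptable": self.acceptable,
        }


def aggregate_expert_matrices(
    matrices: Sequence[PairwiseComparisonMatrix],
) -> PairwiseComparisonMatrix:
    """Element-wise geometric mean of the expert matrices.

    The result is reciprocal by construction (the geometric mean of
    reciprocal pairs is a reciprocal pair).
    """
    if len(matrices) == 0:
        raise InvalidInputError("at least one expert matrix is required")
    first = matrices[0]
    for k, m in enumerate(matrices[1:], start=2):
        if m.labels != first.labels:
            raise InvalidInputError(
                f"expert matrix {k} has labels {m.labels}, expected {first.labels}"
            )
    logs = np.mean([np.log(m.values) for m in matrices], axis=0)
    agg = np.exp(logs)
    # symmetrize exactly against floating-point drift in exp/log
    iu = np.triu_indices(first.n, 1)
    agg[(iu[1], iu[0])] = 1.0 / agg[iu]
    np.fill_diagonal(agg, 1.0)
    return PairwiseComparisonMatrix(first.labels, agg)


def derive_weights(matrix: PairwiseComparisonMatrix) -> CriterionWeightVector:
    """Row-geometric-mean weights, normalized to sum to one."""
    gm = np.exp(np.mean(np.log(matrix.values), axis=1))
    w = gm / gm.sum()
    return CriterionWeightVector(matrix.labels, w)


def estimate_lambda_max(
    matrix: PairwiseComparisonMatrix, weights: CriterionWeightVector
) -> float:
    """Approximate principal eigenvalue: mean of (A.w)_i / w_i."""
    if matrix.labels != weights.labels:
        raise InvalidInputError("matrix and weight labels must match")
    w = weights.values
    if np.any(w == 0):
        raise DegenerateInputError("cannot estimate lambda_max with a zero weight")
    return float(np.mean((matrix.values @ w) / w))


def inconsistency_index(lambda_max: float, n: int) -> float:
    """(lambda_max - n) / (n - 1); defined as 0 for n < 2 (always consistent)."""
    if n < 2:
        return 0.0
    return (lambda_max - n) / (n - 1)


def inconsistency_ratio(
    ii: float,
    n: int,
    random_index_table: Mapping[int, float] | None = None,
) -> "ConsistencyReport":
    """Ratio of the inconsistency index to the random index for dimension n.

    A 1x1 or reciprocal 2x2 matrix is always consistent, so ``ir = 0`` there
    rather than dividing by a zero random index.
    """
    table = SAATY_RANDOM_INDEX if random_index_table is None else random_index_table
    if n <= 2:
        ri = float(table.get(n, 0.0))
        ir = 0.0
    else:
        if n not in table or float(table[n]) == 0.0:
            raise ConfigurationError(
                f"no random index available for matrix dimension {n}"
            )
        ri = float(table[n])
        ir = ii / ri
    lambda_max = ii * (n - 1) + n if n >= 2 else 1.0
    return ConsistencyReport(
        n=n,
        lambda_max=lambda_max,
        ii=ii,
        ir=ir,
        random_index=ri,
        acceptable=ir <= IR_ACCEPTABLE_MAX,
    )


def check_consistency(
    matrix: PairwiseComparisonMatrix,
    weights: CriterionWeightVector | None = None,
    random_index_table: Mapping[int, float] | None = None,
) -> ConsistencyReport:
    """Full consistency check of a matrix (deriving weights if not given)."""
    if weights is None:
        weights = derive_weights(matrix)
    lam = estimate_lambda_max(matrix, weights)
    ii = inconsistency_index(lam, matrix.n)
    report = inconsistency_ratio(ii, matrix.n, random_index_table)
    # keep the directly estimated lambda_max rather than the re-derived one
    return ConsistencyReport(
        n=report.n,
        lambda_max=lam,
        ii=ii,
        ir=report.ir,
        random_index=report.random_index,
        acceptable=report.acceptable,
    )
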