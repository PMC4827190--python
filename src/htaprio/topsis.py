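"""TOPSIS: ranking by similarity to the ideal solution.

The pipeline takes an alternatives x criteria decision matrix, vector-
normalizes each column to unit Euclidean norm, scales columns by the
criterion weights, finds the positive ideal (column-best) and negative
ideal (column-worst) profiles, measures each alternative's Euclidean
separation from both, and ranks by the relative closeness
``cl = d- / (d+ + d-)`` in descending order.  For benefit criteria the
ideal is the column maximum; for cost criteria the minimum.  All
computation is carried at full floating-point precision; rounding happens
only in the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ahp import CriterionWeightVector
from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "DecisionMatrix",
    "NormalizedMatrix",
    "WeightedMatrix",
    "IdealPair",
    "ClosenessRanking",
    "TopsisResult",
    "vector_normalize",
    "apply_weights",
    "compute_ideals",
    "separation",
    "closeness",
    "rank_descending",
    "topsis",
]

BENEFIT = "benefit"
COST = "cost"


def _validate_directions(directions: Sequence[str] | None, n: int) -> tuple[str, ...]:
    if directions is None:
        return (BENEFIT,) * n
    dirs = tuple(str(d).lower() for d in directions)
    if len(dirs) != n:
        raise InvalidInputError(f"expected {n} criterion directions, got {len(dirs)}")
    bad = [d for d in dirs if d not in (BENEFIT, COST)]
    if bad:
        raise InvalidInputError(f"unknown criterion direction(s): {sorted(set(bad))}")
    return dirs


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria score matrix (non-negative reals).

    In the shipped pipeline the scores are the integer 1-5 codes produced by
    the evidence rubrics, but any non-negative reals are accepted.
    """

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "alternatives", tuple(str(a) for a in self.alternatives))
        object.__setattr__(self, "criteria", tuple(str(c) for c in self.criteria))
        m, n = len(self.alternatives), len(self.criteria)
        if n < 1:
            raise InvalidInputError("decision matrix needs >= 1 criterion")
        if vals.shape != (m, n):
            raise InvalidInputError(
                f"scores shape {vals.shape} does not match {m} alternatives x {n} criteria"
            )
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise InvalidInputError("scores must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DecisionMatrix":
        return cls(
            tuple(str(i) for i in df.index),
            tuple(str(c) for c in df.columns),
            df.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.alternatives, columns=self.criteria)


@dataclass(frozen=True)
class NormalizedMatrix:
    """Column-wise unit-Euclidean-norm version of a decision matrix."""

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.alternatives, columns=self.criteria)


@dataclass(frozen=True)
class WeightedMatrix:
    """Normalized matrix with each column scaled by its criterion weight."""

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.alternatives, columns=self.criteria)


@dataclass(frozen=True)
class IdealPair:
    """Positive (A+) and negative (A-) ideal profiles in weighted space."""

    criteria: tuple[str, ...]
    a_plus: np.ndarray = field(repr=False)
    a_minus: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ClosenessRanking:
    """Per-alternative separations, relative closeness, and ordinal rank."""

    alternatives: tuple[str, ...]
    d_plus: np.ndarray = field(repr=False)
    d_minus: np.ndarray = field(repr=False)
    cl: np.ndarray = field(repr=False)
    ranks: np.ndarray = field(repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_plus": self.d_plus,
                "d_minus": self.d_minus,
                "closeness": self.cl,
                "rank": self.ranks,
            },
            index=self.alternatives,
        )


def vector_normalize(matrix: DecisionMatrix) -> NormalizedMatrix:
    """n_ij = r_ij / sqrt(sum_i r_ij^2), column-wise."""
    if matrix.shape[0] < 1:
        raise InvalidInputError("cannot normalize a matrix with no alternatives")
    norms = np.sqrt((matrix.values**2).sum(axis=0))
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        names = [matrix.criteria[j] for j in zero]
        raise DegenerateInputError(
            f"criterion column(s) entirely zero, cannot normalize: {names}"
        )
    return NormalizedMatrix(matrix.alternatives, matrix.criteria, matrix.values / norms)


def apply_weights(
    norm: NormalizedMatrix, weights: CriterionWeightVector
) -> WeightedMatrix:
    """v_ij = n_ij * w_j.  Weights are used as supplied (not re-normalized)."""
    if weights.labels != norm.criteria:
        if len(weights.labels) != len(norm.criteria):
            raise InvalidInputError(
                f"{len(weights.labels)} weights for {len(norm.criteria)} criteria"
            )
        raise InvalidInputError(
            f"weight labels {weights.labels} do not match criteria {norm.criteria}"
        )
    return WeightedMatrix(norm.alternatives, norm.criteria, norm.values * weights.values)


def compute_ideals(
    v: WeightedMatrix, directions: Sequence[str] | None = None
) -> IdealPair:
    """Column-wise best (A+) and worst (A-) weighted scores.

    Benefit criteria take max as ideal / min as negative ideal; cost
    criteria the reverse.  With no directions given all criteria are
    treated as benefit-type, which is how the shipped coding rubrics are
    oriented (every table maps "more priority" to a higher code).
    """
    dirs = _validate_directions(directions, len(v.criteria))
    col_max = v.values.max(axis=0)
    col_min = v.values.min(axis=0)
    is_benefit = np.array([d == BENEFIT for d in dirs])
    a_plus = np.where(is_benefit, col_max, col_min)
    a_minus = np.where(is_benefit, col_min, col_max)
    return IdealPair(v.criteria, a_plus, a_minus)


def separation(v: WeightedMatrix, ideals: IdealPair) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance of each alternative from A+ and from A-."""
    if ideals.criteria != v.criteria:
        raise InvalidInputError("ideal profiles do not match the weighted matrix criteria")
    d_plus = np.sqrt(((v.values - ideals.a_plus) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v.values - ideals.a_minus) ** 2).sum(axis=1))
    return d_plus, d_minus


def closeness(d_plus: np.ndarray, d_minus: np.ndarray) -> np.ndarray:
    """Relative closeness cl = d- / (d+ + d-), in [0, 1].

    Undefined when d+ = d- = 0, which happens only when every alternative is
    identical (the profile coincides with both ideals).
    """
    d_plus = np.asarray(d_plus, dtype=float)
    d_minus = np.asarray(d_minus, dtype=float)
    total = d_plus + d_minus
    if np.any(total == 0.0):
        raise DegenerateInputError(
            "relative closeness undefined: an alternative coincides with both "
            "ideals (all alternatives are identical)"
        )
    return d_minus / total

def rank_descending(cl: np.ndarray) -> np.ndarray:
    """1-based ranks, largest closeness first; ties keep input order (stable)."""
    cl = np.asarray(cl, dtype=float)
    if cl.size < 1:
        raise InvalidInputError("need at least one alternative to rank")
    order = np.argsort(-cl, kind="stable")
    ranks = np.empty(cl.size, dtype=int)
    ranks[order] = np.arange(1, cl.size + 1)
    return ranks


@dataclass(frozen=True)
class TopsisResult:
    """Every intermediate and final product of one TOPSIS run."""

    decision: DecisionMatrix
    weights: CriterionWeightVector
    directions: tuple[str, ...]
    normalized: NormalizedMatrix
    weighted: WeightedMatrix
    ideals: IdealPair
    ranking: ClosenessRanking

    def rounded(self, digits: int = 2) -> dict:
        """Report-layer rounding (the published tables print two decimals)."""
        r = self.ranking
        return {
            "normalized": np.round(self.normalized.values, digits).tolist(),
            "weighted": np.round(self.weighted.values, digits).tolist(),
            "a_plus": np.round(self.ideals.a_plus, digits).tolist(),
            "a_minus": np.round(self.ideals.a_minus, digits).tolist(),
            "d_plus": np.round(r.d_plus, digits).tolist(),
            "d_minus": np.round(r.d_minus, digits).tolist(),
            "closeness": np.round(r.cl, digits).tolist(),
            "ranks": r.ranks.tolist(),
        }


def topsis(
    matrix: DecisionMatrix,
    weights: CriterionWeightVector,
    directions: Sequence[str] | None = None,
) -> TopsisResult:
    """Run the full six-step pipeline on a decision matrix."""
    dirs = _validate_directions(directions, len(matrix.criteria))
    norm = vector_normalize(matrix)
    weighted = apply_weights(norm, weights)
    ideals = compute_ideals(weighted, dirs)
    d_plus, d_minus = separation(weighted, ideals)
    cl = closeness(d_plus, d_minus)
    ranks = rank_descending(cl)
    ranking = ClosenessRanking(matrix.alternatives, d_plus, d_minus, cl, ranks)
    return TopsisResult(matrix, weights, dirs, norm, weighted, ideals, ranking)
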