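"""Seeded generators for expert panels, rating sets, and decision matrices.

Every stage of the pipeline is testable without external data: a known
weight vector induces a perfectly consistent pairwise matrix
(``a_ij = w_i / w_j``); an expert panel is emulated by multiplying each
upper-triangle entry by ``exp(eps)`` with ``eps ~ Normal(0, sigma)`` and
restoring reciprocity — the standard symmetric log-scale judgment-error
model for AHP simulation (the default panel emulates nine experts
comparing nine criteria with sigma = 0.1, mild disagreement well inside
the 0.1 consistency gate).  Ratings and decision matrices are categorical
draws with controllable favorable probabilities.  All generators are pure
functions of their spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ahp import CriterionWeightVector, PairwiseComparisonMatrix
from .errors import InvalidInputError
from .screening import (
    ExpertRatingSet,
    IMPORTANCE_LEVELS,
    NECESSITY_LEVELS,
    RELEVANCE_LEVELS,
)
from .topsis import DecisionMatrix

__all__ = [
    "PanelSpec",
    "consistent_matrix",
    "perturb_panel",
    "random_decision_matrix",
    "random_rating_set",
    "SAATY_GRID",
]

#: The admissible pairwise judgment values: 1/9 ... 1/2, 1 ... 9.
SAATY_GRID = np.array(
    [1 / k for k in range(9, 1, -1)] + [float(k) for k in range(1, 10)]
)


def consistent_matrix(weights: CriterionWeightVector) -> PairwiseComparisonMatrix:
    """The perfectly consistent matrix a_ij = w_i / w_j induced by weights."""
    w = weights.values
    if np.any(w <= 0):
        raise InvalidInputError("consistent matrix requires strictly positive weights")
    return PairwiseComparisonMatrix(weights.labels, np.outer(w, 1.0 / w))


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic expert panel.

    ``noise_sigma`` is the standard deviation of the log-scale
    multiplicative error on each upper-triangle judgment; 0 reproduces the
    consistent matrix for every expert.
    """

    true_weights: CriterionWeightVector
    n_experts: int = 9
    noise_sigma: float = 0.1
    snap_to_saaty: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise InvalidInputError("panel needs at least one expert")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be >= 0")


def _snap(values: np.ndarray) -> np.ndarray:
    """Snap each value to the nearest grid point in log space."""
    logs = np.log(values)[..., None] - np.log(SAATY_GRID)[None, :]
    return SAATY_GRID[np.abs(logs).argmin(axis=-1)]


def perturb_panel(spec: PanelSpec) -> list[PairwiseComparisonMatrix]:
    """Draw one noisy judgment matrix per expert around the consistent one."""
    base = consistent_matrix(spec.true_weights).values
    n = base.shape[0]
    rng = np.random.default_rng(spec.seed)
    iu = np.triu_indices(n, 1)
    panel = []
    for _ in range(spec.n_experts):
        vals = np.ones_like(base)
        upper = base[iu] * np.exp(rng.normal(0.0, spec.noise_sigma, size=len(iu[0])))
        if spec.snap_to_saaty:
            upper = _snap(upper)
        vals[iu] = upper
        vals[(iu[1], iu[0])] = 1.0 / upper
        panel.append(PairwiseComparisonMatrix(spec.true_weights.labels, vals))
    return panel


def random_decision_matrix(
    m: int,
    n: int,
    seed: int = 0,
    planted_dominant: bool = False,
) -> DecisionMatrix:
    """Uniform integer codes on {1..5}; optionally force the first
    alternative to weakly dominate every other one."""
    if m < 1 or n < 1:
        raise InvalidInputError("need m, n >= 1")
    rng = np.random.default_rng(seed)
    vals = rng.integers(1, 6, size=(m, n)).astype(float)
    if planted_dominant:
        vals[0] = vals.max(axis=0)
    alternatives = tuple(f"alt_{i + 1}" for i in range(m))
    criteria = tuple(f"crit_{j + 1}" for j in range(n))
    return DecisionMatrix(alternatives, criteria, vals)


_SCALES: Mapping[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    # scale -> (all levels, favorable levels)
    "necessity": (NECESSITY_LEVELS, ("necessary",)),
    "relevance": (RELEVANCE_LEVELS, ("relevant", "completely-relevant")),
    "importance": (IMPORTANCE_LEVELS, ("important", "very-important")),
}


def random_rating_set(
    items: Sequence[str],
    n_experts: int,
    favorable_prob: float | Mapping[str, float] = 0.8,
    seed: int = 0,
) -> ExpertRatingSet:
    """Seeded categorical ratings with controlled favorable probabilities.

    With probability ``favorable_prob[scale]`` an expert draws uniformly
    among that scale's favorable levels, otherwise uniformly among the
    rest, so the expected CVI / importance share equals the probability and
    the expected CVR equals ``2 p - 1``.
    """
    if n_experts < 1:
        raise InvalidInputError("need at least one expert")
    if len(items) < 1:
        raise InvalidInputError("need at least one item")
    if not isinstance(favorable_prob, Mapping):
        favorable_prob = {s: float(favorable_prob) for s in _SCALES}
    for s, p in favorable_prob.items():
        if not 0.0 <= p <= 1.0:
            raise InvalidInputError(f"favorable_prob[{s!r}] must be in [0, 1]")
    rng = np.random.default_rng(seed)
    experts = tuple(f"expert_{e + 1}" for e in range(n_experts))
    frames: dict[str, pd.DataFrame] = {}
    for scale, (levels, favorable) in _SCALES.items():
        p = favorable_prob.get(scale, 0.8)
        unfavorable = tuple(l for l in levels if l not in favorable)
        hit = rng.random((len(items), n_experts)) < p
        fav_pick = rng.integers(0, len(favorable), size=hit.shape)
        unf_pick = rng.integers(0, len(unfavorable), size=hit.shape)
        labels = np.where(
            hit,
            np.asarray(favorable, dtype=object)[fav_pick],
            np.asarray(unfavorable, dtype=object)[unf_pick],
        )
        frames[scale] = pd.DataFrame(labels, index=list(items), columns=experts)
    face = pd.DataFrame(
        rng.random((len(items), n_experts)) < favorable_prob.get("face", 0.9),
        index=list(items),
        columns=experts,
    )
    return ExpertRatingSet(
        necessity=frames["necessity"],
        relevance=frames["relevance"],
        importance=frames["importance"],
        face_clear=face,
    )
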