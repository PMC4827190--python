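import numpy as np
import pytest

from htaprio.ahp import CriterionWeightVector
from htaprio.topsis import DecisionMatrix
from htaprio import fixtures


def naive_topsis(scores, weights, directions=None):
    """Independent brute-force TOPSIS: plain Python loops, no shared code.

    Returns (normalized, weighted, a_plus, a_minus, d_plus, d_minus, cl,
    ranks) as nested lists, computed exactly as the textbook procedure
    reads: column norms, element-wise weighting, column best/worst,
    Euclidean distances, relative closeness, descending stable ranks.
    """
    m, n = len(scores), len(scores[0])
    directions = directions or ["benefit"] * n
    norm = [[0.0] * n for _ in range(m)]
    for j in range(n):
        s = 0.0
        for i in range(m):
            s += scores[i][j] ** 2
        root = s ** 0.5
        for i in range(m):
            norm[i][j] = scores[i][j] / root
    weighted = [[norm[i][j] * weights[j] for j in range(n)] for i in range(m)]
    a_plus, a_minus = [0.0] * n, [0.0] * n
    for j in range(n):
        col = [weighted[i][j] for i in range(m)]
        if directions[j] == "benefit":
            a_plus[j], a_minus[j] = max(col), min(col)
        else:
            a_plus[j], a_minus[j] = min(col), max(col)
    d_plus, d_minus = [0.0] * m, [0.0] * m
    for i in range(m):
        sp = sn = 0.0
        for j in range(n):
            sp += (weighted[i][j] - a_plus[j]) ** 2
            sn += (weighted[i][j] - a_minus[j]) ** 2
        d_plus[i], d_minus[i] = sp ** 0.5, sn ** 0.5
    cl = [d_minus[i] / (d_plus[i] + d_minus[i]) for i in range(m)]
    order = sorted(range(m), key=lambda i: (-cl[i], i))
    ranks = [0] * m
    for pos, i in enumerate(order, start=1):
        ranks[i] = pos
    return norm, weighted, a_plus, a_minus, d_plus, d_minus, cl, ranks


def random_reciprocal_matrix(n, rng):
    """A random positive reciprocal matrix with log-uniform judgments."""
    vals = np.ones((n, n))
    iu = np.triu_indices(n, 1)
    upper = np.exp(rng.uniform(-np.log(9), np.log(9), size=len(iu[0])))
    vals[iu] = upper
    vals[(iu[1], iu[0])] = 1.0 / upper
    return vals


def make_decision(values, prefix=("alt", "crit")):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return DecisionMatrix(
        tuple(f"{prefix[0]}{i}" for i in range(m)),
        tuple(f"{prefix[1]}{j}" for j in range(n)),
        values,
    )


def make_weights(values, prefix="crit"):
    values = np.asarray(values, dtype=float)
    return CriterionWeightVector(
        tuple(f"{prefix}{j}" for j in range(values.size)), values
    )


@pytest.fixture(scope="session")
def pilot_matrix():
    return fixtures.pilot_decision_matrix()


@pytest.fixture(scope="session")
def pilot_weights():
    return fixtures.pilot_weights()


@pytest.fixture(scope="session")
def pilot_profiles():
    return fixtures.pilot_evidence_profiles()
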