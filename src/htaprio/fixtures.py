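"""The published three-technology pilot: weights, decision matrix, evidence.

These constants reproduce the pilot study shipped with the model: nine
criteria weighted by a nine-expert panel, and three cardiovascular
technologies (adenosine for supraventricular tachycardia, tissue
plasminogen activator and mechanical thrombectomy for stroke) coded from
their published evidence and ranked by TOPSIS.  The printed group weights
are rounded to two decimals and sum to 0.99; they are used exactly as
printed, since the pipeline takes the weight vector as supplied.
"""

from __future__ import annotations

import numpy as np

from .ahp import CriterionWeightVector
from .rubrics import EvidenceProfile
from .topsis import DecisionMatrix

__all__ = [
    "CRITERIA",
    "TECHNOLOGIES",
    "pilot_weights",
    "pilot_decision_matrix",
    "pilot_evidence_profiles",
    "PRINTED_NORMALIZED",
    "PRINTED_WEIGHTED",
    "PRINTED_A_PLUS",
    "PRINTED_A_MINUS",
    "PRINTED_D_PLUS",
    "PRINTED_D_MINUS",
    "PRINTED_CLOSENESS",
    "PRINTED_RANKS",
]

CRITERIA: tuple[str, ...] = (
    "efficiency_effectiveness",
    "safety",
    "population_size",
    "vulnerable_population",
    "alternatives_availability",
    "cost_effectiveness",
    "budget_impact",
    "financial_protection",
    "evidence_quality",
)

TECHNOLOGIES: tuple[str, ...] = (
    "Adenosine",
    "Tissue Plasminogen Activator",
    "Mechanical Thrombectomy",
)

#: Group criterion weights as printed (two decimals; they sum to 0.99).
_WEIGHTS = (0.12, 0.20, 0.06, 0.08, 0.08, 0.13, 0.08, 0.09, 0.15)

#: The published 3 x 9 coded decision matrix.
_DECISION = (
    (5, 4, 4, 4, 2, 1, 1, 1, 5),
    (3, 3, 5, 4, 5, 5, 1, 1, 3),
    (1, 3, 5, 4, 5, 5, 1, 1, 5),
)


def pilot_weights() -> CriterionWeightVector:
    return CriterionWeightVector(CRITERIA, np.array(_WEIGHTS))


def pilot_decision_matrix() -> DecisionMatrix:
    return DecisionMatrix(TECHNOLOGIES, CRITERIA, np.array(_DECISION, dtype=float))


def pilot_evidence_profiles() -> list[EvidenceProfile]:
    """The three technologies' evidence, structured for the rubric engine.

    Notes on two judged slots:

    * ``vulnerable_share`` stores 40 (the 26-50% band) for all three
      technologies, matching the published expert judgment (code 4).  The
      narratives report women as 51-53% of stroke cases and the majority of
      adenosine's target population, but the rubric's quantity is the share
      of the *target population* in the defined vulnerable groups (children
      under 5, women of fertility age, elders over 65, special/neuro-
      psychiatric patients), which the panel judged to fall in 26-50%.
    * Thrombectomy's evidence base (a health-technology-assessment report
      built on a high-quality randomized trial) is classified in the
      high-quality-HTA category, the published code-5 assignment.
    """
    return [
        EvidenceProfile(
            technology_id="Adenosine",
            technology_class="treatment",
            effectiveness="perfect treatment",
            safety_level="relatively safe",
            target_population=180_000,
            vulnerable_share=40.0,
            alternatives_availability="high availability",
            evidence_quality="systematic-review-rct-high",
        ),
        EvidenceProfile(
            technology_id="Tissue Plasminogen Activator",
            technology_class="treatment",
            effectiveness="lifetime increasing and low improvement of quality of life",
            safety_level="proper safety",
            target_population=1_000_001,
            vulnerable_share=40.0,
            alternatives_availability="partial availability",
            evidence_quality="rct-high",
            icer=6255.0,
            gdp_per_capita=53_000.0,
        ),
        EvidenceProfile(
            technology_id="Mechanical Thrombectomy",
            technology_class="treatment",
            effectiveness="low improvement of quality of life",
            safety_level="proper safety",
            target_population=1_000_001,
            vulnerable_share=40.0,
            alternatives_availability="partial availability",
            evidence_quality="hta-high",
            icer=16_000.0,
            gdp_per_capita=53_000.0,
        ),
    ]


# ---------------------------------------------------------------------------
# The published intermediate tables (two-decimal renderings) for comparison.
# The closeness values embed an unstated rounding path and are retained for
# reference only; full-precision computation reproduces the normalized
# matrix, the separations, and the rank order, but not these three digits.

PRINTED_NORMALIZED = np.array([
    [0.85, 0.69, 0.49, 0.58, 0.27, 0.14, 0.58, 0.58, 0.65],
    [0.51, 0.51, 0.62, 0.58, 0.68, 0.70, 0.58, 0.58, 0.39],
    [0.17, 0.51, 0.62, 0.58, 0.68, 0.70, 0.58, 0.58, 0.65],
])

PRINTED_WEIGHTED = np.array([
    [0.11, 0.14, 0.03, 0.05, 0.02, 0.02, 0.05, 0.05, 0.10],
    [0.06, 0.10, 0.04, 0.05, 0.05, 0.09, 0.05, 0.05, 0.06],
    [0.02, 0.10, 0.04, 0.05, 0.05, 0.09, 0.05, 0.05, 0.10],
])

PRINTED_A_PLUS = np.array([0.11, 0.14, 0.04, 0.05, 0.05, 0.09, 0.05, 0.05, 0.10])
PRINTED_A_MINUS = np.array([0.02, 0.10, 0.03, 0.05, 0.02, 0.02, 0.05, 0.05, 0.06])

PRINTED_D_PLUS = np.array([0.08, 0.07, 0.09])
PRINTED_D_MINUS = np.array([0.10, 0.09, 0.09])
PRINTED_CLOSENESS = np.array([0.562, 0.571, 0.493])
PRINTED_RANKS = np.array([2, 1, 3])
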