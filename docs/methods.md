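# Methods

`htaprio` implements a multi-criteria decision-analysis (MCDA) pipeline for
prioritizing health technologies awaiting full health technology assessment
(HTA). The pipeline has four stages, each usable on its own: criteria
screening, group AHP weighting, evidence coding, and TOPSIS ranking. This
note records the model, its assumptions, the tunable parameters, and the
design choices made where the design was genuinely open.

## 1. Criteria screening (`htaprio.screening`)

Candidate criteria are screened on per-expert ratings collected on three
categorical scales plus a binary face-validity judgment.

* **Content validity index (CVI)** — the proportion of experts rating an
  item *relevant* or *completely relevant* on the 5-level relevance scale.
  The retention floor defaults to **0.79**, the conventional CVI minimum
  for panels of about ten raters.
* **Content validity ratio (CVR)** — Lawshe's
  `(n_essential − N/2)/(N/2)` on the 3-level necessity scale, compared to
  the Lawshe critical value for the panel size (0.59 for 11 raters). The
  shipped table is the standard published one (N = 5…15, 20, 25, 30, 35,
  40) and is overridable in configuration; CVR relates to the necessity
  majority by the identity `CVR = 2·majority − 1`.
* **Importance share** — the proportion rating *important* or *very
  important* on the 5-level importance scale; the conventional cut-off for
  admission to the weighting stage is **0.75**.

The retention rule: an item passes via `cvr-pass` when CVR ≥ the Lawshe
critical value; otherwise via `majority-plus-cvi` when at least 50% of the
panel judged it necessary **and** CVI ≥ 0.79; otherwise it is dropped. Ties
at every threshold pass (the thresholds are stated as minima). Face-validity
shares are reported but never gate retention: in practice they inform
rewording and merging of overlapping items, an editorial act outside any
algorithm. Cronbach's alpha on the numeric-coded importance ratings is
provided as the standard reliability diagnostic (unbiased variances,
experts as respondents).

## 2. Group AHP weighting (`htaprio.ahp`)

Each expert supplies a positive reciprocal pairwise-comparison matrix
`A = (a_ij)` over the criteria, conventionally on the Saaty 1–9 scale;
arbitrary positive reals are accepted and never snapped to the grid. The
group matrix is the **element-wise geometric mean** of the expert matrices —
the only aggregation consistent with reciprocity (the aggregate of
reciprocal pairs is reciprocal by construction).

Weights use the **row-geometric-mean approximation**:
`w_i ∝ (Π_j a_ij)^(1/n)`, normalized to sum to one. For a perfectly
consistent matrix (`a_ij = w_i/w_j`) this recovers the generating weights
exactly; it also commutes with aggregation (weights of the aggregate equal
the normalized geometric mean of per-expert weight vectors), a property the
test suite asserts on random panels.

Consistency is checked through an estimate of the principal eigenvalue:
`λ_max ≈ mean_i (A·w)_i / w_i`, the inconsistency index
`II = (λ_max − n)/(n − 1)`, and the inconsistency ratio `IR = II / RI(n)`
against Saaty's random index `RI(1..10) = 0, 0, 0.58, 0.90, 1.12, 1.24,
1.32, 1.41, 1.45, 1.49` (overridable). Judgments are acceptably coherent
when **IR ≤ 0.1**; the `weights` command refuses to emit weights above the
gate unless `--force` is passed, since incoherent judgments should be
revised, not averaged away. Numerical choices: matrices of dimension ≤ 2
are always consistent, so `IR = 0` there rather than dividing by a zero
random index; reciprocity is validated (product tolerance 1e−9) and never
silently repaired — an explicit `--repair-reciprocal` flag replaces each
pair `(a_ij, a_ji)` with the geometric compromise `(g, 1/g)`,
`g = √(a_ij/a_ji)·a_ij`.

The mean-ratio λ_max is an approximation to the dominant eigenvalue; the
tests cross-check it against an independent power-iteration oracle (within
0.01 on the examples used) and assert Saaty's bound `λ_max ≥ n` on random
reciprocal matrices. The eigenvector, least-squares, and logarithmic
least-squares weighting methods are deliberately out of scope.

## 3. Evidence coding rubrics (`htaprio.rubrics`)

Nine criteria score each technology on an integer 1–5 scale where **5
always means more reason to prioritize** — note the
alternatives-availability table is inverted on purpose (a technology that
is the only option scores 5). The criteria, in pipeline order:
efficiency/effectiveness (class-specific: clinical-benefit label for
treatment/rehabilitation, accuracy × treatability for screening/diagnosis,
effectiveness % for prevention), safety (side-effect incidence % or a
qualitative level; numeric takes precedence), target population size,
vulnerable-population share, availability of alternatives, cost
effectiveness (ICER / GDP-per-capita ratio), budget impact, financial
protection, and quality of evidence. Where a table defines an
*unspecified* band (vulnerable share, cost effectiveness, budget impact,
financial protection), absent evidence codes 1 or 2 per that band; safety
has none, so safety evidence is mandatory.

The tables ship as editable JSON (`data/rubrics.json`) so another agency's
bands can be swapped in without touching code. Band-edge conventions:
edges are closed on their stated endpoints, and a value falling in a gap
between printed bands (e.g. a vulnerable share of 10.5%, between the
"≤10" and "11–25" bands) resolves to the **higher** code; the fired band
is recorded in per-criterion provenance. Two corner cases in the screening
effectiveness table are documented rather than guessed: accuracy below 60%
is code 1 whether or not the condition is treatable (the untreatable case
is a gap, flagged in provenance).

## 4. TOPSIS ranking (`htaprio.topsis`)

Given the m×n coded decision matrix `R`, a weight vector `W`, and a
benefit/cost direction per criterion:

1. vector normalization `n_ij = r_ij / √(Σ_i r_ij²)` (unit-Euclidean
   columns — hence invariance to positive rescaling of any criterion);
2. weighting `v_ij = n_ij · w_j`, with `W` used exactly as supplied —
   TOPSIS treats the weights as input and does not re-normalize them (the
   shipped pilot weights are printed at two decimals and sum to 0.99);
3. ideal profiles: for benefit criteria `A⁺_j = max_i v_ij`,
   `A⁻_j = min_i v_ij`; reversed for cost criteria. All nine shipped
   criteria are benefit-type because the rubrics already orient every
   scale;
4. Euclidean separations `d_i± = √(Σ_j (v_ij − A±_j)²)`;
5. relative closeness `cl_i = d_i− / (d_i+ + d_i−) ∈ [0, 1]`, undefined
   only when every alternative is identical (raised as a degenerate-input
   error, as is a single-alternative ranking);
6. descending-order ranks, ties stable by input position.

Full floating-point precision is carried end to end; the report layer
rounds (default two decimals). The pilot's published closeness digits
embed an unstated intermediate-rounding path and are not reproduced —
chasing them would sacrifice correctness — but the normalized matrix, the
separations at two decimals, and the rank order all reproduce exactly from
full precision.

## 5. Synthetic data (`htaprio.synthetic`)

The generators emulate the study conditions so every stage is testable
without external data. A known weight vector induces the consistent matrix
`a_ij = w_i/w_j`; an expert panel multiplies each upper-triangle entry by
`exp(ε)`, `ε ~ Normal(0, σ)`, restoring the lower triangle as exact
reciprocals — the standard symmetric log-scale judgment-error model for
AHP simulation. Defaults emulate the pilot's weighting stage: **9 experts,
9 criteria, σ = 0.1** (mild disagreement comfortably inside the 0.1
consistency gate); snapping to the Saaty grid `{1/9…1/2, 1…9}` is
available but off by default since the AHP stage accepts arbitrary
positive reals. At these conditions the aggregated-then-derived weights
recover the generating vector within L∞ 0.05 in ≥ 95% of 200 seeded
replicates (the suite asserts this, plus monotone improvement over
σ = 0.3, 0.2, 0.1, 0.05), so a real nine-expert panel of comparable
coherence pins the weights well.

Rating generators draw favorably with a controlled probability p, making
the expected CVI / importance share equal p and the expected CVR equal
2p − 1; decision matrices draw codes uniformly on {1..5} with an optional
planted weakly-dominant first row. All generators are pure functions of
spec + seed.

What the synthetic model does **not** emulate: systematic expert bias
(every error is zero-mean), correlated judgments between experts,
within-expert intransitivity structure beyond what log-noise induces, and
real evidence heterogeneity. Passing tests therefore show the pipeline's
algebra and calibration under honest-but-noisy panels, not robustness to
adversarial or biased panels.

## Problem sizes and limitations

The test suite and the reproduction script run the pilot at its natural
size (3 alternatives × 9 criteria), property checks on random instances up
to 8×8, and panel calibrations of 200 replicates of nine 9×9 matrices —
everything completes in a few seconds on one CPU. Known limitations: the
shipped Lawshe table covers panels of 5–15 and a few larger sizes (other
sizes require configuration); rank reversal under added/removed
alternatives is inherent to classical TOPSIS and no mitigation variant is
implemented; block (city-block) separation and entropy weighting are out
of scope; and the rubric bands encode one agency's judgments — they are
data, not truths.
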