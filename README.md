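# htaprio

**AHP–TOPSIS priority setting for health technology assessment.**

HTA agencies receive far more assessment requests than they can fund, so
the requests themselves must be prioritized. `htaprio` implements a
complete multi-criteria decision-analysis pipeline for that problem, built
for analysts at HTA units and researchers in health decision science:

1. **Criteria screening** — candidate prioritization criteria are screened
   on expert-panel ratings using the content validity index (CVI ≥ 0.79),
   Lawshe's content validity ratio `CVR = (n_e − N/2)/(N/2)` against the
   Lawshe critical value for the panel size, a 50% necessity-majority
   rescue rule, and a 75% importance cut.
2. **Group AHP weighting** — each expert's pairwise-comparison matrix
   (Saaty 1–9 scale) is aggregated by the element-wise geometric mean;
   weights are the normalized row geometric means
   `w_i ∝ (Π_j a_ij)^{1/n}`; coherence is gated by the inconsistency
   ratio `IR = (λ_max − n)/((n − 1)·RI(n)) ≤ 0.1`.
3. **Evidence coding** — per-technology evidence (effectiveness, safety,
   population size, vulnerable share, alternatives, ICER vs GDP per
   capita, budget impact, financial protection, evidence quality) is
   converted to integer 1–5 codes through editable rubric tables.
4. **TOPSIS ranking** — vector normalization
   `n_ij = r_ij/√(Σ_i r_ij²)`, weighting `v_ij = n_ij·w_j`, ideal and
   negative-ideal profiles, Euclidean separations `d_i±`, and relative
   closeness `cl_i = d_i−/(d_i+ + d_i−)` ranked in descending order.

The shipped fixtures reproduce a published three-technology pilot
(adenosine, tissue plasminogen activator, mechanical thrombectomy ranked
on nine criteria) end to end. See `docs/methods.md` for the full model
description and design choices.

## Worked example

Rank the pilot technologies from the shipped evidence profiles and
published group weights:

```sh
htaprio pilot
```

which codes the evidence through the rubrics, verifies the coded matrix,
runs TOPSIS, and prints (excerpt):

```
Final priority setting
                              d_plus  d_minus  closeness  rank
Adenosine                       0.08     0.10       0.55     2
Tissue Plasminogen Activator    0.07     0.09       0.58     1
Mechanical Thrombectomy         0.09     0.09       0.50     3
```

`d_plus`/`d_minus` are each technology's Euclidean distances from the
best and worst achievable weighted profiles; closeness near 1 means near
the ideal. Tissue plasminogen activator ranks first for assessment,
adenosine second, mechanical thrombectomy third.

The same pipeline runs on your own files:

```sh
htaprio screen ratings.csv --out screening.csv        # CVI/CVR/importance
htaprio weights expert_*.csv --out weights.csv        # refuses if IR > 0.1
htaprio code evidence.json --out decision.csv         # rubric coding
htaprio rank decision.csv weights.csv --out report.json
htaprio simulate --kind panel --seed 1 --out-dir demo # synthetic inputs
```

The library API mirrors the commands (`htaprio.screening.screen_items`,
`htaprio.ahp.derive_weights`, `htaprio.rubrics.build_decision_matrix`,
`htaprio.topsis.topsis`).

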