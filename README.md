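# epimem

Analysis pipeline for episodic-memory experiments that probe the
what–where–when structure of memory across radically different encoding
timescales, together with a synthetic-data generator that reproduces the
statistical structure of such experiments so every stage is testable
without human data.

The study design being modelled: participants encode 60 objects under one
of three protocols — exploring a virtual town (**VR**, ~42 min of
encoding, ~1 day retention), receiving object images on their phone during
everyday life (**RW**, 3–17 days of encoding, hours-to-days retention), or
a standard laboratory trial sequence (**SL**, ~15 min encoding, ~18 min
retention).  At retrieval they (a) judge each object *Remember* /
*Familiar* / *New*, then answer two-alternative forced-choice questions
about its place and time of encoding plus confidence ratings, and (b)
judge the temporal order of event pairs cued by objects (*TOobj*) or
places (*ev-TOloc*, *noe-TOloc*).

## The two analyses

**Source memory → recollection.**  For correctly recognized old objects,
a random-intercept binomial logistic model predicts the Remember (vs
Familiar) report:

    logit P(Rem) = β₀ + β_P·Place + β_T·Time + β_PC·P:CF + β_TC·T:CF + u_subj

where *Place*/*Time* code a correct source discrimination irrespective of
confidence, *P:CF*/*T:CF* code correct **and** high-confidence source
judgments (0 for every other combination), and u_subj ~ N(0, σ_u²).  The
marginal likelihood is maximized with adaptive Gauss–Hermite quadrature
(15 nodes); inference is Wald.

**Temporal-order retrieval and scale invariance.**  Each order trial gets
a SIMPLE temporal-similarity score from the two events' encoding-to-
retrieval retention delays T_i < T_j:

    TS = (T_i / T_j)^c ,   c = 1 / (ln T_max − ln T_min)

with c calibrated per participant × task block.  Because TS depends only
on delay *ratios*, multiplying every timestamp by a constant leaves every
score — and everything computed from it — unchanged.  Per-participant
robust regressions (IRLS, Tukey bisquare) of RT on TS over correct trials
give slopes that enter a 3 (cue condition, within) × 3 (protocol, between)
mixed ANOVA, a pooled one-sample t against zero, and a JZS Bayes factor
for the null of no between-protocol difference: evidence that the
similarity→RT coupling is the same from minutes to weeks.

All statistical engines (mixed-design ANOVA, Tukey HSD, robust slopes,
the random-intercept logistic model, JZS Bayes factors) are implemented in
the package and verified against independent references
(pingouin, scipy, statsmodels, dense quadrature) in the test suite.

## Worked example

```bash
python analysis/01_simulate.py          # synthetic study, 3 x 20 participants
python analysis/02_score_similarity.py  # SIMPLE similarity per trial
python analysis/03_source_retrieval.py  # source-memory analyses
python analysis/04_temporal_order.py    # order analyses + scale invariance
python analysis/05_report.py            # results/report.md
```

Output of the default run (seed 2026):

```
VR: p_cf logit = +1.05 (p = 2.89e-09), t_cf logit = +0.76 (p = 1.34e-05), sigma_u = 0.32
RW: p_cf logit = +1.11 (p = 8.53e-08), t_cf logit = +1.24 (p = 2.00e-09), sigma_u = 0.58
SL: p_cf logit = +0.96 (p = 1.17e-08), t_cf logit = +0.80 (p = 1.65e-06), sigma_u = 0.36

TOobj accuracy, experiment effect: F(2,57) = 0.45, p = 0.641
slopes: condition F(2,114) = 7.94 (p = 0.0006); experiment F(2,57) = 2.09 (p = 0.133)
pooled slope t(59) = 9.33, p = 3.18e-13; mean slope = 554 ms/unit
JZS BF10 (experiment effect on mean slopes) = 0.4398  (BF01 = 2.3)
```

Reading this: in every protocol, a correct *and confident* place or time
source judgment raises the odds of a Remember report (positive p_cf/t_cf
logits, all significant) — context retrieval drives the subjective sense
of remembering.  Reaction times rise with temporal similarity everywhere
(pooled t(59) = 9.33), the effect is steeper for object cues than place
cues (condition effect), and neither the ANOVA nor the Bayes factor finds
a protocol difference — order retrieval behaves the same across
timescales spanning three orders of magnitude, the scale-invariance
signature.

The same pipeline is available as a CLI:
`epimem simulate|score|analyze|report` (see `epimem --help`).

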