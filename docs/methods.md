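# Methods

## The model of the experiment

The pipeline analyses (and simulates) a three-protocol episodic-memory
study.  Each participant encodes `n_objects = 60` object-events, each
bound to a place and a time, under one of three envelopes (times are
seconds from the participant's first encoding event):

| protocol | encoding span | retention (last encoding → retrieval) |
|---|---|---|
| VR | 2544–2558 s (~42.5 min) | 79,326–107,510 s (~1 day) |
| RW | 3–17 days | 7,984–1,094,910 s (2 h – ~13 days) |
| SL | 854–908 s (~15 min) | 691–1,388 s (~18 min) |

VR and SL envelopes are the observed ranges of the study being modelled;
the RW encoding span uses the protocol's designed 3–17-day window.  RW
retention spans two orders of magnitude and is drawn log-uniformly; the
narrow VR/SL windows are drawn uniformly.  Object-events sit at
jittered-uniform times across the span (equal spacing ± ≤40% of a step,
endpoints fixed), which keeps orderings strict and spans exactly inside
the envelope; 60 additional place-only events (no object) interleave with
them and feed the *noe-TOloc* condition.  Real schedules were constrained
by geolocation and are not reproducible; jittered-uniform is the neutral
choice.

## Generative model (what the synthetic data emulate)

**Recognition.**  Old objects are recognized with probability
`p_recognize_old` (VR .80, RW .70, SL .85 — ordered so the
between-protocol recognition contrast, RW lowest and SL highest, is
present in the generated data); new foils (default 30; the real foil
count is unreported) are falsely recognized with probability .15, and a
false alarm is labelled Remember with probability .3.

**Source strength → confidence, accuracy, recollection.**  Each
recognized old object draws latent place and time strengths
`s ~ LogNormal(0, 1)`.  Confidence is high iff `s > θ_conf = 1` (a median
split).  2AFC source accuracy is `logistic(a0 + a1·s)` with
`a0 = −0.235, a1 = 0.603`, solved (by Monte-Carlo inversion of the
lognormal mixture) so the high-confidence cell sits at ~0.75 accuracy and
the low-confidence cell at ~0.52 — reliable source memory when confident,
near chance when not.  The Remember report follows
`logit P(Rem) = γ0 + γP·1[place correct ∧ confident] + γT·1[time correct ∧
confident] + u_subj`, `u_subj ~ N(0, σ_u²)`, with defaults
`γ0 = −0.5, γP = 1.2, γT = 0.8, σ_u = 0.5`.  Only the confident-correct
conjunctions carry weight, so the fitted place/time main effects should
hover near zero while p_cf/t_cf are positive — the pattern the source
analysis tests.

**Order trials.**  Per condition, 40 trials (trial counts per condition
are unreported in the modelled study; 40 is a typical session load).
Pairs are sampled so encoding distances are roughly log-uniform over the
span; the *ev-TOloc* block reuses the *TOobj* event pairs, since those
place cues reference the very same events.  The retrieval session starts
after the retention draw and advances 10 s per trial (object block first,
then the intermixed place block), so each trial has its own retrieval
timestamp.  RT is `β0 + β1·TS + ε`, `ε ~ N(0, σ_rt²)` truncated at 200 ms,
with `β0 = 1800 ms`, `β1 = 900 ms/unit` for object cues and `450` for
place cues (steeper object-cue slopes are part of the default condition),
`σ_rt = 300 ms`.  Correctness is `logistic(d0 + d1·(1 − TS))` with
`d0 = 0, d1 = 2` — harder (slower, less accurate) when the pair is
similar in log time.

**What the generator does not emulate.**  No spatial structure (places
are opaque ids), no like/dislike encoding task, no forgetting dynamics
within the retention interval, no RT floor effects beyond truncation, no
response-omission process (missingness enters only through analysis-side
exclusions).  Generated order accuracy sits in the low/mid 50s–60s%
rather than the mid-60s% typical of such studies, because a single
logistic link ties accuracy to TS for all conditions.  Passing tests
therefore show that the *analysis chain* is correct and calibrated under
the stated generative assumptions — not that those assumptions capture
every feature of real behaviour.

## Temporal similarity

`TS = (T_i/T_j)^c` with `T_i < T_j` the pair's retention delays and
`c = 1/(ln T_max − ln T_min)` over a calibration set.  Choices the
similarity literature leaves open, fixed here:

* **Log base: natural.**  The base only rescales c; natural log puts the
  calibration extremes at exactly `e^(−1) ≈ 0.368`, matching the
  magnitude of observed TS minima far better than base 10 (which forces
  0.1).
* **Calibration scope: per participant × task block** (object block;
  place block pooling ev/noe), over the union of both delays of every
  trial in the block — matching how the conditions are administered (two
  separate blocks).  Per-condition and global scopes are available.
* **Per-trial retrieval timestamps.**  Each trial's delays use that
  trial's own onset; the session advances trial by trial, so delay drift
  within a session exists as it does in a real task.
* **Numerics.**  `c` is computed from the single ratio `T_max/T_min`
  (algebraically identical to the difference of logs), which makes
  timestamp rescaling by a power of two reproduce every TS *bit for bit*
  (IEEE division is exact under power-of-two scaling); arbitrary positive
  factors reproduce TS to ~1e−15 relative.  This is the computational
  form of the scale-invariance claim and is tested both ways.

Within a calibration group TS cannot drop below `e^(−1)` (both delays lie
inside the calibration range by construction).  Published TS ranges that
dip slightly below that bound imply a different (unreported) calibration
set; observed TS ranges are treated as approximate envelopes, not
reproduction targets.

## Statistical engines

* **Random-intercept logistic regression.**  Marginal ML; the subject
  intercept is integrated by adaptive Gauss–Hermite quadrature (15 nodes;
  1 node = Laplace), with the integrand re-centred at each subject's
  posterior mode (Newton, log-concave) and re-scaled by its curvature.
  Trials collapse to (subject × covariate-pattern) binomial counts first,
  so cost is independent of trial count.  Optimization is L-BFGS-B over
  (β, σ_u ≥ 0) to |Δloglik| ≲ 1e−8; at the σ_u = 0 boundary the fit is
  polished by Newton–Raphson on β, making it exactly the plain ML fit.
  Inference is Wald (finite-difference observed information): per-
  coefficient logits, SE, z, p, 95% CI — the convention when effects are
  reported as logits with intervals.  A constant outcome raises a
  separation error; constant predictors are dropped with a warning;
  |logit| > 15 flags the fit instead of diverging silently.
* **Robust slope.**  IRLS with Tukey bisquare (tuning 4.685, ~95%
  Gaussian efficiency; Huber 1.345 available), scale = MAD/0.6745
  re-estimated per iteration, convergence 1e−8, OLS start.  Requires ≥5
  points and non-constant similarity; failing cells are excluded and
  logged rather than imputed.
* **Mixed ANOVA.**  Classical balanced split-plot decomposition via
  margin sums of squares with subject-nested error strata (one between
  factor, up to two within factors).  Every subject must have every
  within cell; group sizes may differ (the design stays proportional and
  orthogonal).  Equals the Type III sum-to-zero decomposition on balanced
  data; p-values are invariant to level relabelling and location shifts.
* **Tukey HSD.**  Studentized-range p on the pooled one-way MSE,
  Tukey–Kramer for unequal n.  With two groups it reduces exactly to the
  pooled t-test.
* **JZS Bayes factors.**  Cauchy-on-effect / Jeffreys-on-variance
  default prior, integrated numerically over the mixing variable g
  (Inv-Gamma(1/2, r²/2)); the one-way design places the g-prior on k−1
  orthonormalized sum-to-zero contrasts.  Default scale `r = √2/2`
  ("medium") for both designs; the R `BayesFactor` package's fixed-effect
  default (r = 1/2) differs and is available through the `r` argument.
  BF10 is reported with BF01 = 1/BF10; quadrature failure raises with the
  achieved tolerance.  The between-protocol Bayes factor is computed on
  per-subject mean slopes (one value per subject, three groups) — the
  minimal design consistent with "no difference between protocols"; a
  per-condition variant is available.

## Analysis-stage decisions

* Above-chance tests of the source-accuracy cells are two-sided
  one-sample t vs 0.5 on subject means, uncorrected by default (mirroring
  per-cell reporting conventions); a Bonferroni flag exists.
* Participants with an undefined Remember ratio (no recognized old item)
  are dropped from that ANOVA only, logged.
* Subjects missing any condition's slope are excluded from the slope
  ANOVA (balanced-within engine) and the pooled t, logged.
* Missing responses are absent fields, excluded listwise per analysis.

## Problem sizes

Default study: 3 protocols × 20 participants × (60 old + 30 foil source
trials; 120 order trials).  The simulation studies in the acceptance
layer use the designs stated with them: logistic calibration at 20
subjects × 40 trials × 200 replicates (coverage and type-I), slope
recovery at 20 × 40 × 100 replicates, and the scale-invariance experiment
at the full three-protocol design × 100 replicates per arm.  These sizes
give Monte-Carlo standard errors of ~1.5% on coverage/rejection rates,
small against the acceptance bands.

## Known limitations

* The Wald intervals are first-order; profile-likelihood intervals would
  be better near the σ_u boundary.
* The ANOVA engine is deliberately restricted to complete within-subject
  data — no mixed-model fallback for incomplete designs.
* The one-way Bayes factor assumes homogeneous variance across groups.
* Robust-slope scale estimation uses the plain normalized MAD, not the
  leverage-adjusted variant some implementations apply; on these designs
  the difference is ~1e−3 relative.
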