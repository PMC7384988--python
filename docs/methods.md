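# Methods

## Scoring

The three Magee Equations are fixed linear models; the package treats
their coefficients as constants, shipped in
`src/magee_triage/data/coefficients.yaml` and validated against a schema
at load time (each equation carries exactly the variables it is defined
on; the HER2 offset for a negative tumor is pinned at 0). The shipped set
is the 2013 published revision, transcribed from the companion
publications behind the public calculator; the test suite verifies that
it reproduces the reference worked example (21.5 / 21.7 / 20.6) exactly.
Refitting or recalibrating the equations is out of scope.

Numerical conventions:

* **Rounding** — one decimal, ties away from zero (implemented with
  `decimal` to avoid binary-float tie artifacts). This matches the
  display granularity of the public calculator, and bands are computed on
  the rounded values so the package's labels agree with what a user
  reading the calculator display would decide.
* **Clamping** — a negative raw linear value is clamped to 0 before
  rounding; the recurrence-score scale is non-negative. Whether the
  original calculator clamps is not documented; this choice only affects
  tumors far outside the L band boundary, never a triage label.
* **Missing variables** — an equation whose required variable is absent
  is flagged unavailable rather than guessed; the triage layer then
  raises a specific error for variants that need it.
* **HER2** — IHC 0/1+ are negative and 3+ positive; 2+ requires an
  in-situ-hybridization copy number (<4 negative, 4 to <6 equivocal, ≥6
  positive). A 2+ case without FISH cannot be scored.
* **Ki-67** — accepted as a real percent, since labeling indices are
  usually estimated rather than counted.

## Triage rule

Decision order: all used scores in H → expect-high; any score in S →
send; any score in M → mitosis score 1 forgoes testing, otherwise send;
all in L → forgo testing. Band edges are read as closed at 18 and 25 and
closed below at 31 (so 25.0 with mitosis 1 forgoes testing). A mixture of
L and H scores with nothing in between is not enumerated by the published
rule; the package sends such cases for testing (the conservative choice)
and flags them `unclassified_by_rule`. The mitosis cutoff and band edges
are configurable (`Thresholds`) for sensitivity analysis; the defaults
are the published rule.

## Validation statistics

* **Concordance** — do-not-send cases are cross-tabulated against the
  actual score band split at 25 (the post-TAILORx clinical cutoff);
  send-labeled cases are excluded from the table but tallied with the
  fraction whose actual score exceeded 25. Accuracies are exact count
  ratios; percentages are reported at one decimal. Note that a printed
  percentage pair like 70.1/29.9 for a 1538/658 split carries the
  source's own rounding — exact arithmetic gives 70.0/30.0.
* **Group comparisons** — continuous variables use an independent
  two-sample t-test, Welch by default because validation groups are
  typically wildly unbalanced (e.g. 75 vs 1443); a pooled-variance option
  is provided. Categorical variables use an uncorrected chi-square over
  the full level cross-tabulation, with Fisher's exact test substituted
  on 2×2 tables when any expected count is below 5. All p-values are
  two-sided and no multiple-testing correction is applied across rows,
  mirroring standard practice for descriptive comparison tables.
* **Survival** — distant-recurrence-free survival uses the Kaplan–Meier
  product-limit estimator and the unweighted log-rank test (chi-square
  reference, df = groups − 1), computed via `lifelines` behind the
  package's curve/test types; the test suite checks both against
  brute-force oracles (hand product-limit; per-event-time hypergeometric
  expectations). Ties are resolved events-before-censorings. Deaths from
  causes other than breast cancer censor the observation at the death
  time (conventional DRFS); a composite-event mode treating any death as
  an event is available.
* **Cost** — avoided cost = requests × do-not-send fraction × unit cost,
  default $4,000 per assay.

## Synthetic cohort

No patient-level data ship with the package; the generator emulates the
kind of clinical population on which such a triage rule is validated so
the whole pipeline is testable.

What it models:

* marginals of a testing-referral population: age truncated-normal
  (mean 59, sd 11, range 26–87), tumor size lognormal (median ≈1.6 cm),
  grade mix 23/61/16% (I/II/III) with Nottingham-score and
  mitosis-component splits inside each grade, 86% node-negative, 92%
  PR-positive, 2% HER2-equivocal;
* grade-conditional marker distributions (ER and PR H-score means fall
  and Ki-67 rises with grade, Ki-67 gamma with grade means 8/14/35%) —
  grade–Ki-67–PR coupling is what makes grade III cases concentrate in
  the send arm;
* a latent true recurrence score
  `RS = mean unrounded Magee score + N(0, 4.0) + 3.0·1[PR H-score < 10]`,
  rounded to an integer and clamped to [0, 100] for the observed assay
  value. The PR-negative bump makes discordant cases (expected ≤25,
  actual >25) enrich for PR-negative tumors, the mechanism by which PR is
  the one variable separating discordant from concordant cases;
* therapy assignment conditional on the observed assay band (>25 mostly
  chemo-endocrine, ≤25 mostly endocrine alone), follow-up
  truncated-normal around 72 months, and a monthly recurrence hazard
  `4×10⁻⁴ · exp(0.09·(RS_latent − 20))`, halved by chemotherapy, with a
  1% other-cause death rate censoring follow-up.

The noise sd, PR bump and within-grade mitosis split were calibrated once
so that the seeded default cohort (n = 2196) triages ≈70% of cases
do-not-send at ≈95% do-not-send accuracy — the operating point of the
published rule — and then frozen; they are ordinary defaults of
`SimulationParams`, not tuned per run.

What it does **not** model: inter-observer variability in H-score/Ki-67
reading, histologic-type structure, the assay's internal gene-level
behavior, correlation between nodal status and other variables, and
calendar-time effects. Passing pipeline tests on synthetic data therefore
demonstrates correctness of the computations and internal consistency of
the operating point, not the clinical performance of the rule on any real
population. The synthetic expect-high arm is also much smaller than in a
real referral population (all-three-scores ≥31 is rare without
HER2-positive cases), so expect-high accuracy estimates on synthetic data
are noisy.

## Problem sizes and reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; cohort generation and the report pipeline are
bit-reproducible for a fixed configuration. The test suite uses a default
cohort of n = 2196 (one seeded draw, shared as a fixture), 60–250
replicates for Monte-Carlo recovery checks, 2000 null simulations for the
log-rank type-I-error calibration, and 120 replicates at n = 200 per arm
for its power check — sizes chosen so sampling error is well below each
assertion's band.

## Known limitations

* The coefficient transcription is verified against the single published
  worked example plus structural constraints; that is a necessary, not a
  sufficient, check of every digit.
* Accuracy measures condition on cases referred for testing; the package
  does not model referral bias beyond the grade mix.
* The log-rank test relies on the chi-square approximation; with very few
  events (the norm for DRFS in low-risk disease) exact methods would be
  preferable, and p-values on tiny discordant subsets should be read
  cautiously.
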