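# Methods

## Generative models of reality monitoring

All four accounts share a two-channel (left/right orientation) equal-variance
Gaussian signal-detection scaffold. Per trial, the perceptual sample is
`X ~ N(μ_X, I)` with `μ_X = [1,0]`, `[0,1]` or `[0,0]` for a left-tilted,
right-tilted or absent stimulus, and the vividness sample is `V ~ N(μ_V, I)`
with the subject's mean vividness `V_S` on the imagined channel. Across
subjects `V_S ~ N(2.5, 1)` on the 1–5 rating scale, and by the symmetry of
the two orientations imagery is always simulated on the left channel, with
the stimulus congruent, incongruent or absent relative to it.

The accounts differ only in how the experienced percept `P` and imagery `I`
are composed: source separation keeps them apart (`P = X`, `I = V`);
Perky-style suppression explains congruent input away (`P = αX − V`,
`I = V`); source mixing fuses them into a single experience
(`P = I = V + αX`); and the two-parameter variant decouples the weights
(`P = X + αV`, `I = V + βX`, reducing to one-parameter mixing at
`α = β = 1`). The reality judgment thresholds the experience: *real* iff
`max(P) > T`, with `T = 2.5` fixed at the population-mean vividness.

Decisions the readout leaves open, fixed here:

- **Scalar readout of the 2-vector percept.** Judged real iff the maximum
  channel strictly exceeds `T`; the reported orientation is the argmax
  channel. This supports the experiment's three-way response
  (no / left / right) and the wrong-grating exclusion. Ties at the threshold
  (measure zero) are judged *imagined*, ties between channels go to the
  left channel.
- **Vividness report.** The imagined-orientation channel of `I`, kept
  continuous for model predictions and discretised (clip to [1,5],
  round half up) only when emitting rating-scale data.
- **Mixture weights.** `α = β = 1` by default for all figure-style
  simulations; configurable everywhere.
- **V_S is not truncated at zero** by default (the population model is the
  plain normal; negative draws occur on ~0.6% of subjects). A truncation
  flag exists on the cohort simulator for sensitivity analysis.
- **Task-engagement gains.** `attention_gain` scales `μ_X`, `imagery_gain`
  scales `V_S`; the sweep grid defaults to {0.25, 0.5, 0.75, 1.0} in each
  dimension.

## Analytic oracles

With identity covariances the two channels of `P` are independent Gaussians
whose moments follow from the model equations with `V_S` marginalised
(its marginal contribution makes the imagined-channel variance of `V` equal
to 2), so

    p_real = 1 − Φ((T − μ₁)/σ₁) · Φ((T − μ₂)/σ₂).

The expected vividness conditional on the judgment is computed by
deterministic 2-D quadrature (tolerance 1e-6) over the joint Gaussian of the
imagined-channel percept and imagery experience, combined with the other
channel's independent exceedance probability; when the two are uncorrelated
the conditioning is inert and the population mean is returned exactly, and
when they are perfectly correlated (one-parameter mixing, where `I = P`) the
integral collapses to one dimension. The unit tests verify the quadrature
against the closed-form truncated-Gaussian moment identity, and the
Monte-Carlo simulator against both.

Non-identity covariances raise an unsupported-configuration error rather
than silently extending formulas that assume channel independence.

## Qualitative signatures and adjudication

Each account is summarised by four signs: the condition effect on the
"real" rate (congruent − incongruent) and the real-minus-imagined vividness
contrast within the congruent, incongruent and absent conditions. The
canonical patterns are (0,0,0,0) for source separation, (−,−,−,−) for
suppression and (+,+,+,+) for mixing.

Observed signatures come from fitted statistics: the condition effect from
the BIC-selected logistic model (a term eliminated by selection counts as
sign 0) and the vividness contrasts from the ordinal models. An estimate
counts as a non-zero sign only when `|estimate/SE|` exceeds a zero-band,
default 2.50 — Bonferroni 0.05/4 across the four contrasts — so the
familywise false-sign rate under a null account stays near 5%. An
unidentified contrast (singular information matrix, e.g. when the judgment
quasi-separates the ratings) carries sign 0.

Match scoring weights evidence asymmetrically: a reliably observed effect
scores +2 for a model predicting the same sign and −2 for a model predicting
the opposite sign *or no effect*; an observed zero scores +1 for a model
predicting zero and 0 for a model predicting an effect (the data may simply
be underpowered for that contrast). The asymmetry matters in practice: the
wrong-grating exclusion can empty the congruent real-judged cell under the
suppression account, zeroing its vividness contrasts, and a symmetric score
would then hand those datasets to the null account despite a decisive
negative condition effect. A model's score is its best over the α grid
({0.5, 1, 2} by default); ties are reported, never broken.

Model recovery synthesises both experiments under each account
(500 subjects per condition, 20 replicates per account by default), runs the
full pipeline, and tabulates generative against best-matched account;
ties split their replicate evenly so rows sum to the replicate count.

## Synthetic behavioural experiments

Each simulated subject carries a mean vividness `V_S` and a discrimination
sensitivity d′ drawn jointly: a latent bivariate normal with correlation
−0.2 feeds a Gaussian copula whose d′ margin is a two-component mixture —
an "engaged" component `N(2.1, 0.73)` (truncated at 0) and, with
probability 0.25, a near-chance component (half-normal, scale 0.1)
modelling participants whose viewing conditions made the gratings
effectively invisible. After binomial measurement noise on the 40-trial
block this puts roughly 16–18% of subjects below the 55%-accuracy exclusion
threshold. The copula keeps the realised `V_S`–d′ correlation close to the
configured target; note that the exclusion cascade then restricts the d′
range, so the *post-exclusion* correlation is attenuated (anywhere from
−0.05 to −0.2 at typical sample sizes).

Nine pre-critical vividness ratings per subject are the discretised `V_S`
plus trial-to-trial noise (SD 1, a choice the task description does not
constrain); the critical trial is generated by the chosen account; the
40-trial discrimination block is equal-variance 2AFC identification with an
unbiased criterion (accuracy `Φ(d′/2)`), balanced 20/20 and shuffled.
Debrief flags (technical ~1%, multiple participation ~1%, non-imaginer ~3%)
are independent Bernoulli draws. Confidence is a noisy monotone function of
`|max(P) − T|`; the behavioural analyses place no load on its calibration,
so this mapping is documented as arbitrary.

What the generator does *not* emulate: stimulus rendering and contrast
ramps, response-time structure, within-subject vividness drift, sequential
or learning effects, questionnaire-based vividness, and any model
misspecification — the critical trial is generated by exactly the account
under test, so recovery results certify the adjudication procedure, not the
robustness of the accounts to misspecified data.

## Behavioural statistics

- **Exclusions**, applied in order and each counted on the survivors of the
  previous step: technical issues; multiple participation; discrimination
  accuracy < 0.55 (strict); self-reported non-imaginers; and, when a
  stimulus was present, "real" reports of the orthogonal grating. With no
  stimulus there is no orthogonal grating, so any "real" report is an
  analysable false alarm and nothing is excluded at the last step.
- **Sensitivity.** Discrimination d′ treats left as signal,
  `d′ = z(H) − z(FA)` with the log-linear correction (0.5 added to each
  cell, 1 to each denominator), so perfect blocks stay finite. Any monotone
  convention would do; this one is fixed and documented. Detection
  sensitivity is `d′/√2`. Over 10,000 simulated 40-trial blocks at
  d′ = 2.1 the estimator's mean lands within ±0.15 of the truth
  (small-sample bias of the correction, tolerated and tested).
- **Reality-judgment model.** Binary logistic regression (imagined = 0,
  real = 1) on condition, detection d′, mean pre-critical vividness and
  their pairwise interactions; continuous covariates are mean-centred so
  main effects stay interpretable when an interaction survives. Backwards
  elimination removes, one at a time, the term whose removal lowers BIC the
  most (main effects protected under their interactions) until no removal
  lowers it. Reported: coefficients, SEs, CIs, odds ratios, BIC,
  Nagelkerke R² `[1 − (L₀/L₁)^{2/n}] / [1 − L₀^{2/n}]`, and 0.5-threshold
  classification accuracy. Separation is flagged; the fit falls back to
  BFGS when the Newton Hessian is singular. Condition is treatment-coded
  with incongruent as reference (effects coding available). Note the
  stepwise search gives a spurious condition term several survival routes,
  so its null retention rate is ~7%, not the ~2% a single χ² test against
  `ln n` would suggest.
- **Vividness by judgment.** Proportional-odds (cumulative logit; probit
  available) model of the 1–5 critical-trial rating on judgment, condition
  and their interaction, reporting the real-minus-imagined contrast within
  each condition with delta-method SEs. Positive contrasts mean higher
  vividness on real-judged trials.
- **Group tests.** Two-sided pooled-variance (Student) t-tests on
  subject-mean pre-critical vividness split by the reality judgment, per
  condition, with Cohen's d and CIs; plus the Pearson correlation between
  pre-critical vividness and discrimination d′. No multiplicity correction
  is applied (the reported p-values are uncorrected by design).

## Synthetic neural patterns and decoding

Per participant and trial the pattern is
`strength_axis · loading · (rating − 2.5) + content_direction[stimulus] ·
snr(rating) + amplitude_slope · (rating − 2.5) + modality_offset + noise`,
with 50 features, 200 trials per modality, uniform 4-level ratings, unit
noise and loading 0.5 by default (planted low/high separation of 1 noise SD
along the strength axis, Bayes accuracy `Φ(0.5) ≈ 0.69` before estimation
loss). The strength axis is shared between imagery and perception (switchable
off, which abolishes cross-decoding by construction); content fidelity
doubles per rating step (0.1, 0.2, 0.4, 0.8), making stimulus identity more
decodable from high-rating trials; the overall-amplitude slope defaults to
0 (strength is carried by pattern geometry, not mean activation).

Decoding pipeline: ratings binarised (1–2 low, 3–4 high); participants with
fewer than 10 trials per class per modality excluded (strength) or fewer
than 2 trials per stimulus per level (content); majority class down-sampled
within modality; feature means removed per modality so only relative
differences remain (balancing and centring are idempotent). The classifier
is a linear discriminant on a Ledoit–Wolf-shrunk pooled covariance
(shrinkage estimated on standardised features), implemented internally for
speed and verified prediction-identical to the scikit-learn shrinkage-LDA
reference in the test suite; features may outnumber trials. Strength
cross-decoding averages the two train/test directions; content decoding is
pairwise over the six stimulus pairs, trained on one modality's low- or
high-rating trials and tested on all trials of the other.

Group inference permutes class labels within modality 25 times per
participant before decoding; the group null is bootstrapped by drawing, for
each sample, one permuted accuracy per participant (every participant
included once) and averaging, with the one-sided p-value add-one smoothed.
On signal-free data the test rejects at ~5–6.5% at nominal 5% for cohorts of
a dozen or more participants; with very small cohorts (~6) the
25-permutation null is too coarse and the test runs liberal (~9%) — a known
granularity limitation of the procedure, relevant when applying it to small
samples.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed or generator; a single
integer seed expands into independent substreams, and identical seeds
reproduce datasets bit-exactly. Default study sizes: Monte-Carlo oracle
checks at n = 100,000; recovery at 500 subjects per condition × 20
replicates per account; selection calibration at 50–150 replicates of
n = 300; decoding calibration at 400–600 cohorts of 12 participants
(40 trials per modality, 10 features). These sizes put Monte-Carlo error
well below the effects under test while keeping the full suite and the
acceptance script in the minutes range on one CPU.

## Known limitations

- The adjudication is qualitative (sign patterns); the package deliberately
  does not fit α/β to data or compute Bayes factors.
- The reality threshold is fixed and shared across subjects; dynamic or
  subject-specific thresholds are out of scope.
- The analytic oracles require identity channel covariances.
- Passing recovery and calibration on synthetic data shows the pipeline is
  sound under the generative assumptions, not that real data satisfy them.
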