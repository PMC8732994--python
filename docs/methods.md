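# Methods

## The emodiversity index

Emodiversity treats a person's self-reported emotions like an ecologist
treats species counts: what matters is not only how much emotion there
is, but how many distinct emotions are present and how evenly experience
is spread across them. Given mDES ratings r_i ∈ {0..4} over the 18
emotions, the index is computed as

1. x_i = r_i − 2 (rescale to [−2, 2]), then intensity s_i = σ(x_i) with
   the standard logistic σ(x) = 1/(1+e^(−x));
2. proportions p_i = s_i / Σ_j s_j over all 18 items;
3. D_S = −Σ_{i∈S} p_i ln p_i for S = all, positive (10 items), negative
   (8 items), in nats.

Conventions, and why:

- **Sign.** The literal p·ln p sum is negative; we return its negation so
  larger values mean a more diverse emotional life, matching how the
  index is discussed (e.g. "lower positive emotional diversity"). Only
  the sign, not any ordering, depends on this choice.
- **Logistic.** The parameter-free standard sigmoid, centred at the
  scale midpoint with slope 1. It guarantees strictly positive
  intensities — a participant who answers "not at all" everywhere still
  has well-defined proportions (uniform, hence maximal diversity ln 18).
  This is a deliberate property of the transform, not an edge case: the
  index measures *relative* abundance, and an all-zero profile carries no
  evidence of concentration.
- **Global denominator.** The proportions divide by the sum over all 18
  emotions for every subset; positive/negative diversity merely restrict
  the summation set. This makes total = positive + negative hold exactly
  and is the literal reading of the procedure. The alternative
  convention — renormalizing within each valence — is available via
  `within_valence_denominator=True`; it breaks additivity and is off by
  default.
- **Bounds.** Intensities live in (σ(−2), σ(2)) ≈ (0.119, 0.881), so
  total diversity is bounded: the maximum ln 18 ≈ 2.8904 occurs exactly
  when all ratings are equal. Because entropy is Schur-concave, lattice
  minima sit at vertices of the intensity box (every rating 0 or 4);
  scanning those vertices puts the minimum at four 4s against fourteen
  0s, ≈ 2.4169 nats. A single 4 against seventeen 0s gives 2.5882 — a
  useful landmark, but not the global minimum.

Mean positive and mean negative emotion (arithmetic means of the raw
ratings per valence block) are computed alongside, as the adjustment
covariates for all models.

## Inferential models

**Demographic tests.** Group comparisons from summary statistics use the
Welch unequal-variance t (with Welch–Satterthwaite df); 2×2 categorical
tables use the chi-square with the Yates continuity correction. These are
the dialects under which a published CHR/HC demographic table's printed
statistics are reproduced from its printed summaries — the pooled t and
the uncorrected chi-square give visibly different values (17.9 vs 16.30;
3.16 vs 2.50), so the choice is empirically pinned, and both tests keep
the alternative accessible via arguments.

**General linear models.** All focal inference is ordinary least squares
with an intercept:

- Group differences: z(diversity metric) ~ CHR indicator +
  antipsychotic + matching-valence mean emotion (both means for the
  total metric). The coefficient is the adjusted group difference in SD
  units.
- Symptom associations: z(SIPS symptom total) ~ z(diversity metric) +
  antipsychotic + matching-valence mean emotion. The direction (symptoms
  regressed on diversity) is a modelling choice; with both variables
  standardized and identical covariates, the focal partial correlation
  is symmetric in direction, so little rides on it. The analysed sample
  defaults to CHR participants only (≥ 10 required) — healthy-control
  symptom variance is near zero — with `chr_only=False` available.

Each fit reports b, the 95% CI from the t distribution, a two-sided p,
and the focal term's **squared partial correlation** t²/(t² + df_resid)
as the per-term effect size; whole-model R² is emitted alongside.
Missing values exclude a participant listwise from the models that need
them, with a logged count. p values are unadjusted for multiplicity.

## Item profiling

For each SIPS symptom, participants are split into k = 10 folds by a
seeded uniform shuffle (no stratification: the criterion is ordinal with
heavy ties, which makes stratification ill-defined). Within each
training fold, the zero-order Pearson correlation of each of the 18
items with the criterion is computed; the top `n_keep` (default 3, the
size of a publishable "top emotions" row; a |r|-threshold mode is also
exposed) items by |r| are selected, signed by their correlation, and
combined as a unit-weighted composite of training-standardized ratings.
The composite is evaluated on the held-out fold; `cv_composite_r` is the
mean held-out correlation and is leakage-free by construction. Items are
reported with the mean and SD of r across the k training fits — the
parenthetical dispersion is fold-to-fold variability, not a standard
error of r. Final ranking uses |mean r| with ties broken by the canonical
item order. Zero-variance items receive r = 0 with a warning; a training
fold with a constant criterion is an error, and symptoms constant in the
analysed subset are skipped with a warning rather than failing the run.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
calibrated to published CHR/HC group summaries (47/58 participants; age
19.04 ± 1.63 vs 19.24 ± 2.58; parent education 15.66 ± 2.20 vs
15.71 ± 2.68; 26/21 vs 22/36 male/female; 9/47 CHR antipsychotic use;
SIPS totals 11.45/9.28 vs 0.41/0.24):

- **Emotions.** Each participant draws standard-normal latents z over
  the 18 items, exchangeably correlated within valence (ρ = 0.3) and
  independent across valence. The item value mean + sd·z is cut at fixed
  thresholds −1.5, −0.5, 0.5, 1.5 to produce the 0–4 rating. Threshold
  discretization (rather than rounding a truncated normal) keeps the
  rating's moments and its correlation with anything Gaussian in closed
  form. Default latent means make the CHR positive profile concentrated
  on one dominant item (low positive diversity) and the CHR negative
  profile uniformly elevated (higher negative diversity) relative to
  controls; item-level descriptives are unpublished, so these are free
  parameters chosen to produce the qualitative group pattern.
- **Symptoms.** Each SIPS item is clip(round(b + w·z + ε), 0, 6) with
  Gaussian noise (SD 1.5). The intercept b is solved from
  E[S] = Σ_{k=1..6} P(x > k−½) so the group's symptom-total mean equals
  its calibration anchor exactly in expectation, whatever the loadings —
  editing loadings never drifts the planted means. Healthy-control
  loadings are scaled by 0.15. Default loadings encode the qualitative
  pattern of published item–symptom correlations (sadness/anger up, joy
  down); they are illustrative, not estimates.
- **Planting effects.** Because the rating and the symptom are both
  threshold transforms of a bivariate-normal pair, their Pearson
  correlation is a closed form in orthant probabilities;
  `plant_item_effect` root-finds the loading that hits a requested
  item–criterion r (|r| < 0.9) and errors with the attainable bound when
  the noise model cannot reach the target.
- **Demographics** are independent Gaussians/Bernoullis per group;
  antipsychotic use is independent of everything else. A single
  `numpy.random.default_rng(seed)` instance drives a run; no global
  state.

What the generator does **not** emulate: the unpublished raw covariance
between specific emotions and symptoms, floor effects and skew of real
Likert responses beyond what thresholding induces, informative
missingness, or any dependence of medication on severity. Passing
recovery tests therefore demonstrate that the estimators are correct
under the stated data-generating model, not that the published effect
sizes are reproduced — those require the original participant data.

## Recovery studies

Two planted-truth studies back the model code (and are what the
acceptance script reruns):

- **Group GLM** (200 replicates, 500 per group): both groups are drawn
  from one emotion distribution and every CHR participant's positive
  diversity is shifted by −0.5 sample SDs at the score level. The shift
  is applied after scoring, not through emotion means, because a
  generator-level shift would also move the mean-emotion covariate and
  leave the true adjusted coefficient undefined; the score-level plant
  keeps the true standardized partial coefficient exactly computable per
  replicate, so both bias and 95% CI coverage are well-defined checks.
- **Profiler** (50 runs, 2000 CHR): sadness→N1 and guilt→P2 planted at
  true r = 0.5 via the closed-form solver; the planted item should rank
  first for its symptom essentially always at this n, and
  criterion-permuted nulls bound |cv composite r| near zero.

Problem sizes (n = 5000 for moment checks, 200 replicates, 50 profiler
runs) were chosen so Monte-Carlo error is a small fraction of each
tolerance while a full test run stays in the tens of seconds.

## Pipeline

`emodiv run` executes simulate (or read) → score → analyze (3 group
models + 6 association models) → profile (11 symptoms) → report. Outputs
are CSV with fixed column order and a JSON manifest carrying the seed,
a configuration hash and SHA-256 digests of the tables; re-running a
configuration reproduces byte-identical score and profile tables. The
markdown report contains a demographics block (Welch t / Yates χ² on the
run's own cohort), standardized diversity summaries by group, the GLM
table and the top-3 item profiles; degenerate cohorts (a missing group)
get an explanatory note instead of a demographics table.

## Known limitations

- Printed regression coefficients and item–symptom correlations from the
  motivating study are not reproducible without its raw data; the
  package validates machinery, conventions and planted-truth recovery
  instead.
- The exchangeable-within-valence latent correlation is a simplification;
  real mDES items show structured correlations. It is configurable but
  not estimated.
- The profiler's selection size is a fixed top-n per fold; no nested
  tuning of n_keep is attempted.
- OLS inference assumes approximately Gaussian residuals; diversity
  scores are bounded, so very small samples may show mild CI
  miscalibration.
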