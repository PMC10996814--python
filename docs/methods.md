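# Methods

## Overview

`icisurv` implements a hybrid approach to per-patient survival prediction
under immune checkpoint inhibitor (ICI) therapy: mechanistic "mathematical
biomarkers" are estimated from longitudinal tumor-burden imaging series via
a master ordinary differential equation, combined with routine clinical
features, and fed to a discrete-time logistic-hazard neural network whose
output is a per-patient survival curve. The original 93-patient trial
cohort is not publicly deposited, so a synthetic-cohort generator with the
same statistical structure is a first-class component: it defines the
conditions under which every downstream stage is validated.

## Mechanistic model

Normalized tumor burden ρ(t) (burden divided by burden at treatment start,
ρ(0) = 1) follows

    dρ/dt = ρ (α0 − μ + Λμ) + ρ² (−Λμ) = a ρ − b ρ²,

with α0 the intrinsic pre-treatment growth rate (day⁻¹), μ the tumor kill
rate due to therapy (day⁻¹) and Λ the dimensionless anti-tumor immune
state. Negative μ and Λ are legitimate (growth faster after treatment than
before). The logistic-form equation has the closed-form solution

    ρ(t) = a / ((a − b) e^{−a t} + b)    (a ≠ 0),
    ρ(t) = 1 / (1 + b t)                 (a = 0).

This algebraically equivalent rewriting of the textbook form
a·e^{at}/(a + b(e^{at} − 1)) is used because it is cancellation-free for
|a t| → 0 and exact at the a = b equilibrium (ρ ≡ 1); the naive form loses
five to six digits there. For b < 0 with growth the denominator can cross
zero in finite time; the solver raises a domain error rather than clamping,
since burdens are observations and a diverging fit is a modeling failure.

Two further derived quantities: α1 = ln ρ(t1) / t1, the effective growth
rate at first restaging t1, with the prognostic dichotomy favorable iff
α1 ≤ 0.002 day⁻¹; and the canonical limit α1 → α0 − μ as t1 → 0 (the net
initial growth rate a − b, since ρ(0) = 1).

### Biomarker fitting

(μ, Λ) enter the trajectory only through (a, b), so they are only jointly
identified given α0. The fitter minimizes the sum of squared residuals on
log burden (a multiplicative error model, natural for volumes) over (a, b)
by Nelder–Mead from eight deterministic random starts around a crude
log-slope initialization, then reports the canonical representative
μ = α0 − a + b, Λ = b/μ (Λ = 0 when μ = 0). A flat series with α0 = 0 is
canonicalized to exactly (0, 0). α0 is an input (in the original study it
comes from pre-treatment imaging unavailable here; the generator supplies
it; absent values default to 0 with a warning).

## Synthetic cohort generator

The generator emulates the published cohort table, not the raw trial data:

* Continuous features (μ, Λ, age, baseline neutrophil and lymphocyte
  counts, plus α0) are drawn from a two-sided scaled-Beta family: with
  probability ½ the value lies above the published median,
  `median + (hi − median)·Beta(1, s⁺)`, else symmetrically below. The
  median is matched exactly by construction, the published range is
  respected, and the one-sided shape constants s (in
  `cohort.CONTINUOUS_SPECS`) control tail weight — heavy-tailed for μ and
  Λ (whose published ranges are far wider than their interquartile spread),
  broad for age. α0 is not tabulated in the source cohort; its default
  (median 0.01 day⁻¹, range 0.001–0.05) is a realistic volumetric growth
  rate for untreated solid tumors.
* Categorical features use the published proportions. The histology coding
  reserves the two levels with zero patients after eligibility screening
  (Small Cell, Purely Undifferentiated): the generator never emits them but
  the encoder keeps their columns, mirroring the original study's handling
  of imbalanced categories. KPS is drawn on {0.6 … 1.0} with median 0.8.
* Burden series are simulated from the closed-form solution on a restaging
  schedule (60, 120, …, 300 days; truncated before any finite-time blow-up)
  with multiplicative lognormal measurement noise (σ = 0.05 by default);
  α1 is then computed from the noisy first-restaging point, exactly as the
  pipeline would.
* Survival: ground-truth per-bin hazards
  h_ij = sigmoid(logit(b_j) + Σ_f β_f z_if) on internally standardized
  features, with b_j = 0.1 per bin over 20 bins spanning a 730-day horizon
  (median survival just under a year, typical of the trial population).
  Event times are placed uniformly within the sampled bin so the pipeline's
  own discretization is exercised nontrivially. Censoring combines an
  administrative horizon with independent uniform random censoring whose
  activation probability is calibrated toward the target rate (default
  0.25); an unreachable target warns and reports the achieved rate.
* Default effects β load on both mechanistic and clinical features
  (μ −0.5, Λ −0.3, α1 +0.8, baseline neutrophils +0.6, lymphocytes −0.3,
  ever-smoker +0.4, age +0.3): protective kill rate and immune state,
  harmful rapid regrowth and neutrophilia, following the qualitative
  directions reported for this therapy setting. These defaults are the
  study conditions for the three-arm comparison.

What the generator does *not* emulate: lesion-level imaging, adverse-event
dynamics (maximum AE grade is sampled as a static baseline categorical,
reproducing — without resolving — the potential outcome leakage of treating
an on-treatment variable as a baseline feature), correlations between
clinical features, and any treatment-arm effect on the hazard. Passing
tests therefore demonstrate method correctness and recoverability under a
faithful-but-idealized data-generating process, not clinical performance.

## Preprocessing

Multi-level categoricals are one-hot encoded with all declared levels kept
(no reference-level drop; the network has no intercept-collinearity
problem and per-level attributions stay interpretable); binary yes/no
features keep their 0/1 coding; KPS is treated as continuous. Hybrid = 31
encoded columns, clinical-only 28, biomarker-only 3. The
neutrophil-to-lymphocyte ratio is deliberately never constructed (it would
be collinear with its components and muddy the importance analysis).

Continuous columns are standardized with training-set statistics only,
refit per fold; one-hot columns pass through. Time is discretized on an
equidistant grid of 20 bins from 0 to the maximum training duration, with
a (left-open, right-closed] interval convention — an event exactly on an
edge belongs to the earlier bin (the convention is arbitrary; this one
makes the perfect-forecaster step fall at the event time). Test durations
beyond the training horizon clamp to the last bin with a warning.

Splits: test = ⌈0.2 n⌉ patients, validation = 20% of the remainder (59/15/19
for n = 93). The k-fold scheme partitions patients into 5 near-equal
groups and enumerates all ordered (test group, validation group) pairs:
20 folds, each patient in the test set of exactly 4.

## Logistic-hazard network

A single-hidden-layer perceptron maps the scaled features to one hazard
per time bin: affine → batch-norm → ReLU → dropout(0.2) → affine →
sigmoid. Hidden width is the floor of the mean of input and output widths
(25 for the 31-feature hybrid arm). Training minimizes the right-censored
discrete-time negative log-likelihood

    L = −(1/N) Σ_i [ Σ_{j<k_i} log(1−h_ij) + δ_i log h_{i,k_i}
                     + (1−δ_i) log(1−h_{i,k_i}) ],

equivalent to binary cross-entropy over person-period expanded targets,
by Adam (learning rate 0.07, conventional moment decays 0.9/0.999,
ε = 10⁻⁸) in minibatches of min(50, training size), with per-epoch
validation, early stopping (patience 10, cap 512 epochs) and best-epoch
weight restoration (batch-norm running statistics are restored with the
weights). Hazards are clipped at 10⁻⁷ before logs. Everything is NumPy
with analytic gradients; training is single-threaded and bit-reproducible
under a fixed seed, and a JSON checkpoint round-trips to bit-identical
predictions. Survival curves are cumulative products S_k = Π_{j≤k}(1−h_j),
evaluated between grid points as step functions with S(0) = 1.

Hyperparameter search, when used, samples uniformly from a declared space
and minimizes the mean integrated IPCW Brier score across supplied folds.
The defaults above are used throughout the analysis scripts.

## Evaluation metrics

The censoring survival function Ĝ is Kaplan–Meier on the flipped event
indicator. With Ŝ the step-function prediction:

* IPCW Brier: BS(t) = (1/N) Σ_i [ Ŝ(t|x_i)² 1{T_i≤t, δ_i=1}/Ĝ(T_i⁻)
  + (1−Ŝ(t|x_i))² 1{T_i>t}/Ĝ(t) ], with the left limit Ĝ(T⁻) in the event
  term and Ĝ floored at 10⁻⁴ (floored terms counted and warned).
* IPCW NBLL: the same weighting applied to −log(1−Ŝ) / −log Ŝ, with Ŝ
  clipped at 10⁻⁷.
* Event-time concordance: over pairs with T_i < T_j and δ_i = 1, the pair
  is concordant when Ŝ(T_i|x_i) < Ŝ(T_i|x_j); ties (after rounding to 12
  decimals) credit ½.

Per-time curves are averaged by trapezoidal integration over 100
equidistant interior evaluation points — the extreme tails (t = 0, final
edge) are excluded as degenerate. With zero censoring the IPCW Brier
reduces exactly to the plain Brier score. All three metrics are verified
against naive term-by-term / pair-by-pair enumeration oracles, and the
censoring KM against an independent library implementation.

## Feature importance

Three complementary methods, each treating one-hot blocks as a single
feature (per-level views available):

* Permutation importance (test set): signed metric degradation under
  seeded shuffles of one feature across patients, 20 repeats, with
  quartile spread. Error metrics use permuted − baseline, concordance
  baseline − permuted, so larger is always more important.
* Feature ablation (training set): per-bin change in mean predicted hazard
  when a feature is replaced by the baseline value 0 (the training mean of
  a standardized column); global importance is the bin-sum.
* Integrated gradients (training set): path attribution of each per-bin
  pre-sigmoid logit from a zero baseline. Because the evaluation-mode
  network is piecewise linear, the path integral is computed in closed
  form — each hidden unit contributes its weights times the exact measure
  of the path fraction on which its ReLU is active — so the completeness
  axiom Σ_f IG_f = logit(x) − logit(baseline) holds to machine precision.
  A midpoint Riemann sum (`exact=False`, `n_steps`) is retained for
  comparison; it converges only O(1/n) across ReLU kink crossings. Both
  signed-sum and absolute-sum global aggregations are reported.

Importance computations never mutate the model (asserted by bit-identical
predictions before and after).

## Numerical and design notes

* Problem sizes in the shipped analyses: 93-patient cohorts for the
  single-split and k-fold studies (the trial geometry); 240 patients × 10
  seeds for the three-arm seed-median comparison; 1000 patients × 10 seeds
  for the importance recovery study; 5000 for generator-coefficient
  recovery. These are the package's validation scales; all run in a couple
  of minutes on one CPU.
* The three-arm comparison enforces identical split membership across arms
  (a hard error otherwise) — the comparison is meaningless on different
  test sets.
* A single trailing training example is skipped rather than batched alone
  (batch-norm needs ≥ 2 rows).
* Degenerate inputs: zero-variance continuous columns scale by 1 with a
  warning; all-equal durations still yield a valid grid; cohorts with no
  censoring give Ĝ ≡ 1 and plain (unweighted) metrics.

## Known limitations

* The synthetic generator draws features independently; real cohorts have
  correlated biomarkers and clinical measures, which affects importance
  attribution more than discrimination.
* With 19-patient test sets, single-split metrics are noisy; any claim
  about arm ordering should be read off seed medians, not one split.
* The discrete-hazard likelihood treats a patient censored inside a bin as
  at risk for the whole bin, the standard mild bias of discrete-time
  survival models.
* The concordance estimator follows the definition above; published
  toolchains differ in pair weighting, so absolute C-index values are
  comparable only within this package.
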