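# Methods

This note documents the statistical model, the numerical conventions, and
the design decisions behind `oscillobp`.

## Problem setting

Oscillometric cuff monitors estimate SBP/DBP from features of the cuff
deflation waveform's oscillation envelope. Blood pressure fluctuates
physiologically within a session, so a point estimate without an
uncertainty statement conflates device error with biological
variability. The pipeline quantifies that variability for each subject
from only n = 5 measurements by (i) parametric-bootstrap replication of
the small samples, (ii) a deep-belief-network (DBN) regression estimator
trained on the augmented data, and (iii) percentile confidence limits of
the per-subject mean estimate, whose validity rests on a normality
assumption that the package verifies explicitly.

## Synthetic cohort generator

Real oscillometric study data are not redistributable, so the generator
emulates the *statistical shape* a study of this kind produces, with
known ground truth:

* subject truths `SBP_i ~ N(112, 13²)` mmHg, `DBP_i ~ N(66.5, 9²)` mmHg
  (independent), defaults chosen to sit in the range typical of a
  healthy-volunteer wrist-device cohort;
* per-measurement physiological fluctuation `N(0, 3.4²)` (SBP) and
  `N(0, 3.6²)` (DBP) mmHg — a few-mmHg within-subject scatter;
* the auscultatory reference is the average of two simulated observers,
  each with independent 1 mmHg reading noise;
* features are a fixed linear map of the latent pressures plus i.i.d.
  `N(0, 0.5²)` noise. The loading magnitudes are set so that a linear
  regression on the 11 features recovers the latent pressures with a
  residual sd of ≈3 mmHg — features informative of BP but not
  deterministic. Real envelope features are nonlinear and
  cross-correlated; the generator makes no attempt to model that, so
  passing tests demonstrate correctness of the statistical machinery on
  Gaussian-structured data, not device accuracy on clinical waveforms.

Subject truths violating `SBP > DBP > 0` (≈0.2% at the defaults) and
measurements violating `ref_sbp > ref_dbp > 0` are redrawn; the induced
bias on population moments is ≈0.05 mmHg, far below test resolution.
Each subject consumes its own counter-derived random stream
(`SeedSequence([seed, subject_index])`), so records are independent of
cohort size and generation order.

## Parametric bootstrap

A per-subject scalar sample `x₁..xₙ` is fitted as `N(θ̂, σ̂²)` with the
sample mean and the n−1 standard deviation (the sd, not the variance:
the diagnostic magnitudes only make sense on the mmHg scale). An
artificial sample replicates either

* raw draws (`n_inner = 1`) — used to augment features for DBN training,
  with N = 100 pseudo-samples per feature by default, or
* means of `n_inner = 5` inner draws — the replicated sample-mean
  statistic whose sd is σ̂/√5, used for confidence limits and
  diagnostics.

Diagnostics are the bootstrap bias `β = mean(θ*) − θ̂` (≈0 by
construction, |β| ≲ 4σ̂/√(n_inner·N)) and the bootstrap standard error
`Se* = sd(θ*, n−1)` (→ σ̂/√n_inner). The convergence check reports the
KS sup-distance between the empirical law of `√n·(θ* − θ̂)` and
`N(0, σ̂²)` over an N-grid; it decays at the Dvoretzky–Kiefer–Wolfowitz
rate ~1/√N (log–log slope −0.5 in the tests).

Streams are derived per (subject, column) from one root seed, so
augmentation output does not depend on processing order. The
nonparametric (resample-with-replacement) bootstrap is deliberately not
a user path; the method is parametric throughout.

## DBN regression

Architecture 11–32–32–32 with a linear 2-unit read-out. The first RBM
has Gaussian visibles with unit variance — valid because inputs are
standardized per column (train-set mean/sd; a zero-variance column is a
hard error naming the column). Hidden conditionals are
`sigm(b + vW)` for both visible kinds.

**Contrastive divergence.** `cd_gradient` supports two negative-phase
variants. The default samples both hidden and visible states (Gaussian
visibles with unit-variance noise), which makes the Gibbs chain converge
to the model distribution as k → ∞; the final statistics pair sampled
visibles with their hidden probabilities and are asymptotically
unbiased — this is the variant validated against the exact
enumerable-RBM gradient (cosine > 0.99 averaged over random 2×2
models). Pre-training uses the classical low-noise CD-1 recipe instead
(mean-field reconstruction), which is markedly more stable for
Gaussian-visible layers at the configured learning rates; with sampled
visibles the unit-variance kicks inflate the hidden biases and saturate
the stack before fine-tuning.

**Pre-training.** Greedy and layer-wise: each RBM trains on the previous
layer's hidden probabilities, 200 epochs, learning rates 0.001 (weights)
and 0.01 (biases), momentum 0.9, batches of 10, weights and biases
initialised uniformly on (−1, 1). Non-finite parameters raise a
divergence error advising a smaller learning rate.

**Fine-tuning.** The stack is unrolled into a deterministic feed-forward
network; the read-out layer — not part of the pre-trained stack — is
initialised at zero so the initial prediction is the target mean. The
loss is the batch MSE summed over the two standardized targets; updates
are classical momentum, `v ← η·v − ϵ·∇Ω`, `θ ← θ + v`, with a single
learning rate (0.001) for all fine-tuned parameters; 200 epochs. (The
compact "new weight = −ϵ∇ + ηW" shorthand sometimes quoted for this
update is not usable literally — it would discard the current weights —
so the package implements the standard momentum-on-increment form.)
Back-propagated gradients match central finite differences to 1e−5
relative.

**Output activation.** Hidden layers are sigmoid; the read-out is
linear, since a bounded activation cannot express mmHg targets.

**Ensemble.** 50 members by default, differing only in seed (weight
init, CD noise, batch order); the prediction is the member mean. A
bagging flag instead gives each member its own bootstrap-augmented
training set. Members are seeded by counter-derived children of the root
seed, so the ensemble is reproducible and order-independent.

Training-set targets for augmented records are themselves per-subject
bootstrap draws of the reference pressures; this keeps the feature/target
pairing at the subject level (between-subject variation carries the
signal, within-subject pairing is irreducibly noisy at a few mmHg).

## Confidence limits

Per subject and pressure stream: fit `N(μ̂, σ̂²)` to the five estimates,
draw a 5 × 1000 matrix `μ̂ + σ̂·Z`, take column means, sort ascending,
and report the order statistics at 1-based indices `⌈αN⌉` and
`⌈(1−α)N⌉` with α = 0.025 (for N = 1000: the 25th and 975th values).
SBP and DBP use independent derived streams, so editing one stream never
perturbs the other's limits.

**Known coverage behaviour.** The interval's half-width converges to
1.96·σ̂/√5, so its *empirical* coverage of the subject's generating mean
is `P(|t₄| ≤ 1.96) ≈ 0.878`, not the nominal 95% — the plug-in σ̂ from
five values ignores the Student-t correction. This is an inherent
property of the percentile rule at n = 5, verified in the tests against
the closed form; the intervals are reported as nominal-95% percentile
intervals with this caveat.

## Normality suite

* **Moments.** Kurtosis `m₄/m₂²` and skewness `m₃/m₂^{3/2}` with 1/n
  central moments (identical to the raw-moment expansions, which is
  asserted as an algebraic identity test). Standard errors use the exact
  finite-n Gaussian-null formulas; z-scores are `(kurt − 3)/se_kurt` and
  `skew/se_skew` — the kurtosis null is 3, matching the joint hypothesis
  `kurt = 3 ∧ skew = 0` (centering at 0 would reject every Gaussian
  sample). The joint test rejects when either z-test rejects; its
  Gaussian type-I rate sits between α and 2α as expected for a union
  test.
* **Kolmogorov–Smirnov.** Two-sided sup-distance with both one-sided
  corrections at jump points. The default reference is a normal with
  mean/sd *estimated from the tested sample*, evaluated against standard
  fully-specified-null critical values and p-values — exact finite-n
  (numerical inversion of the D_n distribution) up to n = 10⁴,
  asymptotic Kolmogorov beyond. This combination is conservative in the
  Lilliefors situation (estimated parameters shrink D), and is the
  convention under which the per-subject bootstrap distributions are
  screened; a `lilliefors=True` mode applies the parameter-estimation
  correction (statsmodels p-values, 0.886/√n-type critical values) for
  users who want a calibrated test. Exact p-values are used rather than
  the asymptotic law so that `h = 1 ⟺ D > cv ⟺ p < α` holds
  internally.
* **Spearman.** r is the Pearson correlation of mean-tie ranks
  (bootstrap means are continuous so ties are measure-zero, but
  file-rounded inputs can tie); `z = r·√(N−1)` from the null moments
  E(r) = 0, var(r) = 1/(N−1).
* **Cohort report.** Per-subject statistics of the SBP/DBP
  bootstrap-mean vectors (in generation order for the rank test, so
  independence is testable), averaged across subjects with sds.
  Degenerate subjects (σ̂ = 0) are excluded with a logged count. Both
  the empirical across-subject variance of r and the theoretical
  1/(N−1) are reported, since the two are equally natural summaries and
  agree at ≈0.001 for N = 1000.

## Evaluation

Errors are `estimate − reference`, summarized per measurement by default
(a per-subject aggregation is available through the report tables). AAMI
SP10 pass: |ME| ≤ 5 mmHg and SDE ≤ 8 mmHg. BHS grades use the published
protocol rows A ≥ (60, 85, 95)%, B ≥ (50, 75, 90)%, C ≥ (40, 65, 85)%,
else D, all three thresholds required.

## Problem sizes in the shipped tests

The suite exercises the full pipeline at reduced but statistically
meaningful sizes, chosen as the smallest scales at which each property
is cleanly resolvable: cohorts of 8–85 subjects; bootstrap replications
up to N = 10⁵ for closed-form limits; 2000 simulated subjects for
coverage; 100 enumerable RBMs with 20 000 negative-phase chains for the
CD oracle; a 2000-row training set with a 2-member ensemble for the
noiseless linear-recovery check. The acceptance script runs the full
85-subject, N = 1000 configuration.

## Known limitations

* The generator's linear-Gaussian feature model cannot surface failure
  modes caused by nonlinear or heteroscedastic envelope features.
* The percentile confidence limits undercover at n = 5 (see above); a
  t-calibrated interval would fix this but is outside the implemented
  procedure.
* The identity of features 9–11 is not standardized in the oscillometric
  literature; they are treated as generic informative features.
* The default KS screen is conservative by construction; use the
  Lilliefors mode for a calibrated normality test.
* No GPU path, no alternative optimizers, no hyperparameter search.
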