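# Methods

This note documents the models behind `staircurve`, the defaults and
why they were chosen, and what the synthetic cohort does and does not
emulate.

## The staircase model

The engine implements the transformed up-down rule in its multiplicative
form: after three consecutive correct responses the stimulus level
(presentation duration, arbitrary positive units — the procedure is
scale-free because all steps are multiplicative) is set to 90% of its
value; after every error it is set to 110%. The run counter resets after
every step and after every error, the standard transformed up-down
semantics. A *reversal* is a trial whose step direction differs from
the most recent earlier step; the first step of a track is never a
reversal, and reversal bookkeeping restarts at each block. The block
threshold is the arithmetic mean of the reversal levels after discarding
the first four (even total count) or five (odd total), which always
leaves an even number; fewer than six reversals invalidate the block
(the estimate is absent and the block is flagged, never fatal).

**Convergence.** The textbook analysis equates the per-trial rates of
down and up steps. With the run-counter Markov chain at constant
accuracy *p*, down steps fire at rate p³/(1+p+p²) and up steps at rate
1−p; with *equal* step sizes the balance reduces to p³ = ½, the classic
target p\* = 2^(−1/3) ≈ 0.7937 returned by `convergence_point()`. The
multiplicative rule, however, is slightly asymmetric on the log scale
(|ln 0.9| = 0.1054 > ln 1.1 = 0.0953), so the stationary track
equilibrates where

p³/(1+p+p²) · |ln 0.9| = (1−p) · ln 1.1,

i.e. at p ≈ 0.7802 (`equilibrium_accuracy()`); long stationary
simulations land at ≈ 0.779. The package treats 2^(−1/3) as the nominal
design target — the psychometric model is calibrated so the response
probability *at the true threshold* equals it — and documents the ~1.4
percentage-point equilibrium deficit as a genuine property of the
×0.9/×1.1 rule. In a full simulated protocol, start-of-block transients
(each block starts above or below the new effective threshold and the
track spends correct-heavy runs descending) lift pooled accuracy to
≈ 78.8–79.0%.

**Numerical guards.** Levels are clamped to [10⁻³, 10³]; a step absorbed
by the clamp keeps its direction for reversal bookkeeping but is flagged
on the trial record. A correct run pending at the end of a block is
discarded.

## The psychometric response model

No response-function form is implied by the staircase itself, so one was
chosen: logistic in log-level with a 0.5 guessing floor (the task is a
binary same/different judgement) and a 1 − λ ceiling,

P(correct | x) = 0.5 + (0.5 − λ) · σ( s·(ln x − ln T) + logit c ),
c = (p\* − 0.5)/(0.5 − λ),

so that P(T) = p\* exactly for every observer and block: the level the
staircase nominally tracks coincides with the generative learning-curve
threshold T(n) by construction. Defaults: slope s = 6 (a ±20% change in
duration spans roughly the 0.65–0.85 accuracy range, a plausible
steepness for a duration-limited discrimination), lapse λ ~ U(0, 0.04).
Because of the equilibrium deficit above, the level actually tracked
sits ≈ e^(−0.117/s) ≈ 2% below T(n); at s = 6 this is well inside the
other noise sources.

## The generative learning curve and cohort

Each observer carries ground-truth (α, β, γ): threshold
T(n) = α·exp(−n/β) + γ over blocks n = 1…20 (10 days × 2 blocks),
held constant within a block (piecewise-constant learning, matching
block-level fitting). Defaults are the trained-arm means/SDs of the
emulated study: α = 8.29 ± 1.27, β = 8.12 ± 2.01 blocks,
γ = 1.89 ± 0.11, age 75 ± 8 years (age mean/SD are not reported by the
study; 75 ± 8 spans its 60–95 recruitment range).

(α, β, γ, age) are drawn from a Gaussian copula: a latent multivariate
normal with the configured correlation matrix — defaulting to the
printed study correlations (age–amount 0.565, age–speed −0.435,
age–asymptote 0.548, amount–speed −0.648, amount–asymptote 0.541,
speed–asymptote −0.466; verified positive definite) — mapped through
the marginal means/SDs, with rejection of any draw containing a
non-positive value. Non-PSD specifications are rejected with the
offending entries named. Initial performance α + γ is derived, not
sampled; its positive correlation with α follows from α's dominant SD.

**Day-to-day threshold noise.** Real block thresholds vary far more than
staircase estimation error alone: the study's exponential fits explain
only 63.5% of block variance on average. The generator therefore
multiplies each block's threshold by mean-one lognormal noise,
exp(σZ − σ²/2). σ was calibrated once so that the mean per-subject r²
of the default simulated cohort reproduces 0.635 (sweep over σ at 400
subjects: σ = 0.32 gives mean r² = 0.638 ± 0.008) and then frozen. A
33% day-to-day threshold swing is large but is exactly what the target
goodness-of-fit implies for this signal range.

**Scores.** Pre-test MoCA and MMSE are drawn per arm from a correlated
bivariate normal (latent r = 0.9 — the two instruments track the same
construct), rounded to the integer 0–30 scale and clipped. Trained-arm
gains follow gain = m + b·(pre − pre_mean) + ε with (m, b, ε-SD) derived
from the target marginal gain moments and the target baseline–gain
correlations (MoCA: 6.39 ± 2.96, r = −0.641; MMSE: 4.93 ± 2.54,
r = −0.830) — the compensation structure. Control gains are a pure
practice effect (MoCA 1.17 ± 1.05, MMSE 0.70 ± 0.70). Gains are rounded
to integers and posts re-clipped, after which gain = post − pre holds
exactly. Demographic categories (sex, education band, occupation band)
are Bernoulli draws at the pooled study frequencies. Learning-curve
parameters are sampled independently of the score model, mirroring the
study's null finding between the two domains.

**What the generator does not emulate:** reaction times, within-block
learning, feedback effects, sequential dependencies beyond the staircase
itself, non-random dropout (the optional dropout removes the last
sampled trained subjects), and any causal pathway from age to the
learning parameters (age is correlated, not causal). Passing tests on
this cohort show the *pipeline* behaves correctly under the study's
statistical structure; they cannot validate the psychological model
itself.

## Curve fitting

`LearningCurveRegressor` minimises unweighted squared error under box
constraints α ∈ [0, 10³], β ∈ [10⁻², 10³], γ ∈ [0, 10³] (positivity is
implied by the quantities' meaning) using `scipy.optimize.least_squares`
(trust-region reflective). Initialisation: γ₀ = min(T), α₀ = max(T₁ −
γ₀, 10⁻⁶), β₀ = n_blocks/3; on non-convergence up to three restarts with
lognormal-jittered starts (seeded, so fits are deterministic given input
and settings). At least four valid block thresholds are required; NaN
(invalid) blocks are skipped. r² = 1 − SS_res/SS_tot on the fitted
blocks; for a zero-variance series the convention is r² = 1 if the
residuals are identically zero, else 0. Blocks are indexed n = 1…20 in
the fit while α + γ is reported as the "initial performance" T(0), the
field's convention.

**Identifiability.** Noiseless series on a wide parameter grid are
recovered to 10⁻⁴ relative error. Under the calibrated day-to-day noise
the unweighted estimator is *biased*: the noise is multiplicative
(SD ∝ T) and the model nonlinear, so near-linear noisy trajectories are
absorbed by large-α/large-β fits, inflating α and β and deflating γ
(isolation experiment with pure lognormal noise at σ = 0.32, 400
replicates, no staircase: mean errors γ −0.40, β +2.0, α heavy-tailed).
Weighted or log-domain fitting would reduce this but would no longer be
the plain least-squares procedure being modelled. Consumers of fitted
parameters at r² ≈ 0.6 noise levels should treat individual α, β as
noisy and asymmetric; cohort-level *sign* structure is preserved.

## Statistics

- Pearson r by the product-moment formula; two-sided p from the
  t-transform with n−2 df; two-tier flags at p < 0.05 and p < 0.01
  (the emulated tables mark significance without stating a threshold).
  Zero-variance columns yield NaN with a warning.
- Paired t from the gain summary, t = m/(s/√n), df = n−1; the raw-data
  path agrees with the summary path to float precision.
- Two-sample t: Welch by default (some of the emulated study's printed
  values match Welch, one matches the pooled form; both are available).
- 2×2 chi-square: Σ(O−E)²/E from the margins, df = 1, *no* continuity
  correction — required to reproduce the emulated demographic table.
- No multiple-testing correction by default (none was applied in the
  emulated analysis).
- p values below 0.001 are rendered "< 0.001" rather than "0.000".

## Pipeline determinism

One root `SeedSequence` per run: substream 0 samples the cohort and
scores, substream *i* drives subject *i*'s trial stream; every stage
logs its substream at INFO and the manifest records the seed and a
canonical-JSON sha256 of the config. Identical config + seed gives
byte-identical output tables.

## Problem sizes

Default simulations used throughout the tests and the acceptance script:
28 trained observers × 20 blocks × 70 trials (39 200 trials, a few
seconds), 10⁵-trial stationary diagnostics, 200-subject recovery
studies, and 4000–5000-subject cohorts for moment/correlation checks —
sizes at which binomial/sampling error is small relative to the effects
under test.

## Known limitations

- The equilibrium accuracy of the ×0.9/×1.1 rule (≈ 0.780) sits below
  the nominal 2^(−1/3) target; analyses that assume the track samples
  exactly the 79.4%-point of the psychometric function inherit a ~2%
  threshold offset.
- Fitted α, β, γ are biased at realistic noise levels (see
  Identifiability); the package reports but does not correct this.
- Score distributions are rounded clipped normals, adequate for
  mid-scale MCI cohorts but wrong near the instrument floor/ceiling.
- The trial loop is pure Python; ~10⁶ trials/minute, fine for study-size
  simulations, not for massive parameter sweeps.
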