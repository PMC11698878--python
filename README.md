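# staircurve

Simulation and analysis tools for adaptive cognitive-training studies
that track a perceptual threshold with a **three-down/one-up staircase**
and summarise learning with a **single-exponential curve**.

The scientific setting: older adults with mild cognitive impairment
train on a speeded selective-attention task whose stimulus presentation
time is controlled adaptively — three consecutive correct responses
shorten the presentation time to 90% of its value, every error lengthens
it to 110%. Block-wise threshold estimates (mean of late staircase
reversals) trace a learning curve

> T(n) = α · exp(−n/β) + γ

over training blocks *n*, with α the learning amount, β the learning
speed (larger = slower), γ the asymptotic threshold and α + γ the
initial performance (lower thresholds = better performance). The
correlation structure among (α, β, γ, α+γ) and the relation between
baseline screening scores (MoCA/MMSE) and their training gains
adjudicate the **compensation** account (poorer baselines gain more)
against the **magnification** account (the Matthew effect).

The package provides, for users who want to plan, power or re-analyse
such designs without access to raw patient data:

- `staircurve.cohort` — a synthetic-observer generator: ground-truth
  learning curves with a configurable Gaussian-copula correlation
  structure, a calibrated logistic psychometric response model, and
  pre/post MoCA/MMSE scores with baseline-dependent training gains;
- `staircurve.staircase` — the 3-down/1-up engine: trial updates,
  reversal bookkeeping, the late-reversal threshold estimator, full
  10-day / 20-block protocol simulation, and convergence analytics
  (including the exact drift-balance accuracy of the asymmetric
  ×0.9/×1.1 rule);
- `staircurve.learning_curve` — bounded nonlinear least-squares fitting
  of the exponential curve, exposed as a scikit-learn estimator
  (`LearningCurveRegressor`) plus convenience wrappers;
- `staircurve.stats` / `staircurve.report` — Pearson correlation
  matrices with significance flags, paired and Welch/pooled two-sample
  t-tests (raw or summary statistics), 2×2 chi-square tests without
  continuity correction, and a study-style four-table report;
- `staircurve.pipeline` / CLI — a deterministic, manifest-tracked
  `simulate → fit → stats → report` chain.

## Worked example

```python
import numpy as np
from staircurve import (CohortConfig, ProtocolConfig, sample_cohort,
                        run_protocol, fit_learning_curve, summarize_fits)

cfg = CohortConfig(seed=1)                      # 28 trained + 30 control observers
observers, scores = sample_cohort(cfg)
trained = [o for o in observers if o.group == "training"]

streams = np.random.SeedSequence(2).spawn(len(trained))
fits = []
for obs, ss in zip(trained, streams):
    series = run_protocol(obs, ProtocolConfig(), np.random.default_rng(ss))
    fits.append(fit_learning_curve(series))

f0, o0 = fits[0], trained[0]
print(f"subject {o0.subject_id}: true (alpha, beta, gamma) = "
      f"({o0.alpha:.2f}, {o0.beta:.2f}, {o0.gamma:.2f})")
print(f"fitted: alpha={f0.alpha:.2f}, beta={f0.beta:.2f}, gamma={f0.gamma:.2f}, "
      f"initial={f0.initial_performance:.2f}, r2={f0.r_squared:.3f}")
print(summarize_fits(fits).round(2))
```

prints

```
subject S001: true (alpha, beta, gamma) = (9.74, 5.56, 1.94)
fitted: alpha=8.50, beta=12.91, gamma=0.11, initial=8.60, r2=0.711

            mean     sd
alpha      16.49  33.57
beta        8.50   5.78
gamma       1.77   1.49
initial    18.26  34.34
r_squared   0.66   0.13
```

The first two lines show one observer's generative parameters and what a
20-block staircase run recovers: with realistic day-to-day threshold
variability the fit explains about two thirds of the block-to-block
variance (`r2=0.711`), and individual parameters are only loosely
identified — β and γ trade off against α along the curve. The cohort
summary makes the same point at group level: the mean r² (0.66) sits
near the per-subject signal-to-noise of the design, while fitted α has
a heavy right tail (SD 33.6) because near-linear noisy trajectories are
equally well described by a large-α/large-β curve. This identifiability
limit is a property of 20-point exponential fits, not of the optimizer;
see `docs/methods.md`.

The same chain from a shell:

```bash
staircurve all --seed 1 --out run/
cat run/report/summary.txt
```

writes `trials.csv`, `blocks.csv`, `scores.csv`, `params.csv`, a
four-table report (demographics chi-squares, MoCA/MMSE pre/post
comparisons with paired and between-group t-tests, an 11-variable
correlation matrix) and a `manifest.json` with the seed and config hash.

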