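"""Synthetic observer cohorts for adaptive cognitive-training simulations.

A simulated participant is an :class:`ObserverModel`: a psychometric
response function wrapped around a ground-truth exponential learning
trajectory ``T(n) = alpha * exp(-n / beta) + gamma``, where ``T`` is the
selective-attention threshold (stimulus presentation duration, arbitrary
units), ``n`` the training-block index, ``alpha`` the learning amount,
``beta`` the learning speed (larger = slower) and ``gamma`` the
asymptotic threshold.  Lower thresholds mean better performance.

The cohort generator draws (age, alpha, beta, gamma) from a Gaussian
copula so that the latent correlation structure among learning-curve
parameters and age can be specified directly, and produces pre/post
MoCA and MMSE score records with a baseline-dependent gain model for
the trained arm (compensation structure: larger gains for poorer
baselines) and a small practice effect for controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CONVERGENCE_P",
    "ObserverModel",
    "ScoreRecord",
    "Moments",
    "GainModel",
    "CohortConfig",
    "sample_cohort",
    "true_threshold",
    "p_correct",
    "respond",
    "generate_scores",
]

#: Accuracy targeted by a 3-down/1-up track with equal step sizes: the
#: root of p**3 = 1/2.  The response model is calibrated so that the
#: psychometric function passes through this value at the observer's
#: true threshold.
CONVERGENCE_P: float = 0.5 ** (1.0 / 3.0)

_SCORE_MAX = 30  # MoCA and MMSE are both scored 0-30


@dataclass(frozen=True)
class ObserverModel:
    """Ground-truth generative model of one simulated participant."""

    subject_id: str
    alpha: float   # learning amount, threshold units
    beta: float    # learning speed, blocks (larger = slower)
    gamma: float   # asymptotic threshold, threshold units
    slope: float   # psychometric slope on the log-level scale
    lapse: float   # stimulus-independent error probability
    age: float     # years
    group: str     # "training" or "control"

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.gamma > 0):
            raise ValueError(
                f"alpha, beta, gamma must be positive; got "
                f"({self.alpha}, {self.beta}, {self.gamma})"
            )
        if not self.slope > 0:
            raise ValueError(f"psychometric slope must be > 0, got {self.slope}")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError(f"lapse must lie in [0, 0.1], got {self.lapse}")
        if self.group not in ("training", "control"):
            raise ValueError(f"group must be 'training' or 'control', got {self.group!r}")


@dataclass(frozen=True)
class ScoreRecord:
    """Pre/post cognitive screening scores for one participant.

    ``moca_gain``/``mmse_gain`` equal post minus pre exactly; all scores
    are integers clipped to the instruments' 0-30 range.
    """

    subject_id: str
    group: str
    age: float
    sex: str          # "male" / "female"
    education: str    # ">7y" / "<=7y"
    occupation: str   # "mental" / "manual"
    moca_pre: int
    moca_post: int
    mmse_pre: int
    mmse_post: int

    @property
    def moca_gain(self) -> int:
        return self.moca_post - self.moca_pre

    @property
    def mmse_gain(self) -> int:
        return self.mmse_post - self.mmse_pre


@dataclass(frozen=True)
class Moments:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class GainModel:
    """Linear baseline-dependent gain: gain = mean + slope*(pre - pre_mean) + noise."""

    mean: float
    baseline_slope: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _gain_from_correlation(r: float, gain: Moments, pre: Moments) -> GainModel:
    """Gain model whose (pre, gain) correlation and marginal moments hit targets."""
    slope = r * gain.sd / pre.sd
    noise = gain.sd * math.sqrt(max(0.0, 1.0 - r * r))
    return GainModel(mean=gain.mean, baseline_slope=slope, noise_sd=noise)


def _default_latent_corr() -> np.ndarray:
    # order: age, alpha, beta, gamma
    return np.array(
        [
            [1.000, 0.565, -0.435, 0.548],
            [0.565, 1.000, -0.648, 0.541],
            [-0.435, -0.648, 1.000, -0.466],
            [0.548, 0.541, -0.466, 1.000],
        ]
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition defaults for the simulated cohort.

    Parameter means/SDs mirror the trained-arm summary of the study the
    generator emulates: alpha 8.29 +/- 1.27, beta 8.12 +/- 2.01, gamma
    1.89 +/- 0.11 (threshold units / blocks), with MoCA/MMSE pre-test
    and gain distributions per arm.  ``latent_corr`` specifies the
    Gaussian-copula correlation among (age, alpha, beta, gamma).
    """

    n_training: int = 28
    n_control: int = 30
    dropout_training: int = 0  # sampled subjects that withdraw before training
    alpha: Moments = field(default_factory=lambda: Moments(8.29, 1.27))
    beta: Moments = field(default_factory=lambda: Moments(8.12, 2.01))
    gamma: Moments = field(default_factory=lambda: Moments(1.89, 0.11))
    age: Moments = field(default_factory=lambda: Moments(75.0, 8.0))
    latent_corr: np.ndarray = field(default_factory=_default_latent_corr)
    slope: float = 6.0
    lapse_max: float = 0.04
    # screening instruments, per arm
    moca_pre_training: Moments = field(default_factory=lambda: Moments(14.82, 4.81))
    moca_pre_control: Moments = field(default_factory=lambda: Moments(14.00, 3.35))
    mmse_pre_training: Moments = field(default_factory=lambda: Moments(20.07, 3.67))
    mmse_pre_control: Moments = field(default_factory=lambda: Moments(19.67, 2.73))
    pre_score_corr: float = 0.90  # latent MoCA-MMSE pre-test correlation
    moca_gain_training: GainModel = field(
        default_factory=lambda: _gain_from_correlation(
            -0.641, Moments(6.39, 2.96), Moments(14.82, 4.81)
        )
    )
    mmse_gain_training: GainModel = field(
        default_factory=lambda: _gain_from_correlation(
            -0.830, Moments(4.93, 2.54), Moments(20.07, 3.67)
        )
    )
    moca_gain_control: GainModel = field(default_factory=lambda: GainModel(1.17, 0.0, 1.05))
    mmse_gain_control: GainModel = field(default_factory=lambda: GainModel(0.70, 0.0, 0.70))
    # demographic category probabilities (male, >7y education, mental labor)
    p_male: float = 30 / 58
    p_edu_high: float = 20 / 58
    p_mental: float = 18 / 58
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_training < 2 or self.n_control < 2:
            raise ValueError("group sizes must be >= 2")
        if not 0 <= self.dropout_training < self.n_training:
            raise ValueError("dropout_training must lie in [0, n_training)")
        if not 0 < self.slope:
            raise ValueError("slope must be > 0")
        if not 0.0 <= self.lapse_max <= 0.1:
            raise ValueError("lapse_max must lie in [0, 0.1]")
        if not -1.0 < self.pre_score_corr < 1.0:
            raise ValueError("pre_score_corr must lie in (-1, 1)")
        _validate_corr(np.asarray(self.latent_corr, dtype=float))

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))


_CORR_NAMES = ("age", "alpha", "beta", "gamma")


def _validate_corr(corr: np.ndarray) -> None:
    if corr.shape != (4, 4):
        raise ValueError(f"latent_corr must be 4x4 (age, alpha, beta, gamma), got {corr.shape}")
    bad = [
        (_CORR_NAMES[i], _CORR_NAMES[j])
        for i in range(4)
        for j in range(i + 1, 4)
        if abs(corr[i, j]) > 1 or not np.isclose(corr[i, j], corr[j, i])
    ]
    if not np.allclose(np.diag(corr), 1.0):
        bad.append(("diagonal", "diagonal"))
    if bad:
        raise ValueError(f"invalid correlation entries: {bad}")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        offenders = [
            (_CORR_NAMES[i], _CORR_NAMES[j], corr[i, j])
            for i in range(4)
            for j in range(i + 1, 4)
            if corr[i, j] != 0.0
        ]
        raise ValueError(
            "latent_corr is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.4g}); off-diagonal entries: {offenders}"
        )


def true_threshold(obs: ObserverModel, n) -> float | np.ndarray:
    """Ground-truth threshold at training block ``n``: alpha*exp(-n/beta) + gamma.

    ``n`` may be a scalar or an array of non-negative block indices.
    """
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError(f"block index must be >= 0, got {n}")
    out = obs.alpha * np.exp(-n_arr / obs.beta) + obs.gamma
    return float(out) if np.isscalar(n) or n_arr.ndim == 0 else out


def p_correct(obs: ObserverModel, level, n: float = 0.0, threshold: float | None = None):
    """Probability of a correct response at a stimulus ``level``.

    Logistic in log-level with a 0.5 guessing floor (same/different
    judgement) and a ``1 - lapse`` ceiling.  The location is shifted so
    the function passes through :data:`CONVERGENCE_P` exactly at the
    observer's true threshold for block ``n`` (or at an explicit
    ``threshold`` override), tying the staircase's tracked level to the
    generative learning curve.
    """
    level_arr = np.asarray(level, dtype=float)
    if np.any(level_arr <= 0):
        raise ValueError(f"stimulus level must be > 0, got {level}")
    thr = true_threshold(obs, n) if threshold is None else float(threshold)
    if thr <= 0:
        raise ValueError(f"threshold must be > 0, got {thr}")
    span = 0.5 - obs.lapse
    c = (CONVERGENCE_P - 0.5) / span  # logistic value required at threshold
    z = obs.slope * (np.log(level_arr) - math.log(thr)) + math.log(c / (1.0 - c))
    out = 0.5 + span / (1.0 + np.exp(-z))
    return float(out) if np.isscalar(level) or level_arr.ndim == 0 else out


def respond(
    obs: ObserverModel,
    level: float,
    n: float,
    rng: np.random.Generator,
    threshold: float | None = None,
) -> bool:
    """Draw one Bernoulli response at ``level`` during block ``n``."""
    return bool(rng.random() < p_correct(obs, level, n, threshold=threshold))


def _sample_observers(config: CohortConfig, rng: np.random.Generator) -> list[ObserverModel]:
    n = config.n_training + config.n_control
    corr = np.asarray(config.latent_corr, dtype=float)
    # eigh-based factor tolerates semi-definite specifications
    w, v = np.linalg.eigh(corr)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    means = np.array([m.mean for m in (config.age, config.alpha, config.beta, config.gamma)])
    sds = np.array([m.sd for m in (config.age, config.alpha, config.beta, config.gamma)])

    draws = np.empty((n, 4))
    filled = 0
    while filled < n:
        z = rng.standard_normal((n - filled, 4)) @ factor.T
        x = means + sds * z
        ok = np.all(x > 0, axis=1)  # truncate: resample any draw with a non-positive value
        kept = x[ok]
        draws[filled : filled + len(kept)] = kept
        filled += len(kept)

    lapses = rng.uniform(0.0, config.lapse_max, size=n)
    observers = []
    for i in range(n):
        group = "training" if i < config.n_training else "control"
        observers.append(
            ObserverModel(
                subject_id=f"S{i + 1:03d}",
                age=draws[i, 0],
                alpha=draws[i, 1],
                beta=draws[i, 2],
                gamma=draws[i, 3],
                slope=config.slope,
                lapse=lapses[i],
                group=group,
            )
        )
    return observers


def _round_clip(x) -> np.ndarray:
    return np.clip(np.rint(x), 0, _SCORE_MAX).astype(int)


def generate_scores(
    observers: list[ObserverModel],
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[ScoreRecord]:
    """Draw pre/post MoCA and MMSE records for the given observers.

    Pre-test scores come from a correlated bivariate normal per arm
    (MoCA and MMSE track the same construct), rounded to the integer
    instrument scale and clipped to [0, 30].  Trained-arm gains follow
    the baseline-dependent linear model (negative slope: compensation);
    control gains are pure practice effect.  Gains are rounded to
    integers and posts re-clipped, after which gain == post - pre holds
    exactly.
    """
    n = len(observers)
    z = rng.standard_normal((n, 2))
    rho = config.pre_score_corr
    z_mmse = rho * z[:, 0] + math.sqrt(1 - rho * rho) * z[:, 1]

    records = []
    for i, obs in enumerate(observers):
        if obs.group == "training":
            moca_m, mmse_m = config.moca_pre_training, config.mmse_pre_training
            moca_g, mmse_g = config.moca_gain_training, config.mmse_gain_training
        else:
            moca_m, mmse_m = config.moca_pre_control, config.mmse_pre_control
            moca_g, mmse_g = config.moca_gain_control, config.mmse_gain_control

        moca_pre = int(_round_clip(moca_m.mean + moca_m.sd * z[i, 0]))
        mmse_pre = int(_round_clip(mmse_m.mean + mmse_m.sd * z_mmse[i]))

        moca_gain = (
            moca_g.mean
            + moca_g.baseline_slope * (moca_pre - moca_m.mean)
            + moca_g.noise_sd * rng.standard_normal()
        )
        mmse_gain = (
            mmse_g.mean
            + mmse_g.baseline_slope * (mmse_pre - mmse_m.mean)
            + mmse_g.noise_sd * rng.standard_normal()
        )
        moca_post = int(_round_clip(moca_pre + moca_gain))
        mmse_post = int(_round_clip(mmse_pre + mmse_gain))

        records.append(
            ScoreRecord(
                subject_id=obs.subject_id,
                group=obs.group,
                age=obs.age,
                sex="male" if rng.random() < config.p_male else "female",
                education=">7y" if rng.random() < config.p_edu_high else "<=7y",
                occupation="mental" if rng.random() < config.p_mental else "manual",
                moca_pre=moca_pre,
                moca_post=moca_post,
                mmse_pre=mmse_pre,
                mmse_post=mmse_post,
            )
        )
    return records


def sample_cohort(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[list[ObserverModel], list[ScoreRecord]]:
    """Sample a full cohort: observer models plus pre/post score records.

    Deterministic given ``config`` (including ``config.seed``) unless an
    explicit generator is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    observers = _sample_observers(config, rng)
    scores = generate_scores(observers, config, rng)
    return observers, scores
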