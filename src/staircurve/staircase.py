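"""Three-down/one-up multiplicative staircase engine.

The tracker lowers the stimulus level to 90% of its current value after
three consecutive correct responses and raises it to 110% after every
error.  A reversal is a trial whose step direction differs from the most
recent earlier step; block thresholds are the mean of the late reversals
after discarding the first four (even total) or five (odd total).

``convergence_point`` returns the classic transformed up-down target,
the root of ``p**3 = 1/2`` (~0.7937).  Note that this value assumes
up and down steps of equal size; with the multiplicative 0.9/1.1 rule
the log-step sizes differ slightly (|ln 0.9| > ln 1.1), so a stationary
track equilibrates a little below it (drift balance at ~0.780 correct).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import ObserverModel, respond, true_threshold

__all__ = [
    "DOWN_FACTOR",
    "UP_FACTOR",
    "StaircaseState",
    "TrialRecord",
    "BlockResult",
    "BlockSeries",
    "ProtocolConfig",
    "InsufficientReversalsError",
    "update",
    "detect_reversal",
    "estimate_threshold",
    "run_block",
    "run_protocol",
    "convergence_point",
    "equilibrium_accuracy",
]

DOWN_FACTOR = 0.9   # level multiplier after 3 consecutive correct responses
UP_FACTOR = 1.1     # level multiplier after each incorrect response


class InsufficientReversalsError(ValueError):
    """Raised when a block yields too few reversals for a threshold estimate."""


@dataclass(frozen=True)
class StaircaseState:
    """Current position of the up-down tracker."""

    level: float
    run_count: int = 0               # consecutive correct since the last step/error
    last_step_direction: str = "none"  # "down" | "up" | "none"
    trial_index: int = 0

    def __post_init__(self) -> None:
        if not self.level > 0:
            raise ValueError(f"level must be > 0, got {self.level}")
        if self.run_count not in (0, 1, 2):
            raise ValueError(f"run_count must be 0, 1 or 2, got {self.run_count}")
        if self.last_step_direction not in ("down", "up", "none"):
            raise ValueError(f"bad step direction {self.last_step_direction!r}")


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    level: float          # level presented on this trial
    correct: bool
    stepped: str          # "down" | "up" | "none"
    is_reversal: bool
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.is_reversal and self.stepped == "none":
            raise ValueError("a reversal requires a step")


@dataclass(frozen=True)
class BlockResult:
    block_index: int                    # 1-based
    threshold_estimate: float | None    # None when the block is invalid
    n_trials: int
    n_reversals: int
    accuracy: float
    trials: tuple[TrialRecord, ...]
    valid: bool = True

    @property
    def reversal_levels(self) -> list[float]:
        return [t.level for t in self.trials if t.is_reversal]


@dataclass(frozen=True)
class BlockSeries:
    subject_id: str
    blocks: tuple[BlockResult, ...]

    def __post_init__(self) -> None:
        idx = [b.block_index for b in self.blocks]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError(f"block indices must run 1..{len(idx)}, got {idx}")

    @property
    def thresholds(self) -> list[float | None]:
        return [b.threshold_estimate for b in self.blocks]

    @property
    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(block indices, threshold estimates) of the valid blocks."""
        pairs = [(b.block_index, b.threshold_estimate) for b in self.blocks if b.valid]
        if not pairs:
            return np.array([]), np.array([])
        idx, thr = zip(*pairs)
        return np.asarray(idx, dtype=float), np.asarray(thr, dtype=float)


@dataclass(frozen=True)
class ProtocolConfig:
    """Training-protocol layout: 10 days x 2 blocks of 70 trials by default."""

    n_days: int = 10
    blocks_per_day: int = 2
    trials_per_block: int = 70
    start_level: float | None = None     # block-1 start; None -> factor * true threshold
    start_level_factor: float = 1.5
    block_jitter_sd: float = 0.32        # log-SD of mean-one lognormal day-to-day threshold noise
    level_min: float = 1e-3
    level_max: float = 1e3

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.blocks_per_day < 1:
            raise ValueError("n_days and blocks_per_day must be >= 1")
        if not 60 <= self.trials_per_block <= 80:
            raise ValueError(
                f"trials_per_block must lie in [60, 80], got {self.trials_per_block}"
            )
        if self.start_level is not None and self.start_level <= 0:
            raise ValueError("start_level must be > 0")
        if self.block_jitter_sd < 0:
            raise ValueError("block_jitter_sd must be >= 0")
        if not 0 < self.level_min < self.level_max:
            raise ValueError("require 0 < level_min < level_max")

    @property
    def n_blocks(self) -> int:
        return self.n_days * self.blocks_per_day


def update(
    state: StaircaseState,
    correct: bool,
    level_min: float = 1e-3,
    level_max: float = 1e3,
) -> tuple[StaircaseState, str, bool]:
    """Apply the 3-down/1-up rule to one response.

    Returns ``(new_state, stepped, clamped)`` where ``stepped`` is
    "down", "up" or "none".  The run counter resets after every step and
    after every error.  A step absorbed by the level clamp still counts
    for direction bookkeeping but is flagged ``clamped``.
    """
    if correct:
        if state.run_count == 2:
            raw = state.level * DOWN_FACTOR
            stepped = "down"
        else:
            return (
                replace(state, run_count=state.run_count + 1, trial_index=state.trial_index + 1),
                "none",
                False,
            )
    else:
        raw = state.level * UP_FACTOR
        stepped = "up"
    new_level = min(max(raw, level_min), level_max)
    clamped = new_level != raw
    return (
        StaircaseState(
            level=new_level,
            run_count=0,
            last_step_direction=stepped,
            trial_index=state.trial_index + 1,
        ),
        stepped,
        clamped,
    )


def detect_reversal(previous_step_direction: str, current_step_direction: str) -> bool:
    """True iff the current step reverses the most recent earlier step.

    The first step of a track (no prior step) is never a reversal.
    """
    if current_step_direction not in ("down", "up"):
        raise ValueError("detect_reversal requires a current step")
    return previous_step_direction in ("down", "up") and (
        current_step_direction != previous_step_direction
    )


def estimate_threshold(reversal_levels) -> float:
    """Mean of the late reversals: drop the first 4 (even total) or 5 (odd).

    Requires at least 6 reversals so that at least two are retained;
    the retained count is always even.
    """
    levels = list(reversal_levels)
    k = len(levels)
    if k < 6:
        raise InsufficientReversalsError(
            f"need >= 6 reversals for a threshold estimate, got {k}"
        )
    drop = 4 if k % 2 == 0 else 5
    return float(np.mean(levels[drop:]))


def run_block(
    obs: ObserverModel,
    block_index: int,
    start_level: float,
    n_trials: int,
    rng: np.random.Generator,
    threshold: float | None = None,
    level_min: float = 1e-3,
    level_max: float = 1e3,
) -> BlockResult:
    """Run one staircase block against a simulated observer.

    ``threshold`` overrides the observer's noiseless learning-curve
    threshold for the block (used to inject day-to-day variability).
    A block with fewer than 6 reversals is returned flagged invalid
    with no estimate.
    """
    if start_level <= 0:
        raise ValueError(f"start_level must be > 0, got {start_level}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    thr = true_threshold(obs, block_index) if threshold is None else threshold

    state = StaircaseState(level=min(max(start_level, level_min), level_max))
    records: list[TrialRecord] = []
    reversal_levels: list[float] = []
    n_correct = 0
    for t in range(n_trials):
        prev_dir = state.last_step_direction
        level = state.level
        correct = respond(obs, level, block_index, rng, threshold=thr)
        n_correct += correct
        state, stepped, clamped = update(state, correct, level_min, level_max)
        is_rev = stepped != "none" and detect_reversal(prev_dir, stepped)
        if is_rev:
            reversal_levels.append(level)
        records.append(
            TrialRecord(
                trial_index=t,
                level=level,
                correct=correct,
                stepped=stepped,
                is_reversal=is_rev,
                clamped=clamped,
            )
        )
    try:
        estimate = estimate_threshold(reversal_levels)
        valid = True
    except InsufficientReversalsError:
        estimate = None
        valid = False
    return BlockResult(
        block_index=block_index,
        threshold_estimate=estimate,
        n_trials=n_trials,
        n_reversals=len(reversal_levels),
        accuracy=n_correct / n_trials,
        trials=tuple(records),
        valid=valid,
    )


def run_protocol(
    obs: ObserverModel,
    protocol: ProtocolConfig | None = None,
    rng: np.random.Generator | None = None,
) -> BlockSeries:
    """Simulate the full training protocol for one observer.

    Block 1 starts at the configured level (default 1.5x the true
    block-1 threshold, mirroring a start "close to the anticipated
    threshold"); each later block starts at the most recent valid
    threshold estimate.  Per-block effective thresholds are the
    learning-curve value times mean-one lognormal noise with log-SD
    ``block_jitter_sd``, modelling day-to-day threshold variability.
    Invalid blocks propagate as flagged gaps, never as a crash.
    """
    if protocol is None:
        protocol = ProtocolConfig()
    if rng is None:
        rng = np.random.default_rng(0)

    s = protocol.block_jitter_sd
    start = protocol.start_level
    if start is None:
        start = protocol.start_level_factor * true_threshold(obs, 1)

    blocks: list[BlockResult] = []
    for n in range(1, protocol.n_blocks + 1):
        thr = true_threshold(obs, n)
        if s > 0:
            thr *= math.exp(s * rng.standard_normal() - 0.5 * s * s)
        block = run_block(
            obs,
            n,
            start_level=start,
            n_trials=protocol.trials_per_block,
            rng=rng,
            threshold=thr,
            level_min=protocol.level_min,
            level_max=protocol.level_max,
        )
        blocks.append(block)
        if block.valid:
            start = block.threshold_estimate
    return BlockSeries(subject_id=obs.subject_id, blocks=tuple(blocks))


def convergence_point() -> float:
    """Accuracy targeted by a 3-down/1-up staircase: the root of p**3 = 1/2."""
    return 0.5 ** (1.0 / 3.0)


def equilibrium_accuracy(down: float = DOWN_FACTOR, up: float = UP_FACTOR) -> float:
    """Drift-balance accuracy of the multiplicative 3-down/1-up track.

    Down steps fire at per-trial rate p^3/(1+p+p^2), up steps at rate
    1-p; the stationary level drifts nowhere when the log-step sizes
    balance: p^3/(1+p+p^2) * |ln down| = (1-p) * ln up.  With equal
    step sizes this reduces to the classic p^3 = 1/2.
    """
    from scipy.optimize import brentq

    dlog, ulog = -math.log(down), math.log(up)
    return float(
        brentq(lambda p: p**3 / (1 + p + p * p) * dlog - (1 - p) * ulog, 0.5, 1 - 1e-9)
    )
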