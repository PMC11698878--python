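"""Staircase engine: update rule, reversal bookkeeping, threshold
estimation, block/protocol simulation and convergence analytics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from staircurve import (
    InsufficientReversalsError,
    ProtocolConfig,
    StaircaseState,
    convergence_point,
    detect_reversal,
    equilibrium_accuracy,
    estimate_threshold,
    run_block,
    run_protocol,
    update,
)


def _replay(start_level, corrects, lmin=1e-3, lmax=1e3):
    """Brute-force re-simulation of the 3-down/1-up rule, independent of update()."""
    lvl, run = start_level, 0
    levels, dirs, revs = [], [], []
    last = None
    for c in corrects:
        levels.append(lvl)
        if not c:
            lvl = min(max(lvl * 1.1, lmin), lmax)
            d = "up"
            run = 0
        elif run == 2:
            lvl = min(max(lvl * 0.9, lmin), lmax)
            d = "down"
            run = 0
        else:
            d = "none"
            run += 1
        dirs.append(d)
        if d == "none":
            revs.append(False)
        else:
            revs.append(last is not None and d != last)
            last = d
    return levels, dirs, revs


class TestUpdate:
    @pytest.mark.parametrize(
        "level,run_count,correct,exp_level,exp_step,exp_run",
        [
            (100.0, 2, True, 90.0, "down", 0),   # third consecutive correct
            (90.0, 0, False, 99.0, "up", 0),     # each error raises by 10%
            (100.0, 0, True, 100.0, "none", 1),  # rule only fires on the 3rd
            (100.0, 1, True, 100.0, "none", 2),
            (100.0, 2, False, 110.0, "up", 0),
        ],
    )
    def test_rule(self, level, run_count, correct, exp_level, exp_step, exp_run):
        state = StaircaseState(level=level, run_count=run_count)
        new, stepped, clamped = update(state, correct)
        assert new.level == pytest.approx(exp_level)
        assert stepped == exp_step
        assert new.run_count == exp_run
        assert not clamped
        assert new.trial_index == state.trial_index + 1

    def test_run_counter_resets_after_every_step_and_error(self):
        state = StaircaseState(level=10.0, run_count=2)
        down, _, _ = update(state, True)
        up, _, _ = update(state, False)
        assert down.run_count == up.run_count == 0

    def test_clamp_flags_absorbed_step_but_keeps_direction(self):
        state = StaircaseState(level=1e-3, run_count=2)
        new, stepped, clamped = update(state, True, level_min=1e-3)
        assert stepped == "down" and clamped and new.level == 1e-3
        assert new.last_step_direction == "down"

    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    @settings(derandomize=True, max_examples=50)
    def test_step_ratio_law(self, corrects):
        """Consecutive level ratios are exactly 0.9, 1.0 or 1.1 away from clamps."""
        state = StaircaseState(level=50.0)
        levels = [state.level]
        for c in corrects:
            state, _, _ = update(state, c, level_min=1e-12, level_max=1e12)
            levels.append(state.level)
        ratios = np.array(levels[1:]) / np.array(levels[:-1])
        for r in ratios:
            assert min(abs(r - 0.9), abs(r - 1.0), abs(r - 1.1)) < 1e-12
        assert all(lv > 0 for lv in levels)


class TestReversals:
    @pytest.mark.parametrize(
        "prev,curr,expected",
        [
            ("down", "up", True),
            ("up", "down", True),
            ("down", "down", False),
            ("up", "up", False),
            ("none", "down", False),  # first-ever step is not a reversal
            ("none", "up", False),
        ],
    )
    def test_detect(self, prev, curr, expected):
        assert detect_reversal(prev, curr) is expected

    def test_requires_a_current_step(self):
        with pytest.raises(ValueError):
            detect_reversal("down", "none")


class TestEstimateThreshold:
    @pytest.mark.parametrize(
        "levels,expected",
        [
            ([5, 5, 5, 5, 5, 5], 5.0),            # 6 (even): mean of last 2
            ([1, 2, 3, 4, 5, 6, 7], 6.5),          # 7 (odd): drop 5, mean of [6, 7]
            ([10, 12, 10, 12, 10, 12, 10, 12], 11.0),  # 8 (even): mean of last 4
        ],
    )
    def test_omission_rule(self, levels, expected):
        assert estimate_threshold(levels) == pytest.approx(expected)

    @pytest.mark.parametrize("k", [0, 3, 5])
    def test_too_few_reversals_rejected(self, k):
        with pytest.raises(InsufficientReversalsError):
            estimate_threshold([4.0] * k)

    @given(st.lists(st.floats(0.5, 50.0), min_size=6, max_size=40))
    @settings(derandomize=True, max_examples=100)
    def test_estimate_within_retained_range_and_even_count(self, levels):
        drop = 4 if len(levels) % 2 == 0 else 5
        retained = levels[drop:]
        assert len(retained) % 2 == 0
        est = estimate_threshold(levels)
        assert min(retained) - 1e-12 <= est <= max(retained) + 1e-12


class TestRunBlock:
    def test_always_correct_forced_sequence(self):
        """A perfect responder steps down every 3rd trial with no reversals."""
        state = StaircaseState(level=100.0)
        post_levels = []
        for _ in range(6):
            state, stepped, _ = update(state, True)
            post_levels.append(state.level)
        assert post_levels == pytest.approx([100.0, 100.0, 90.0, 90.0, 90.0, 81.0])
        assert state.last_step_direction == "down"

    def test_trial_log_replays_bit_exactly(self, observer, rng):
        block = run_block(observer, 1, start_level=12.0, n_trials=70, rng=rng)
        corrects = [t.correct for t in block.trials]
        levels, dirs, revs = _replay(12.0, corrects)
        assert levels == [t.level for t in block.trials]
        assert dirs == [t.stepped for t in block.trials]
        assert revs == [t.is_reversal for t in block.trials]

    def test_accuracy_and_reversal_counts_consistent(self, observer, rng):
        block = run_block(observer, 1, start_level=12.0, n_trials=70, rng=rng)
        assert block.accuracy == sum(t.correct for t in block.trials) / 70
        assert block.n_reversals == sum(t.is_reversal for t in block.trials)
        if block.valid:
            levels = block.reversal_levels
            drop = 4 if len(levels) % 2 == 0 else 5
            retained = levels[drop:]
            assert min(retained) <= block.threshold_estimate <= max(retained)

    def test_short_block_flagged_invalid(self, observer, rng):
        block = run_block(observer, 1, start_level=12.0, n_trials=3, rng=rng)
        assert not block.valid and block.threshold_estimate is None

    def test_bad_inputs_rejected(self, observer, rng):
        with pytest.raises(ValueError):
            run_block(observer, 1, start_level=-1.0, n_trials=70, rng=rng)

    def test_stationary_accuracy_matches_drift_balance(self, stationary_observer):
        """Long-run accuracy sits at the multiplicative-rule equilibrium.

        The 0.9/1.1 steps are asymmetric on the log scale, so the track
        equilibrates where p^3/(1+p+p^2)*|ln 0.9| = (1-p)*ln 1.1, a
        little below the classic equal-step point 2^(-1/3).
        """
        rng = np.random.default_rng(99)
        n = 40000
        block = run_block(stationary_observer, 1, start_level=5.0, n_trials=n, rng=rng)
        p_eq = equilibrium_accuracy()
        mc_se = np.sqrt(p_eq * (1 - p_eq) / n)
        assert block.accuracy == pytest.approx(p_eq, abs=4 * mc_se)


class TestRunProtocol:
    def test_default_protocol_shape(self, observer):
        series = run_protocol(observer, rng=np.random.default_rng(3))
        assert len(series.blocks) == 20
        assert [b.block_index for b in series.blocks] == list(range(1, 21))

    def test_seeded_determinism(self, observer):
        a = run_protocol(observer, rng=np.random.default_rng(5))
        b = run_protocol(observer, rng=np.random.default_rng(5))
        assert a == b

    def test_thresholds_trend_downward_for_learners(self, observer):
        proto = ProtocolConfig(block_jitter_sd=0.0)
        series = run_protocol(observer, proto, np.random.default_rng(8))
        idx, thr = series.valid_points
        early = thr[idx <= 5].mean()
        late = thr[idx > 15].mean()
        assert late < early

    def test_no_learning_observer_has_flat_trend(self, stationary_observer):
        proto = ProtocolConfig(block_jitter_sd=0.0)
        series = run_protocol(stationary_observer, proto, np.random.default_rng(21))
        idx, thr = series.valid_points
        slope, intercept = np.polyfit(idx, thr, 1)
        resid = thr - (slope * idx + intercept)
        se = resid.std(ddof=2) / (idx.std(ddof=0) * np.sqrt(len(idx)))
        assert abs(slope) < 3 * se

    def test_later_blocks_start_at_previous_estimate(self, observer):
        series = run_protocol(observer, rng=np.random.default_rng(13))
        for prev, nxt in zip(series.blocks[:-1], series.blocks[1:]):
            if prev.valid:
                assert nxt.trials[0].level == pytest.approx(prev.threshold_estimate)


class TestConvergencePoint:
    def test_analytic_root(self):
        p = convergence_point()
        assert p**3 == pytest.approx(0.5, abs=1e-15)
        assert p == pytest.approx(0.79370, abs=5e-6)

    def test_equilibrium_reduces_to_classic_value_for_equal_steps(self):
        assert equilibrium_accuracy(0.9, 1 / 0.9) == pytest.approx(
            convergence_point(), abs=1e-12
        )
        assert equilibrium_accuracy() < convergence_point()
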