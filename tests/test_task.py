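"""Task engine: session design, hazard, trial dynamics, behavioral summary."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aaconflict import task


class TestSessionGeneration:
    def test_design_constants(self, default_config, default_session):
        assert len(default_session) == 240
        assert sum(not s.conflict for s in default_session) == 48
        assert default_config.n_blocks == 12
        assert default_config.block_length == 20

    def test_conflict_free_stratified_per_block(self, default_config, default_session):
        bl = default_config.block_length
        for b in range(default_config.n_blocks):
            block = default_session[b * bl : (b + 1) * bl]
            assert sum(not s.conflict for s in block) == 4

    def test_counterbalancing_within_session(self, default_session):
        conflict = [s for s in default_session if s.conflict]
        cells = {}
        for s in conflict:
            key = (s.pacman_start_side, s.ghost_start_direction, s.dot_sizes)
            cells[key] = cells.get(key, 0) + 1
        counts = set(cells.values())
        assert len(cells) == 16  # side x direction x dot pattern fully crossed
        assert counts == {12}  # each cell once per block

    def test_deterministic_given_seed(self, default_config):
        a = task.generate_session(default_config, seed=3)
        b = task.generate_session(default_config, seed=3)
        assert a == b
        c = task.generate_session(default_config, seed=4)
        assert a != c

    def test_dots_between_avatar_and_patrol(self, default_session):
        for s in default_session:
            assert all(
                s.pacman_start_position < d for d in s.dot_positions
            )
            assert list(s.dot_positions) == sorted(s.dot_positions)
            if s.conflict:
                assert s.dot_positions[-1] < s.patrol_min

    def test_impossible_counterbalance_rejected(self):
        with pytest.raises(task.ConfigurationError):
            task.TaskConfig(n_trials=230)
        with pytest.raises(task.ConfigurationError):
            task.TaskConfig(conflict_free_fraction=0.17)


class TestAttackHazard:
    def test_far_distance_limit(self, default_config):
        p = task.attack_probability(default_config.corridor_length, default_config)
        assert p == pytest.approx(0.0, abs=1e-9)

    def test_matches_scaled_beta_cdf(self, default_config):
        from scipy import stats

        grid = np.linspace(0.0, default_config.corridor_length, 33)
        expected = default_config.hazard_max * stats.beta.cdf(
            1.0 - grid / default_config.corridor_length,
            default_config.hazard_alpha,
            default_config.hazard_beta,
        )
        got = np.array([task.attack_probability(d, default_config) for d in grid])
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        alpha=st.floats(0.5, 10.0),
        beta=st.floats(0.5, 10.0),
        hmax=st.floats(0.001, 1.0),
    )
    def test_monotone_nonincreasing_for_any_shape(self, alpha, beta, hmax):
        cfg = task.TaskConfig(hazard_alpha=alpha, hazard_beta=beta, hazard_max=hmax)
        grid = np.linspace(0.0, cfg.corridor_length, 64)
        vals = [task.attack_probability(d, cfg) for d in grid]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= hmax + 1e-12 for v in vals)

    def test_negative_distance_rejected(self, default_config):
        with pytest.raises(ValueError):
            task.attack_probability(-1.0, default_config)


def _conflict_spec(session):
    return next(s for s in session if s.conflict)


def _conflict_free_spec(session):
    return next(s for s in session if not s.conflict)


class TestTrialDynamics:
    def test_stationary_before_first_press(self, default_config, default_session):
        spec = _conflict_spec(default_session)
        state = task.TrialState.initial(spec, default_config)
        start = state.pac_pos
        task.step(state, "none")
        assert state.pac_pos == start

    def test_strike_always_captures(self, default_config, default_session):
        spec = dataclasses.replace(
            _conflict_spec(default_session), attack_outcome_assignment="strike"
        )
        caught = []
        for seed in range(40):
            log = task.run_trial(
                spec,
                task.ThresholdPolicy(threshold=20.0, large_bonus=0.0),
                default_config,
                seed=seed,
            )
            if log.attack_onset is not None:
                caught.append(log.caught)
        assert len(caught) >= 5
        assert all(caught)

    def test_strike_capture_forfeits_points(self, default_config, default_session):
        spec = dataclasses.replace(
            _conflict_spec(default_session), attack_outcome_assignment="strike"
        )
        for seed in range(40):
            log = task.run_trial(
                spec,
                task.ThresholdPolicy(threshold=20.0, large_bonus=0.0),
                default_config,
                seed=seed,
            )
            if log.caught:
                assert log.points == 0
                assert log.dots_collected >= 0
                return
        pytest.fail("no capture observed")

    def test_chase_escapable_with_immediate_flight(
        self, default_config, default_session
    ):
        # Agent flees the moment the attack begins, from a distance at which
        # the equal-speed chase cannot close the gap before the exit.
        spec = dataclasses.replace(
            _conflict_spec(default_session), attack_outcome_assignment="chase"
        )
        escaped = []
        for seed in range(40):
            log = task.run_trial(
                spec,
                task.ThresholdPolicy(threshold=60.0, large_bonus=0.0),
                default_config,
                seed=seed,
            )
            if log.attack_onset is not None and log.attack_kind == "chase":
                escaped.append(not log.caught)
        assert escaped and all(escaped)

    def test_conflict_free_full_approach_collects_five_dots(
        self, default_config, default_session
    ):
        spec = _conflict_free_spec(default_session)
        log = task.run_trial(spec, task.ThresholdPolicy(), default_config, seed=0)
        assert log.dots_collected == 5
        assert log.points == sum(
            default_config.reward_points(s) for s in spec.dot_sizes
        )

    def test_immediate_exit_collects_nothing(self, default_config, default_session):
        spec = _conflict_spec(default_session)
        log = task.run_trial(spec, task.never_approach, default_config, seed=0)
        assert log.dots_collected == 0
        assert log.points == 0
        assert not log.caught

    def test_frozen_policy_times_out(self, default_config, default_session):
        spec = _conflict_spec(default_session)
        cfg = dataclasses.replace(default_config, max_ticks=50)
        log = task.run_trial(spec, lambda s: "none", cfg, seed=0)
        assert log.timeout
        assert log.movement_onset is None


class TestSession:
    def test_never_approach_gives_twelve_minigames(
        self, default_config, default_session
    ):
        _, summary = task.run_session(
            default_session, task.never_approach, default_config, seed=9
        )
        assert summary.minigame_lengths == [20] * 12
        assert all(l == 3 for l in summary.lives_at_start)

    def test_three_captures_end_a_minigame_early(self, default_config):
        # A greedy agent that parks next to the threat is captured quickly;
        # every minigame must terminate at three captures or a full block.
        specs = task.generate_session(default_config, seed=2)
        logs, summary = task.run_session(
            specs,
            task.ThresholdPolicy(threshold=1.0, large_bonus=0.0),
            default_config,
            seed=3,
        )
        caught_per_game = []
        for start, length in zip(
            summary.minigame_boundaries, summary.minigame_lengths
        ):
            n_caught = sum(lg.caught for lg in logs[start : start + length])
            assert n_caught <= 3
            caught_per_game.append(n_caught)
            if length < default_config.block_length and start + length < len(logs):
                assert n_caught == 3
        assert any(c == 3 for c in caught_per_game)

    def test_chase_fraction_near_half(self, default_config):
        # Pool attacks over several sessions played by a risk-taking agent.
        chase = attacks = 0
        for seed in range(14):
            specs = task.generate_session(default_config, seed=seed)
            _, summary = task.run_session(
                specs,
                task.ThresholdPolicy(threshold=15.0, large_bonus=0.0),
                default_config,
                seed=100 + seed,
            )
            chase += summary.chase_count
            attacks += summary.attack_count
        assert attacks >= 1000
        se = np.sqrt(0.25 / attacks)
        assert abs(chase / attacks - 0.5) < 3 * se


class TestBehaviorSummary:
    def test_reward_sensitivity_direction(self, played_session):
        logs, _ = played_session
        summary = task.summarize_behavior(logs)
        by = summary.turnaround_distance_by_last_dot_size
        # The threshold agent tolerates more risk for a large final reward.
        assert by["large"] < by["small"]
        # Oracle: direct group means over the same logs.
        for size in ("small", "large"):
            vals = [
                lg.turnaround_distance
                for lg in logs
                if lg.conflict
                and lg.turnaround_times
                and lg.last_dot_size == size
                and lg.turnaround_distance is not None
            ]
            assert by[size] == pytest.approx(np.mean(vals))

    def test_single_trial_mean_equals_its_distance(
        self, default_config, default_session
    ):
        spec = _conflict_spec(default_session)
        log = task.run_trial(spec, task.ThresholdPolicy(), default_config, seed=1)
        assert log.turnaround_distance is not None
        summary = task.summarize_behavior([log])
        assert summary.mean_turnaround_distance == pytest.approx(
            log.turnaround_distance
        )

    def test_conflict_free_and_no_turn_trials_excluded(self, played_session):
        logs, _ = played_session
        summary = task.summarize_behavior(logs)
        eligible = [
            lg for lg in logs if lg.conflict and lg.turnaround_times
        ]
        assert summary.n_turnaround_trials == len(eligible)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            task.summarize_behavior([])


class TestTabularExport:
    def test_tidy_frames_roundtrip_csv(self, played_session, tmp_path):
        logs, _ = played_session
        events, trials = task.logs_to_frames(logs)
        assert set(events.columns) == {"trial_id", "time_ms", "event", "value"}
        assert len(trials) == len(logs)
        assert (events["event"] == "trial_end").sum() == len(logs)
        events.to_csv(tmp_path / "events.csv", index=False)
        trials.to_csv(tmp_path / "trials.csv", index=False)
        back = __import__("pandas").read_csv(tmp_path / "trials.csv")
        assert back["dots_collected"].tolist() == trials["dots_collected"].tolist()

    def test_config_from_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_trials: 40\nblock_length: 20\nhazard_max: 0.01\n")
        cfg = task.TaskConfig.from_yaml(path)
        assert cfg.n_trials == 40
        assert cfg.hazard_max == 0.01
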