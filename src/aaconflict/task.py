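"""Continuous-choice approach-avoidance task simulator.

A player-controlled avatar ("Pac-Man") and a patrolling threat ("ghost")
share a single corridor.  Approaching the threat collects rewards (dots,
small = 10 or large = 20 points) but raises the per-tick probability of a
ghost attack, which grows with proximity.  An attack is either an escapable
*Chase* (threat keeps its speed) or an inescapable *Strike* (threat speed is
boosted until capture is guaranteed).  Sessions are organised into
minigames: a minigame ends when three lives are lost or a block of trials
completes, and score/lives reset at each minigame boundary.

The simulator runs in discrete ticks (default 50 ms) in canonical
coordinates: position 0 is the avatar's exit, the corridor extends to
``corridor_length``, and the threat patrols near the far end.  Trials whose
spec says ``pacman_start_side == "right"`` are mirrored screens of the same
geometry; positions are logged in canonical coordinates and the side kept
as metadata.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "TaskConfig",
    "TrialSpec",
    "GhostState",
    "TrialLog",
    "BehaviorSummary",
    "SessionSummary",
    "generate_session",
    "attack_probability",
    "TrialState",
    "step",
    "run_trial",
    "run_session",
    "summarize_behavior",
    "ThresholdPolicy",
    "always_approach",
    "never_approach",
]


class ConfigurationError(ValueError):
    """Raised when a task configuration cannot be counterbalanced."""


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the approach-avoidance task.

    Defaults reproduce the published design: 240 trials in blocks of 20,
    20% conflict-free, 5 dots worth 10/20 points, 3 lives per minigame.
    Speeds are in corridor units per tick; only the relative speed of the
    threat matters for chase/strike logic.
    """

    n_trials: int = 240
    block_length: int = 20
    conflict_free_fraction: float = 0.20
    n_dots: int = 5
    reward_small: int = 10
    reward_large: int = 20
    n_lives: int = 3
    corridor_length: float = 200.0
    pacman_start: float = 10.0
    pacman_speed: float = 2.0
    ghost_pace_speed: float = 2.0
    strike_speed_multiplier: float = 2.5
    hazard_alpha: float = 6.0
    hazard_beta: float = 2.0
    hazard_max: float = 0.015
    tick_ms: float = 50.0
    dot_jitter: float = 5.0
    patrol_buffer: float = 20.0
    patrol_buffer_jitter: float = 5.0
    max_ticks: int = 1200

    def __post_init__(self) -> None:
        if self.n_trials % self.block_length != 0:
            raise ConfigurationError("n_trials must be divisible by block_length")
        cf = self.conflict_free_fraction * self.block_length
        if abs(cf - round(cf)) > 1e-9:
            raise ConfigurationError(
                "conflict_free_fraction x block_length must be an integer"
            )
        if not (0.0 < self.hazard_max <= 1.0):
            raise ConfigurationError("hazard_max must lie in (0, 1]")
        if self.strike_speed_multiplier <= 1.0:
            raise ConfigurationError("strike_speed_multiplier must exceed 1")
        if self.reward_small >= self.reward_large:
            raise ConfigurationError("small reward must be worth less than large")

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_length

    @property
    def conflict_free_per_block(self) -> int:
        return round(self.conflict_free_fraction * self.block_length)

    def reward_points(self, size: str) -> int:
        return self.reward_large if size == "large" else self.reward_small

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as f:
            return cls(**(yaml.safe_load(f) or {}))


# Four fixed dot-size patterns; two end on a large dot, two on a small dot,
# and sizes are balanced overall.  Crossed with side x ghost direction this
# gives the 16 conflict cells of a 20-trial block.
_DOT_PATTERNS: tuple[tuple[str, ...], ...] = (
    ("small", "large", "small", "large", "large"),
    ("large", "small", "large", "small", "large"),
    ("large", "large", "small", "large", "small"),
    ("small", "small", "large", "small", "small"),
)


@dataclass(frozen=True)
class TrialSpec:
    trial_id: int
    conflict: bool
    pacman_start_side: str  # {"left", "right"}
    pacman_start_position: float
    ghost_start_position: Optional[float]
    ghost_start_direction: Optional[str]  # {"toward", "away"}
    dot_positions: tuple[float, ...]
    dot_sizes: tuple[str, ...]
    attack_outcome_assignment: str  # {"chase", "strike"}, pre-drawn
    patrol_min: Optional[float] = None
    patrol_max: Optional[float] = None


class GhostState(enum.Enum):
    PACE = "pace"
    CHASE = "chase"
    STRIKE = "strike"


@dataclass
class TrialLog:
    """Tick-indexed record of one simulated trial."""

    trial_id: int
    conflict: bool
    pacman_positions: np.ndarray
    ghost_positions: np.ndarray  # NaN when the ghost is absent
    tick_ms: float
    movement_onset: Optional[float]  # ms
    turnaround_times: list[float] = field(default_factory=list)  # ms
    attack_onset: Optional[float] = None  # ms
    attack_kind: Optional[str] = None
    trial_end: float = 0.0  # ms
    dots_collected: int = 0
    points: int = 0
    caught: bool = False
    timeout: bool = False
    last_dot_size: str = "none"
    turnaround_distance: Optional[float] = None

    @property
    def final_turnaround(self) -> Optional[float]:
        """Final turn = the decision to avoid."""
        return self.turnaround_times[-1] if self.turnaround_times else None

    @property
    def approach_duration_ms(self) -> Optional[float]:
        if self.movement_onset is None or self.final_turnaround is None:
            return None
        return self.final_turnaround - self.movement_onset


@dataclass
class BehaviorSummary:
    mean_dots_per_trial: float
    mean_turnaround_distance: float
    turnaround_distance_by_last_dot_size: dict[str, float]
    attack_count: int
    chase_fraction: float
    n_trials: int
    n_turnaround_trials: int


@dataclass
class SessionSummary:
    minigame_boundaries: list[int]  # start index of each minigame
    minigame_lengths: list[int]
    minigame_scores: list[int]
    lives_at_start: list[int]
    attack_count: int
    chase_count: int
    strike_count: int


def attack_probability(distance: float, config: TaskConfig) -> float:
    """Per-tick attack hazard as a function of avatar-threat distance.

    The hazard is ``hazard_max * BetaCDF(1 - d/L; alpha, beta)``: a beta
    distribution over proximity, so attacks are rare when far apart and
    common at close range, monotone non-increasing in distance by
    construction of the CDF.
    """
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise ValueError("distance must be non-negative")
    proximity = np.clip(1.0 - distance / config.corridor_length, 0.0, 1.0)
    p = config.hazard_max * stats.beta.cdf(
        proximity, config.hazard_alpha, config.hazard_beta
    )
    return float(p) if np.isscalar(distance) or distance.ndim == 0 else p


def _block_cells(config: TaskConfig) -> tuple[list[dict], list[dict]]:
    """Factorial cells for one block: (conflict cells, conflict-free cells)."""
    n_cf = config.conflict_free_per_block
    n_conflict = config.block_length - n_cf
    sides = ("left", "right")
    directions = ("toward", "away")
    conflict_cells = [
        {"side": s, "direction": d, "pattern": p}
        for s in sides
        for d in directions
        for p in range(len(_DOT_PATTERNS))
    ]
    if n_conflict % len(conflict_cells) != 0:
        raise ConfigurationError(
            f"{n_conflict} conflict trials per block cannot balance "
            f"{len(conflict_cells)} factorial cells"
        )
    conflict_cells = conflict_cells * (n_conflict // len(conflict_cells))
    # Conflict-free cells: side x (last dot large / small); ghost absent.
    cf_base = [
        {"side": s, "direction": None, "pattern": p}
        for s in sides
        for p in (0, 3)  # patterns ending large / small
    ]
    if n_cf % len(cf_base) != 0:
        raise ConfigurationError(
            f"{n_cf} conflict-free trials per block cannot balance "
            f"{len(cf_base)} cells"
        )
    cf_cells = cf_base * (n_cf // len(cf_base))
    return conflict_cells, cf_cells


def generate_session(config: TaskConfig, seed: int) -> list[TrialSpec]:
    """Generate a counterbalanced session of trial specifications.

    Within every block, pacman side x ghost starting direction x dot-size
    pattern are fully crossed for the conflict trials, and the configured
    fraction of conflict-free trials is stratified into each block.  Dot
    positions are evenly spaced with seeded jitter; the threat's patrol zone
    starts a jittered buffer beyond the last dot.  Chase/strike assignments
    form a balanced, shuffled sequence across the session.  The result is a
    pure function of ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    conflict_cells, cf_cells = _block_cells(config)

    # Balanced chase/strike sequence across the whole session.
    n_half = (config.n_trials + 1) // 2
    outcomes = np.array(["chase", "strike"] * n_half)[: config.n_trials]
    rng.shuffle(outcomes)

    specs: list[TrialSpec] = []
    trial_id = 0
    for _ in range(config.n_blocks):
        cells = [dict(c, conflict=True) for c in conflict_cells] + [
            dict(c, conflict=False) for c in cf_cells
        ]
        order = rng.permutation(len(cells))
        for idx in order:
            cell = cells[idx]
            pattern = _DOT_PATTERNS[cell["pattern"]]
            lo = config.pacman_start + 30.0
            hi = config.corridor_length * 0.70
            base = np.linspace(lo, hi, config.n_dots)
            jitter = rng.uniform(-config.dot_jitter, config.dot_jitter, config.n_dots)
            dots = np.sort(base + jitter)
            sizes = tuple(pattern[i % len(pattern)] for i in range(config.n_dots))
            if cell["conflict"]:
                buffer = config.patrol_buffer + rng.uniform(
                    -config.patrol_buffer_jitter, config.patrol_buffer_jitter
                )
                patrol_min = float(dots[-1] + buffer)
                patrol_max = config.corridor_length - 10.0
                ghost_pos = float(rng.uniform(patrol_min, patrol_max))
                ghost_dir = cell["direction"]
            else:
                patrol_min = patrol_max = None
                ghost_pos = None
                ghost_dir = None
            specs.append(
                TrialSpec(
                    trial_id=trial_id,
                    conflict=cell["conflict"],
                    pacman_start_side=cell["side"],
                    pacman_start_position=config.pacman_start,
                    ghost_start_position=ghost_pos,
                    ghost_start_direction=ghost_dir,
                    dot_positions=tuple(float(d) for d in dots),
                    dot_sizes=sizes,
                    attack_outcome_assignment=str(outcomes[trial_id]),
                    patrol_min=patrol_min,
                    patrol_max=patrol_max,
                )
            )
            trial_id += 1
    return specs


@dataclass
class TrialState:
    """Mutable state of a trial in progress (canonical coordinates)."""

    spec: TrialSpec
    config: TaskConfig
    tick: int = 0
    pac_pos: float = 0.0
    pac_dir: int = 0  # +1 toward threat, -1 toward exit, 0 stationary
    ghost_pos: float = float("nan")
    ghost_dir: int = 0  # patrol direction: +1 away from avatar
    ghost_state: GhostState = GhostState.PACE
    dots_remaining: list[tuple[float, str]] = field(default_factory=list)
    dots_collected: int = 0
    points: int = 0
    ended: bool = False
    caught: bool = False
    exited: bool = False

    @classmethod
    def initial(cls, spec: TrialSpec, config: TaskConfig) -> "TrialState":
        state = cls(spec=spec, config=config)
        state.pac_pos = spec.pacman_start_position
        state.dots_remaining = list(zip(spec.dot_positions, spec.dot_sizes))
        if spec.conflict:
            state.ghost_pos = float(spec.ghost_start_position)
            state.ghost_dir = 1 if spec.ghost_start_direction == "away" else -1
        return state

    @property
    def distance(self) -> float:
        return abs(self.ghost_pos - self.pac_pos)


def step(
    state: TrialState,
    action: str,
    rng: Optional[np.random.Generator] = None,
    attack_outcome: Optional[str] = None,
) -> TrialState:
    """Advance the trial by one game tick (mutates and returns ``state``).

    ``action`` is {"toward", "away", "none"}: the avatar keeps moving at
    constant speed in the last commanded direction.  While the threat is
    pacing, an attack triggers with probability ``attack_probability`` at
    the current distance; a chase keeps the patrol speed, a strike boosts it
    so capture is guaranteed even under immediate flight.
    """
    if state.ended:
        raise RuntimeError("trial already ended")
    cfg = state.config
    if action == "toward":
        state.pac_dir = 1
    elif action == "away":
        state.pac_dir = -1
    elif action != "none":
        raise ValueError(f"unknown action {action!r}")

    state.pac_pos += state.pac_dir * cfg.pacman_speed
    state.pac_pos = min(state.pac_pos, cfg.corridor_length)

    # Collect any dots the avatar has reached or passed while approaching.
    if state.pac_dir > 0:
        remaining = []
        for pos, size in state.dots_remaining:
            if state.pac_pos >= pos:
                state.dots_collected += 1
                state.points += cfg.reward_points(size)
            else:
                remaining.append((pos, size))
        state.dots_remaining = remaining

    if state.spec.conflict:
        _step_ghost(state, rng, attack_outcome)

    if state.spec.conflict and state.ghost_pos <= state.pac_pos:
        state.caught = True
        state.points = 0  # capture forfeits the trial's points
        state.ended = True
    elif state.pac_pos <= 0.0 and state.pac_dir < 0:
        state.exited = True
        state.ended = True

    state.tick += 1
    return state


def _step_ghost(
    state: TrialState,
    rng: Optional[np.random.Generator],
    attack_outcome: Optional[str],
) -> None:
    cfg = state.config
    spec = state.spec
    if state.ghost_state is GhostState.PACE:
        state.ghost_pos += state.ghost_dir * cfg.ghost_pace_speed
        if state.ghost_pos >= spec.patrol_max:
            state.ghost_pos = spec.patrol_max
            state.ghost_dir = -1
        elif state.ghost_pos <= spec.patrol_min:
            state.ghost_pos = spec.patrol_min
            state.ghost_dir = 1
        if rng is not None:
            p = attack_probability(state.distance, cfg)
            if rng.random() < p:
                kind = attack_outcome or spec.attack_outcome_assignment
                state.ghost_state = (
                    GhostState.STRIKE if kind == "strike" else GhostState.CHASE
                )
    else:
        speed = cfg.ghost_pace_speed
        if state.ghost_state is GhostState.STRIKE:
            speed *= cfg.strike_speed_multiplier
            # Capture guarantee: if current geometry would allow escape,
            # raise the strike speed for this trial.
            gap = max(state.ghost_pos - state.pac_pos, 0.0)
            flight_ticks = state.pac_pos / cfg.pacman_speed
            if flight_ticks > 0:
                needed = cfg.pacman_speed + gap / flight_ticks
                speed = max(speed, needed * 1.05)
        state.ghost_pos -= speed  # attack: move toward the avatar (exit side)


def run_trial(
    spec: TrialSpec,
    policy: Callable[[TrialState], str],
    config: TaskConfig,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    attack_outcome: Optional[str] = None,
) -> TrialLog:
    """Run one trial under ``policy`` and return its event log.

    The policy maps the observable trial state to an action.  Trials that
    never end (a policy that never moves) are terminated at
    ``config.max_ticks`` and logged as timeouts.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    state = TrialState.initial(spec, config)
    pac_track = [state.pac_pos]
    ghost_track = [state.ghost_pos]
    movement_onset: Optional[float] = None
    turnarounds: list[float] = []
    turnaround_dist: Optional[float] = None
    attack_onset: Optional[float] = None
    attack_kind: Optional[str] = None
    prev_dir = 0

    while not state.ended and state.tick < config.max_ticks:
        action = policy(state)
        was_pacing = state.ghost_state is GhostState.PACE
        step(state, action, rng=rng, attack_outcome=attack_outcome)
        t_ms = state.tick * config.tick_ms
        if movement_onset is None and state.pac_dir != 0:
            movement_onset = t_ms
        if prev_dir > 0 and state.pac_dir < 0:
            turnarounds.append(t_ms)
            if spec.conflict:
                turnaround_dist = state.distance
        prev_dir = state.pac_dir if state.pac_dir != 0 else prev_dir
        if was_pacing and state.ghost_state is not GhostState.PACE:
            attack_onset = t_ms
            attack_kind = state.ghost_state.value
        pac_track.append(state.pac_pos)
        ghost_track.append(state.ghost_pos)

    timeout = not state.ended
    return TrialLog(
        trial_id=spec.trial_id,
        conflict=spec.conflict,
        pacman_positions=np.asarray(pac_track),
        ghost_positions=np.asarray(ghost_track),
        tick_ms=config.tick_ms,
        movement_onset=movement_onset,
        turnaround_times=turnarounds,
        attack_onset=attack_onset,
        attack_kind=attack_kind,
        trial_end=state.tick * config.tick_ms,
        dots_collected=state.dots_collected,
        points=state.points,
        caught=state.caught,
        timeout=timeout,
        last_dot_size=spec.dot_sizes[-1] if spec.dot_sizes else "none",
        turnaround_distance=turnaround_dist,
    )


def run_session(
    specs: Sequence[TrialSpec],
    policy: Callable[[TrialState], str],
    config: TaskConfig,
    seed: int,
) -> tuple[list[TrialLog], SessionSummary]:
    """Run a full session with minigame bookkeeping.

    A minigame ends when three captures occur or a block of trials
    completes; lives and score reset at each minigame boundary.  A balanced
    chase/strike sequence is consumed in attack-trigger order so the
    realized split stays near 50% regardless of when attacks fire.
    """
    rng = np.random.default_rng(seed)
    n_half = (len(specs) + 1) // 2
    outcome_queue = list(np.array(["chase", "strike"] * n_half)[: len(specs)])
    rng.shuffle(outcome_queue)
    queue_idx = 0

    logs: list[TrialLog] = []
    boundaries = [0]
    lengths: list[int] = []
    scores: list[int] = []
    lives_at_start: list[int] = []
    lives = config.n_lives
    lives_at_start.append(lives)
    score = 0
    game_len = 0
    attack_count = chase_count = strike_count = 0

    for i, spec in enumerate(specs):
        next_outcome = outcome_queue[min(queue_idx, len(outcome_queue) - 1)]
        log = run_trial(spec, policy, config, rng=rng, attack_outcome=next_outcome)
        logs.append(log)
        game_len += 1
        score += log.points
        if log.attack_onset is not None:
            queue_idx += 1
            attack_count += 1
            if log.attack_kind == "chase":
                chase_count += 1
            else:
                strike_count += 1
        if log.caught:
            lives -= 1
        minigame_over = lives <= 0 or game_len >= config.block_length
        if minigame_over and i < len(specs) - 1:
            lengths.append(game_len)
            scores.append(score)
            boundaries.append(i + 1)
            lives = config.n_lives
            lives_at_start.append(lives)
            score = 0
            game_len = 0
    lengths.append(game_len)
    scores.append(score)

    summary = SessionSummary(
        minigame_boundaries=boundaries,
        minigame_lengths=lengths,
        minigame_scores=scores,
        lives_at_start=lives_at_start,
        attack_count=attack_count,
        chase_count=chase_count,
        strike_count=strike_count,
    )
    return logs, summary


def summarize_behavior(logs: Sequence[TrialLog]) -> BehaviorSummary:
    """Behavioral summary over a set of trial logs.

    Turnaround statistics use only conflict trials with at least one turn,
    mirroring the exclusion rules of the behavioral analysis (conflict-free
    trials and trials without a turn are dropped).
    """
    logs = list(logs)
    if not logs:
        raise ValueError("no trial logs supplied")
    eligible = [
        lg
        for lg in logs
        if lg.conflict and lg.turnaround_times and lg.turnaround_distance is not None
    ]
    if not eligible:
        raise ValueError("no conflict trial with a turnaround")
    dists = np.array([lg.turnaround_distance for lg in eligible])
    by_size: dict[str, float] = {}
    for size in ("small", "large"):
        vals = [
            lg.turnaround_distance for lg in eligible if lg.last_dot_size == size
        ]
        if vals:
            by_size[size] = float(np.mean(vals))
    attacks = [lg for lg in logs if lg.attack_onset is not None]
    chase = sum(1 for lg in attacks if lg.attack_kind == "chase")
    return BehaviorSummary(
        mean_dots_per_trial=float(np.mean([lg.dots_collected for lg in logs])),
        mean_turnaround_distance=float(dists.mean()),
        turnaround_distance_by_last_dot_size=by_size,
        attack_count=len(attacks),
        chase_fraction=chase / len(attacks) if attacks else float("nan"),
        n_trials=len(logs),
        n_turnaround_trials=len(eligible),
    )


def logs_to_frames(
    logs: Sequence[TrialLog],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy tables from trial logs: (events, per-trial summary).

    ``events`` has one row per event (trial_id, time_ms, event, value);
    ``trials`` one row per trial with outcome fields — ready for CSV export
    or the stats module.
    """
    ev_rows, tr_rows = [], []
    for lg in logs:
        if lg.movement_onset is not None:
            ev_rows.append((lg.trial_id, lg.movement_onset, "movement_onset", ""))
        for t in lg.turnaround_times:
            ev_rows.append((lg.trial_id, t, "turnaround", ""))
        if lg.attack_onset is not None:
            ev_rows.append((lg.trial_id, lg.attack_onset, "attack_onset", lg.attack_kind))
        ev_rows.append((lg.trial_id, lg.trial_end, "trial_end", ""))
        tr_rows.append(
            dict(
                trial_id=lg.trial_id,
                conflict=lg.conflict,
                dots_collected=lg.dots_collected,
                points=lg.points,
                caught=lg.caught,
                timeout=lg.timeout,
                turned=bool(lg.turnaround_times),
                last_dot_size=lg.last_dot_size,
                turnaround_distance=lg.turnaround_distance,
                approach_duration_ms=lg.approach_duration_ms,
                attack_kind=lg.attack_kind,
            )
        )
    events = pd.DataFrame(ev_rows, columns=["trial_id", "time_ms", "event", "value"])
    return events, pd.DataFrame(tr_rows)


# ---------------------------------------------------------------------------
# Agent policies


@dataclass
class ThresholdPolicy:
    """Approach until the threat is within a distance threshold, then flee.

    ``large_bonus`` shrinks the threshold when the last dot in the corridor
    is large, emulating the reward-sensitive risk trade-off.  The agent
    flees immediately when an attack starts, and on conflict-free trials
    turns back once every dot is collected.
    """

    threshold: float = 40.0
    large_bonus: float = 10.0
    start_delay_ticks: int = 10

    def __call__(self, state: TrialState) -> str:
        if state.tick < self.start_delay_ticks:
            return "none"
        if state.pac_dir < 0:
            return "away"  # the avoidance decision is a commitment
        if not state.spec.conflict:
            return "toward" if state.dots_remaining else "away"
        if state.ghost_state is not GhostState.PACE:
            return "away"
        thr = self.threshold
        if state.spec.dot_sizes and state.spec.dot_sizes[-1] == "large":
            thr -= self.large_bonus
        return "toward" if state.distance > thr else "away"


def always_approach(state: TrialState) -> str:
    return "toward"


def never_approach(state: TrialState) -> str:
    return "away"
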