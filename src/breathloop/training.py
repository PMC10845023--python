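"""Closed-loop adaptive breath-training engine.

The training is a performance-adaptive ("closed-loop") breath-counting
practice.  At level ``L`` the trainee monitors ``L`` breaths per screen tap
during a block lasting ``L`` minutes.  The app scores each block for
consistency of the tap responses; after ``repeats_required`` consecutive
consistent blocks the trainee is promoted one level, up to level 10, where
they remain for the rest of the assigned sessions.  A compassion prompt is
shown before each session and advances every ``prompt_block_size`` sessions
through a fixed curriculum of 10 prompts.

The module provides the deterministic engine (:func:`evaluate_block`,
:func:`update_level`, :func:`prompt_for_session`) and a stochastic simulated
user (:class:`SimulatedUser`, :func:`simulate_participant_course`) that
produces realistic session logs for testing the downstream analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TrainingConfig",
    "TrainingState",
    "BlockLog",
    "SessionLog",
    "SimulatedUser",
    "COMPASSION_PROMPTS",
    "evaluate_block",
    "update_level",
    "prompt_for_session",
    "simulate_block_taps",
    "simulate_participant_course",
]

#: Titles of the 10-step compassion cultivation curriculum, one prompt per
#: block of ``prompt_block_size`` sessions, increasing in complexity.
COMPASSION_PROMPTS = (
    "settling the mind",
    "compassion for a loved one",
    "compassion for oneself",
    "loving kindness for oneself",
    "embracing common humanity",
    "embracing common humanity continued",
    "cultivating compassion for oneself and others",
    "cultivating compassion for others continued",
    "active compassion",
    "integrated compassion cultivation practice",
)


@dataclass(frozen=True)
class TrainingConfig:
    """Parameters of the adaptive training protocol.

    ``max_level`` doubles as breaths-per-tap and minutes-per-block at that
    level.  ``nominal_breath_period_s`` (6 s, i.e. 10 breaths/min) sets the
    expected tap count of a block; ``consistency_cv_threshold`` and
    ``tap_count_tolerance`` define block consistency.
    """

    max_level: int = 10
    repeats_required: int = 3
    total_sessions: int = 60
    prompt_block_size: int = 6
    session_minutes_min: float = 5.0
    session_minutes_max: float = 10.0
    consistency_cv_threshold: float = 0.25
    tap_count_tolerance: int = 1
    nominal_breath_period_s: float = 6.0

    def __post_init__(self) -> None:
        if self.max_level < 1 or self.repeats_required < 1:
            raise ValueError("max_level and repeats_required must be >= 1")
        n_prompts = len(COMPASSION_PROMPTS)
        if self.prompt_block_size * n_prompts != self.total_sessions:
            raise ValueError(
                "prompt_block_size x number of prompts must equal total_sessions "
                f"({self.prompt_block_size} x {n_prompts} != {self.total_sessions})"
            )

    def block_minutes(self, level: int) -> float:
        return float(level)

    def expected_taps(self, level: int) -> int:
        """Expected taps in a block: block seconds / (level breaths x period)."""
        block_s = 60.0 * self.block_minutes(level)
        return int(round(block_s / (level * self.nominal_breath_period_s)))


@dataclass(frozen=True)
class TrainingState:
    """Per-participant engine state; level never decreases."""

    level: int = 1
    consecutive_consistent: int = 0
    session_index: int = 1
    cumulative_minutes: float = 0.0


@dataclass(frozen=True)
class BlockLog:
    level: int
    tap_times: tuple[float, ...]
    expected_taps: int
    consistent: bool
    chimes: int


@dataclass(frozen=True)
class SessionLog:
    session_index: int
    prompt_id: int
    blocks: tuple[BlockLog, ...]
    minutes: float
    reward_shown: bool = True  # session-end nature-scene event flag


def evaluate_block(
    tap_times, level: int, config: TrainingConfig | None = None
) -> BlockLog:
    """Score one training block from its tap timestamps.

    A block is *consistent* when the tap count is within
    ``tap_count_tolerance`` of the expected count for the level and the
    coefficient of variation (CV) of the inter-tap intervals is at most
    ``consistency_cv_threshold``.  A reminder chime fires whenever an
    inter-tap interval exceeds ``(1 + cv_threshold)`` times the running
    median of the preceding intervals (the in-session distraction feedback).
    """
    config = config or TrainingConfig()
    if not 1 <= level <= config.max_level:
        raise ValueError(f"level {level} outside [1, {config.max_level}]")
    taps = np.asarray(tap_times, dtype=float)
    expected = config.expected_taps(level)
    if taps.size == 0:
        return BlockLog(level, (), expected, consistent=False, chimes=0)
    if taps.size > 1 and np.any(np.diff(taps) <= 0):
        raise ValueError("tap_times must be strictly increasing")

    intervals = np.diff(taps)
    count_ok = abs(taps.size - expected) <= config.tap_count_tolerance
    if intervals.size >= 2:
        cv = intervals.std() / intervals.mean()
    else:
        cv = 0.0
    consistent = bool(count_ok and cv <= config.consistency_cv_threshold)

    chimes = 0
    for i in range(1, intervals.size):
        running_median = float(np.median(intervals[:i]))
        if intervals[i] > (1.0 + config.consistency_cv_threshold) * running_median:
            chimes += 1
    return BlockLog(level, tuple(taps.tolist()), expected, consistent, chimes)


def update_level(
    state: TrainingState, block: BlockLog, config: TrainingConfig | None = None
) -> TrainingState:
    """Advance the engine state after a scored block.

    Consistent blocks build a streak; ``repeats_required`` in a row promote
    one level (capped at ``max_level``) and reset the streak.  An
    inconsistent block resets the streak without demotion.  At the maximum
    level the trainee stays there for all remaining sessions.
    """
    config = config or TrainingConfig()
    if block.level != state.level:
        raise ValueError("block level does not match current state level")
    minutes = state.cumulative_minutes + config.block_minutes(block.level)
    if not block.consistent:
        return replace(state, consecutive_consistent=0, cumulative_minutes=minutes)
    streak = state.consecutive_consistent + 1
    if streak >= config.repeats_required:
        return replace(
            state,
            level=min(state.level + 1, config.max_level),
            consecutive_consistent=0,
            cumulative_minutes=minutes,
        )
    return replace(state, consecutive_consistent=streak, cumulative_minutes=minutes)


def prompt_for_session(
    session_index: int, config: TrainingConfig | None = None
) -> int:
    """Compassion-prompt id for a session: advances every prompt_block_size
    sessions through the 10-prompt curriculum."""
    config = config or TrainingConfig()
    if not 1 <= session_index <= config.total_sessions:
        raise ValueError(
            f"session_index {session_index} outside [1, {config.total_sessions}]"
        )
    return min(
        math.ceil(session_index / config.prompt_block_size), len(COMPASSION_PROMPTS)
    )


def prompt_text(prompt_id: int) -> str:
    return COMPASSION_PROMPTS[prompt_id - 1]


@dataclass(frozen=True)
class SimulatedUser:
    """Generative model of a trainee.

    Breath periods are lognormal around ``breath_period_mean``.  With
    probability ``lapse_rate`` per breath the trainee loses count; a lapsed
    tap interval is stretched (missed count) or shortened (premature tap),
    which breaks both the tap count and the interval CV.  ``motivation``
    parameters give the truncated-normal distribution of sessions completed
    (defaults match an adherence of about 41 of 60 sessions with wide
    individual spread).
    """

    breath_period_mean: float = 6.0
    breath_period_sd: float = 0.5
    lapse_rate: float = 0.05
    motivation_mean: float = 40.64
    motivation_sd: float = 17.79
    motivation_bounds: tuple[float, float] = (0.0, 60.0)

    def __post_init__(self) -> None:
        if self.breath_period_mean <= 0:
            raise ValueError("breath_period_mean must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be a probability")

    def draw_sessions(self, rng: np.random.Generator) -> int:
        lo, hi = self.motivation_bounds
        for _ in range(1000):
            n = rng.normal(self.motivation_mean, self.motivation_sd)
            if lo <= n <= hi:
                return int(round(n))
        return int(round(np.clip(self.motivation_mean, lo, hi)))


def simulate_block_taps(
    user: SimulatedUser,
    level: int,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Tap times for one block from the breath/lapse model."""
    block_s = 60.0 * config.block_minutes(level)
    mu = math.log(user.breath_period_mean) - 0.5 * math.log(
        1.0 + (user.breath_period_sd / user.breath_period_mean) ** 2
    )
    sigma = math.sqrt(
        math.log(1.0 + (user.breath_period_sd / user.breath_period_mean) ** 2)
    )
    taps = []
    t = 0.0
    while True:
        # one tap spans `level` breaths; any lapse among them distorts the interval
        periods = rng.lognormal(mu, sigma, size=level)
        interval = float(periods.sum())
        lapsed = rng.random(level) < user.lapse_rate
        if lapsed.any():
            if rng.random() < 0.5:
                interval *= float(rng.uniform(1.6, 3.0))  # lost count, tapped late
            else:
                interval *= float(rng.uniform(0.3, 0.6))  # miscount, tapped early
        t += interval
        if t > block_s:
            break
        taps.append(t)
    return np.asarray(taps)


def simulate_participant_course(
    user: SimulatedUser,
    config: TrainingConfig | None = None,
    seed: int | np.random.Generator = 0,
    n_sessions: int | None = None,
) -> tuple[list[SessionLog], TrainingState]:
    """Simulate a full training course for one participant.

    The number of sessions is drawn from the user's motivation distribution
    unless ``n_sessions`` pins it.  Within a session, blocks at the current
    level are run until at least ``session_minutes_min`` minutes have been
    practiced; block length equals the level in minutes, so sessions span
    roughly 5-10 minutes.
    """
    config = config or TrainingConfig()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if n_sessions is None:
        n_sessions = user.draw_sessions(rng)
    n_sessions = int(min(n_sessions, config.total_sessions))

    state = TrainingState()
    sessions: list[SessionLog] = []
    for s in range(1, n_sessions + 1):
        prompt = prompt_for_session(s, config)
        blocks: list[BlockLog] = []
        minutes = 0.0
        state = replace(state, session_index=s)
        while minutes < config.session_minutes_min:
            taps = simulate_block_taps(user, state.level, config, rng)
            block = evaluate_block(taps, state.level, config)
            state = update_level(state, block, config)
            minutes += config.block_minutes(block.level)
            blocks.append(block)
        sessions.append(SessionLog(s, prompt, tuple(blocks), minutes))
    return sessions, state
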