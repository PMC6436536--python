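"""The adaptive dot-comparison experiment: levels, staircase rule, simulation.

Twelve fixed ratio levels (1:3 easiest through 11:12 hardest) each carry a
fixed pair of dot counts chosen to keep the total near 20.  A test session is
30 trials starting at the 1:2 ratio under a two-up/one-down staircase: two
consecutive correct answers at a level promote to the next harder level, one
error demotes, and the 1:2 ratio is the test floor.  Before testing,
participants must clear an 8-trial practice block at the 1:3 ratio with zero
errors, within at most three attempts.

Each level has a deck of 8 trial versions (4 red-correct, 4 black-correct),
shuffled per participant and dealt without replacement; a deck is reshuffled
when exhausted.  `simulate_session` drives all of this with a Bernoulli
responder whose accuracy follows the Gaussian ANS model, and every generated
session can be replayed from its seed and re-validated against the rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .psychophysics import Trial, _check_w, p_correct

__all__ = [
    "RatioLevel",
    "SessionRecord",
    "PracticeResult",
    "DotStimulusSpec",
    "InvalidStateError",
    "StimulusGenerationError",
    "PRACTICE_LEVEL",
    "START_LEVEL",
    "TEST_FLOOR",
    "TOP_LEVEL",
    "level_table",
    "next_level",
    "build_trial_deck",
    "simulate_session",
    "run_practice",
    "make_stimulus_spec",
    "validate_session",
]


class InvalidStateError(ValueError):
    """Staircase state outside its legal range."""


class StimulusGenerationError(RuntimeError):
    """Dot placement failed within the retry budget; retry with a new seed."""


@dataclass(frozen=True)
class RatioLevel:
    """One difficulty level: its 0-based index, ratio label, and fixed counts."""

    index: int
    ratio_label: str
    n_small: int
    n_large: int


# The published level list, easiest to hardest, with its fixed count pairs.
_LEVELS: tuple[RatioLevel, ...] = tuple(
    RatioLevel(i, label, s, l)
    for i, (label, s, l) in enumerate(
        [
            ("1:3", 5, 15),
            ("1:2", 7, 14),
            ("2:3", 8, 12),
            ("3:4", 9, 12),
            ("4:5", 8, 10),
            ("5:6", 10, 12),
            ("6:7", 12, 14),
            ("7:8", 7, 8),
            ("8:9", 8, 9),
            ("9:10", 9, 10),
            ("10:11", 10, 11),
            ("11:12", 11, 12),
        ]
    )
)

PRACTICE_LEVEL = 0  #: 1:3 — used only for the practice block
START_LEVEL = 1  #: 1:2 — every test session starts here
TEST_FLOOR = 1  #: errors at 1:2 keep the participant at 1:2
TOP_LEVEL = 11  #: 11:12 — promotions clamp here


def level_table() -> tuple[RatioLevel, ...]:
    """The 12 ratio levels in fixed order (immutable)."""
    return _LEVELS


@dataclass(frozen=True)
class SessionRecord:
    """An ordered test session for one participant on one task."""

    participant_id: str
    task: str
    trials: tuple[Trial, ...]
    seed: int


@dataclass(frozen=True)
class PracticeResult:
    """Outcome of the practice gate (pass requires a zero-error attempt)."""

    passed: bool
    attempts_used: int
    per_attempt_errors: tuple[int, ...]


@dataclass(frozen=True)
class DotStimulusSpec:
    """Geometry of one dot display inside the unit disc (not rasterized).

    The red and black radius sets are matched on their largest and smallest
    members; dots do not overlap and lie fully inside the disc.
    """

    level: RatioLevel
    red_is_larger: bool
    dot_radii_red: tuple[float, ...]
    dot_radii_black: tuple[float, ...]
    dot_centers: tuple[tuple[float, float], ...]


def next_level(current_index: int, outcome: str, consecutive_correct_at_level: int) -> int:
    """Two-up/one-down transition for the 30-trial test phase.

    ``consecutive_correct_at_level`` counts correct answers already given in a
    row at the current level, before this outcome.  A wrong answer demotes
    (floor at the 1:2 ratio); a second consecutive correct answer promotes
    (clamped at 11:12); otherwise the level is unchanged.
    """
    if not TEST_FLOOR <= current_index <= TOP_LEVEL:
        raise InvalidStateError(f"test level index out of {TEST_FLOOR}..{TOP_LEVEL}: {current_index}")
    if outcome not in ("correct", "wrong"):
        raise InvalidStateError(f"outcome must be 'correct' or 'wrong', got {outcome!r}")
    if consecutive_correct_at_level < 0:
        raise InvalidStateError("consecutive_correct_at_level must be >= 0")
    if outcome == "wrong":
        return max(current_index - 1, TEST_FLOOR)
    if consecutive_correct_at_level >= 1:
        return min(current_index + 1, TOP_LEVEL)
    return current_index


def _as_rng(rng_seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def build_trial_deck(
    level: RatioLevel, rng_seed: int | np.random.Generator
) -> list[bool]:
    """A shuffled deck of the level's 8 versions, as red-correct flags.

    Exactly four versions have red as the more numerous (correct) color and
    four have black; the order is a seeded uniform shuffle.  Decks are dealt
    without replacement during a session and rebuilt when exhausted.
    """
    rng = _as_rng(rng_seed)
    deck = [True] * 4 + [False] * 4
    rng.shuffle(deck)
    return deck


def _deal(decks: dict[int, list[bool]], level: RatioLevel, rng: np.random.Generator) -> bool:
    deck = decks.get(level.index)
    if not deck:
        deck = build_trial_deck(level, rng)
        decks[level.index] = deck
    return deck.pop(0)


def _respond(level: RatioLevel, red_correct: bool, w: float, rng: np.random.Generator,
             task: str, trial_index: int) -> Trial:
    p = p_correct(level.n_small, level.n_large, w)
    correct = bool(rng.random() < p)
    correct_color = "red" if red_correct else "black"
    other = "black" if red_correct else "red"
    return Trial(
        n_small=level.n_small,
        n_large=level.n_large,
        correct_color=correct_color,
        response_color=correct_color if correct else other,
        level_index=level.index,
        task=task,
        trial_index=trial_index,
    )


def simulate_session(
    w: float,
    task: str,
    participant_id: str,
    rng_seed: int | np.random.Generator,
    n_trials: int = 30,
) -> SessionRecord:
    """Simulate one test session for a responder with Weber fraction ``w``.

    Responses are Bernoulli draws at the model accuracy for each level's fixed
    count pair; the level sequence follows :func:`next_level`.  Passing an
    integer seed makes the record fully replayable.
    """
    w = _check_w(w)
    rng = _as_rng(rng_seed)
    seed = rng_seed if isinstance(rng_seed, int) else -1
    levels = level_table()
    decks: dict[int, list[bool]] = {}
    idx = START_LEVEL
    streak = 0  # consecutive correct answers at the current level
    trials: list[Trial] = []
    for t in range(1, n_trials + 1):
        level = levels[idx]
        red_correct = _deal(decks, level, rng)
        trial = _respond(level, red_correct, w, rng, task, t)
        trials.append(trial)
        new_idx = next_level(idx, "correct" if trial.is_correct else "wrong", streak)
        if trial.is_correct and new_idx == idx and streak == 0:
            streak = 1
        else:
            streak = 0  # reset on any level change, on promotion-clamp, or on error
        idx = new_idx
    return SessionRecord(participant_id=participant_id, task=task,
                         trials=tuple(trials), seed=seed)


def run_practice(w: float, rng_seed: int | np.random.Generator) -> PracticeResult:
    """Run the practice gate: up to three 8-trial blocks at the 1:3 ratio.

    An attempt passes only with zero errors; each attempt re-shuffles the
    eight practice versions.
    """
    w = _check_w(w)
    rng = _as_rng(rng_seed)
    level = level_table()[PRACTICE_LEVEL]
    errors: list[int] = []
    for attempt in range(1, 4):
        deck = build_trial_deck(level, rng)
        n_err = 0
        for i, red_correct in enumerate(deck, start=1):
            trial = _respond(level, red_correct, w, rng, "cards", i)
            n_err += 0 if trial.is_correct else 1
        errors.append(n_err)
        if n_err == 0:
            return PracticeResult(True, attempt, tuple(errors))
    return PracticeResult(False, 3, tuple(errors))


def validate_session(record: SessionRecord) -> None:
    """Replay the staircase over the session's outcomes; raise on any mismatch.

    Checks consecutive trial indices from 1, level/count consistency with the
    level table, the start level, and every level transition.
    """
    levels = level_table()
    idx = START_LEVEL
    streak = 0
    for t, trial in enumerate(record.trials, start=1):
        if trial.trial_index != t:
            raise InvalidStateError(
                f"trial_index {trial.trial_index} at position {t} is not consecutive"
            )
        lev = levels[trial.level_index]
        if (trial.n_small, trial.n_large) != (lev.n_small, lev.n_large):
            raise InvalidStateError(
                f"trial {t}: counts ({trial.n_small}, {trial.n_large}) do not match "
                f"level {lev.ratio_label} ({lev.n_small}, {lev.n_large})"
            )
        if trial.level_index != idx:
            raise InvalidStateError(
                f"trial {t}: at level {trial.level_index}, staircase expects {idx}"
            )
        new_idx = next_level(idx, "correct" if trial.is_correct else "wrong", streak)
        if trial.is_correct and new_idx == idx and streak == 0:
            streak = 1
        else:
            streak = 0
        idx = new_idx


def make_stimulus_spec(
    level: RatioLevel,
    red_is_larger: bool,
    rng_seed: int | np.random.Generator,
    radius_bounds: tuple[float, float] = (0.02, 0.07),
    max_tries_per_dot: int = 4000,
) -> DotStimulusSpec:
    """Generate a non-overlapping dot layout in the unit disc for one level.

    Radii are drawn log-uniform within ``radius_bounds`` and then the largest
    and smallest radius of each color set are forced equal across the two
    sets (the extremes-matching constraint).  Centers are rejection-sampled
    so dots neither overlap each other nor cross the disc boundary.
    """
    rng = _as_rng(rng_seed)
    lo, hi = radius_bounds
    if not 0 < lo < hi:
        raise ValueError(f"radius_bounds must satisfy 0 < lo < hi, got {radius_bounds}")
    n_red = level.n_large if red_is_larger else level.n_small
    n_black = level.n_small if red_is_larger else level.n_large

    def draw(n: int) -> np.ndarray:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    red = draw(n_red)
    black = draw(n_black)
    # Match extremes: both sets share the global max and global min radius.
    r_max = max(red.max(), black.max())
    r_min = min(red.min(), black.min())
    for arr in (red, black):
        arr[int(np.argmax(arr))] = r_max
        arr[int(np.argmin(arr))] = r_min

    radii = np.concatenate([red, black])
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii:
        for _ in range(max_tries_per_dot):
            # uniform in the disc of radius 1 - r
            u = rng.random()
            theta = rng.uniform(0.0, 2.0 * np.pi)
            rad = (1.0 - r) * np.sqrt(u)
            x, y = rad * np.cos(theta), rad * np.sin(theta)
            if all(
                (x - cx) ** 2 + (y - cy) ** 2 > (r + pr) ** 2
                for (cx, cy), pr in zip(centers, placed_r)
            ):
                centers.append((float(x), float(y)))
                placed_r.append(float(r))
                break
        else:
            raise StimulusGenerationError(
                f"could not place dot of radius {r:.4f} after {max_tries_per_dot} tries"
            )
    return DotStimulusSpec(
        level=level,
        red_is_larger=red_is_larger,
        dot_radii_red=tuple(float(r) for r in red),
        dot_radii_black=tuple(float(r) for r in black),
        dot_centers=tuple(centers),
    )
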