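"""Gaussian model of approximate-number comparison.

The approximate number sense (ANS) is modeled as noisy Gaussian magnitude
codes: a set of ``n`` dots is represented as a draw from ``Normal(n, (w*n)**2)``,
where ``w`` is the subject's Weber fraction (smaller ``w`` = sharper acuity).
A two-color comparison ("more red or more black?") is answered correctly when
the representation of the larger set exceeds that of the smaller, which gives
the closed form

    P(correct) = Phi( |n1 - n2| / (w * sqrt(n1**2 + n2**2)) )

with ``Phi`` the standard normal CDF.  This is the canonical linking function
of the maximum-likelihood Weber-fraction fitting tradition; the difference of
two independent scalar-variability Gaussians is Gaussian with variance
``w**2 * (n1**2 + n2**2)``.

This module holds the trial container, the psychometric function, and the
session log-likelihood that every estimator downstream maximizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "COLORS",
    "TASKS",
    "Trial",
    "InvalidParameterError",
    "p_correct",
    "session_loglik",
]

#: Valid response/correct colors of the two intermixed dot sets.
COLORS = ("red", "black")

#: The two presentation modes of the comparison task.
TASKS = ("cards", "computer")

#: Per-trial probabilities are clamped into this open interval inside the log
#: so the likelihood stays finite at extreme Weber fractions.
_P_FLOOR = 1e-9


class InvalidParameterError(ValueError):
    """A Weber fraction, count, or lapse rate outside its valid domain."""


@dataclass(frozen=True)
class Trial:
    """One more-red-or-more-black judgment.

    ``n_small``/``n_large`` are the two set sizes (the color assignment is
    carried by ``correct_color``: the correct answer is the more numerous
    color).  ``level_index`` is the 0-based difficulty level (0 = 1:3 practice
    ratio, 11 = 11:12); consistency of the counts with the level table is
    enforced where trials cross a file or session boundary, not here, to keep
    this container independent of the staircase.
    """

    n_small: int
    n_large: int
    correct_color: str
    response_color: str
    level_index: int
    task: str
    trial_index: int

    def __post_init__(self) -> None:
        if self.n_small < 1 or self.n_large < 1:
            raise InvalidParameterError(
                f"dot counts must be >= 1, got ({self.n_small}, {self.n_large})"
            )
        if self.n_small > self.n_large:
            raise InvalidParameterError(
                f"n_small must not exceed n_large, got ({self.n_small}, {self.n_large})"
            )
        if self.correct_color not in COLORS or self.response_color not in COLORS:
            raise InvalidParameterError(
                f"colors must be in {COLORS}, got "
                f"({self.correct_color!r}, {self.response_color!r})"
            )
        if self.task not in TASKS:
            raise InvalidParameterError(f"task must be in {TASKS}, got {self.task!r}")
        if not 0 <= self.level_index <= 11:
            raise InvalidParameterError(f"level_index out of 0..11: {self.level_index}")
        if self.trial_index < 1:
            raise InvalidParameterError(f"trial_index must be >= 1: {self.trial_index}")

    @property
    def is_correct(self) -> bool:
        return self.response_color == self.correct_color


def _check_w(w: float) -> float:
    w = float(w)
    if not math.isfinite(w) or w <= 0.0:
        raise InvalidParameterError(f"Weber fraction must be a finite positive real, got {w!r}")
    return w


def p_correct(n_small: float, n_large: float, w: float) -> float:
    """Probability of a correct comparison of ``n_small`` vs ``n_large`` dots.

    Parameters
    ----------
    n_small, n_large
        The two set sizes (order does not matter; the absolute difference is
        used).  Must be >= 1.
    w
        Weber fraction, > 0.

    Returns
    -------
    float
        ``Phi(|n_large - n_small| / (w * sqrt(n_small**2 + n_large**2)))``,
        in ``[0.5, 1)``; exactly 0.5 when the sets are equinumerous.
    """
    w = _check_w(w)
    if n_small < 1 or n_large < 1:
        raise InvalidParameterError(
            f"dot counts must be >= 1, got ({n_small}, {n_large})"
        )
    d = abs(float(n_large) - float(n_small))
    if d == 0.0:
        return 0.5
    sigma = w * math.hypot(float(n_small), float(n_large))
    return float(ndtr(d / sigma))


def _p_correct_vec(n_small: np.ndarray, n_large: np.ndarray, w: float) -> np.ndarray:
    """Vectorized psychometric function (no per-element validation)."""
    # sigma > 0 whenever w > 0 and counts >= 1; d == 0 yields ndtr(0) == 0.5
    return ndtr(np.abs(n_large - n_small) / (w * np.hypot(n_small, n_large)))


def session_loglik(
    trials: Sequence[Trial] | Iterable[Trial], w: float, lapse: float = 0.0
) -> float:
    """Bernoulli log-likelihood of a set of trials under Weber fraction ``w``.

    Each trial contributes ``log(p_eff)`` if answered correctly and
    ``log(1 - p_eff)`` otherwise, with
    ``p_eff = (1 - lapse) * p_correct + lapse * 0.5``.  The default lapse rate
    is 0 (no guessing parameter); probabilities are clamped away from {0, 1}
    so the sum stays finite.  An empty trial set has log-likelihood 0.
    """
    w = _check_w(w)
    lapse = float(lapse)
    if not 0.0 <= lapse < 0.5:
        raise InvalidParameterError(f"lapse must lie in [0, 0.5), got {lapse}")
    trials = list(trials)
    if not trials:
        return 0.0
    ns = np.array([t.n_small for t in trials], dtype=float)
    nl = np.array([t.n_large for t in trials], dtype=float)
    ok = np.array([t.is_correct for t in trials], dtype=bool)
    p = _p_correct_vec(ns, nl, w)
    p_eff = (1.0 - lapse) * p + lapse * 0.5
    p_eff = np.clip(p_eff, _P_FLOOR, 1.0 - _P_FLOOR)
    return float(np.sum(np.where(ok, np.log(p_eff), np.log1p(-p_eff))))
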