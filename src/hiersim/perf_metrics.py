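"""Individual and group performance scores.

Each agent receives a binary feedback per round (1 for a correct guess of
the environment state, 0 otherwise).  Its running score is an exponential
moving average (EMA) of the full feedback history with half-life
``half_life`` rounds: a feedback received ``r`` rounds ago carries relative
weight ``beta**r`` where ``beta = 2**(-1/half_life)``, so 0.5 at one
half-life and 0.25 at two.  To avoid start-up transients the history is
treated as preceded by an infinite run of the agent's own ability ``a_i``
(the long-run score it would earn without any communication), which simply
means the EMA is initialised at ``a_i``.

Group performance is the mean score over agents; the *relative improvement*
compares it with the no-communication baseline, the mean ability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScoreState",
    "ema_decay",
    "ema_update",
    "group_performance",
    "relative_improvement",
]


def ema_decay(half_life: float) -> float:
    """Per-round decay factor ``beta = 2**(-1/half_life)``.

    ``half_life`` must be positive; beta lies in (0, 1).
    """
    if half_life <= 0:
        raise ValueError(f"half_life must be positive, got {half_life}")
    return 0.5 ** (1.0 / half_life)


def ema_update(score, feedback, beta: float):
    """One EMA step, ``score' = beta * score + (1 - beta) * feedback``.

    Works element-wise on arrays.  ``feedback`` must be 0/1 (booleans are
    accepted); with the normalised ``(beta, 1-beta)`` weighting the score
    stays in [0, 1] and equals the weight-``beta**r`` average of the whole
    (infinitely ``a_i``-prefixed) feedback history.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must lie in (0, 1), got {beta}")
    fb = np.asarray(feedback)
    if not np.all((fb == 0) | (fb == 1)):
        raise ValueError("feedback values must be 0 or 1")
    out = beta * np.asarray(score, dtype=float) + (1.0 - beta) * fb
    return out if out.ndim else float(out)


def group_performance(scores) -> float:
    """Mean EMA score over the group (the group's overall performance)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("group_performance of an empty population is undefined")
    return float(scores.mean())


def relative_improvement(group_perf: float, baseline: float) -> float:
    """Group performance relative to the no-communication baseline.

    Returns ``group_perf / baseline - 1``: 0 means communication adds
    nothing, 1 (i.e. 100%) means the group performs twice as well as
    isolated agents would.  ``baseline`` is normally the mean ability.
    """
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    return group_perf / baseline - 1.0


@dataclass
class ScoreState:
    """EMA scores of a population plus the decay constant."""

    scores: np.ndarray
    half_life: float = 50.0
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.beta = ema_decay(self.half_life)

    def update(self, feedback) -> None:
        self.scores = ema_update(self.scores, feedback, self.beta)

    @property
    def group_performance(self) -> float:
        return group_performance(self.scores)
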