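"""Adaptive descending staircase for behavioural recognition thresholds.

The signal starts at 76 dB and is lowered in 3 dB steps until the first
non-response; a single final probe is then presented half a step (1.5 dB)
above the non-response level.  If the probe elicits a response it becomes the
upper bound (UB) and the non-response level the lower bound (LB); otherwise
the probe level is the lower bound and the last responded level the upper
bound.  The recognition threshold is the power-domain average

    threshold = 10 * log10((10**(UB/10) + 10**(LB/10)) / 2)

which always lies between LB and UB (and at or above their dB midpoint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseResult",
    "threshold_formula",
    "run_staircase",
    "DeterministicObserver",
    "LogisticObserver",
]


@dataclass(frozen=True)
class StaircaseConfig:
    start_db: float = 76.0
    step_db: float = 3.0
    min_db: float = 20.0

    def __post_init__(self) -> None:
        if self.step_db <= 0:
            raise ValueError("step_db must be positive")
        if self.min_db >= self.start_db:
            raise ValueError("min_db must lie below start_db")

    @property
    def half_step_db(self) -> float:
        return self.step_db / 2.0


@dataclass
class StaircaseResult:
    ub_db: float
    lb_db: float
    threshold_db: float
    trials: list[tuple[float, bool]]  # (level, responded)
    above_range: bool = False
    below_range: bool = False


def threshold_formula(ub_db: float, lb_db: float) -> float:
    """Power-domain average of the bracketing levels (exact evaluation)."""
    if not (math.isfinite(ub_db) and math.isfinite(lb_db)):
        raise ValueError("bounds must be finite")
    return 10.0 * math.log10((10.0 ** (ub_db / 10.0) + 10.0 ** (lb_db / 10.0)) / 2.0)


class DeterministicObserver:
    """Responds iff level >= true threshold (hard threshold)."""

    def __init__(self, threshold_db: float):
        self.threshold_db = threshold_db

    def __call__(self, level_db: float, rng: np.random.Generator) -> bool:
        return level_db >= self.threshold_db


class LogisticObserver:
    """Responds with probability 1/(1+exp(-(level-threshold)/slope))."""

    def __init__(self, threshold_db: float, slope_db: float = 1.0):
        if slope_db <= 0:
            raise ValueError("slope_db must be positive")
        self.threshold_db = threshold_db
        self.slope_db = slope_db

    def probability(self, level_db: float) -> float:
        return 1.0 / (1.0 + math.exp(-(level_db - self.threshold_db) / self.slope_db))

    def __call__(self, level_db: float, rng: np.random.Generator) -> bool:
        return rng.random() < self.probability(level_db)


def run_staircase(observer: Callable[[float, np.random.Generator], bool],
                  cfg: StaircaseConfig = StaircaseConfig(),
                  seed: Optional[int] = None) -> StaircaseResult:
    """Run the descending staircase against an observer.

    ``observer(level_db, rng) -> bool`` reports whether the subject responded
    at that level.  A non-response at the starting level flags the estimate
    as above-range; reaching ``min_db`` without a non-response flags it as
    below-range (bounds then bracket the floor).
    """
    rng = np.random.default_rng(seed)
    trials: list[tuple[float, bool]] = []
    level = cfg.start_db
    last_yes: Optional[float] = None
    first_no: Optional[float] = None
    while True:
        responded = bool(observer(level, rng))
        trials.append((level, responded))
        if not responded:
            first_no = level
            break
        last_yes = level
        if level - cfg.step_db < cfg.min_db:
            # ran into the floor while still responding
            ub = level
            lb = level - cfg.step_db
            return StaircaseResult(ub_db=ub, lb_db=lb,
                                   threshold_db=threshold_formula(ub, lb),
                                   trials=trials, below_range=True)
        level -= cfg.step_db
    if last_yes is None:
        # non-response at the very first level: threshold above tested range
        ub = cfg.start_db + cfg.step_db
        lb = cfg.start_db
        return StaircaseResult(ub_db=ub, lb_db=lb,
                               threshold_db=threshold_formula(ub, lb),
                               trials=trials, above_range=True)
    probe = first_no + cfg.half_step_db
    responded = bool(observer(probe, rng))
    trials.append((probe, responded))
    if responded:
        ub, lb = probe, first_no
    else:
        ub, lb = last_yes, probe
    return StaircaseResult(ub_db=ub, lb_db=lb,
                           threshold_db=threshold_formula(ub, lb),
                           trials=trials)
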