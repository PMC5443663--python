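"""Signal-detection analysis of auditory-nerve responses: masked thresholds.

Multi-unit nerve responses are reduced to a per-sweep scalar (impulse count
or window RMS over a fixed 40 ms window), separately for a masker-alone epoch
and a signal-plus-masker epoch.  Detectability at each swept level is the
standard separation

    d_a = (mu_sn - mu_n) / sqrt((sigma2_sn + sigma2_n) / 2)

which, unlike d', does not assume equal variances.  A monotone logistic is
fitted to d_a versus level and the masked threshold is the level at which the
fitted curve crosses d_a = 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ear import SpikeTrain
from .vibrometry import FittedSigmoid, fit_sigmoid

__all__ = [
    "ResponseSample",
    "DaPoint",
    "MaskedThreshold",
    "detect_impulses",
    "standard_separation",
    "masked_threshold",
]

RESPONSE_WINDOW_S = 0.040  # fixed analysis window


@dataclass
class ResponseSample:
    """Per-sweep response measures for one condition at one level."""

    condition: str  # "masker_alone" | "signal_plus_masker"
    values: np.ndarray  # one scalar per sweep
    level_db: float
    measure: str = "impulse_count"  # or "window_rms"
    window_s: float = RESPONSE_WINDOW_S

    def __post_init__(self) -> None:
        if self.condition not in ("masker_alone", "signal_plus_masker"):
            raise ValueError("condition must be masker_alone or signal_plus_masker")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D per-sweep array")

    @property
    def sweeps(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def var(self) -> float:
        return float(np.var(self.values, ddof=1))


@dataclass
class DaPoint:
    level_db: float
    d_a: float


@dataclass
class MaskedThreshold:
    threshold_db: Optional[float]
    ear: str = "unspecified"
    in_range: bool = True
    fit: Optional[FittedSigmoid] = None


def detect_impulses(voltage: np.ndarray, fs_hz: float,
                    quiet_epoch: tuple[float, float],
                    dead_time_ms: float = 1.0,
                    channel: str = "unspecified") -> SpikeTrain:
    """Threshold-crossing impulse detection on an extracellular voltage trace.

    The detection threshold is RMS(quiet) + 3*SD(quiet), calibrated on an
    unstimulated epoch of at least 100 ms; events are upward crossings of the
    rectified voltage, with a 1 ms dead time between accepted events.
    """
    x = np.asarray(voltage, dtype=float)
    q0 = int(round(quiet_epoch[0] * fs_hz))
    q1 = int(round(quiet_epoch[1] * fs_hz))
    if q1 - q0 < int(0.1 * fs_hz):
        raise ValueError("quiet epoch must span at least 100 ms")
    quiet = x[q0:q1]
    if quiet.size == 0:
        raise ValueError("quiet epoch lies outside the trace")
    rms = float(np.sqrt(np.mean(quiet ** 2)))
    sd = float(np.std(quiet))
    thresh = rms + 3.0 * sd
    if thresh <= 0:
        return SpikeTrain(times_s=np.empty(0), channel=channel)
    rect = np.abs(x)
    above = rect > thresh
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    dead = dead_time_ms / 1000.0
    times: list[float] = []
    t_last = -np.inf
    for idx in crossings:
        t = idx / fs_hz
        if t - t_last >= dead:
            times.append(t)
            t_last = t
    return SpikeTrain(times_s=np.array(times), channel=channel)


def standard_separation(sample_n: ResponseSample | np.ndarray,
                        sample_sn: ResponseSample | np.ndarray,
                        form: str = "pooled") -> float:
    """Standard separation d_a between masker-alone and signal-plus-masker.

    form="pooled" (default): denominator sqrt((var_sn + var_n)/2), the usual
    unequal-variance-tolerant definition.  form="printed": denominator
    sqrt((var_sn - var_n)/2); returns NaN when the radicand is not positive,
    since a variance *difference* can vanish or go negative.
    """
    vn = sample_n.values if isinstance(sample_n, ResponseSample) else np.asarray(sample_n, float)
    vs = sample_sn.values if isinstance(sample_sn, ResponseSample) else np.asarray(sample_sn, float)
    if len(vn) < 2 or len(vs) < 2:
        raise ValueError("need at least 2 sweeps per condition")
    mu_n, mu_sn = float(np.mean(vn)), float(np.mean(vs))
    var_n, var_sn = float(np.var(vn, ddof=1)), float(np.var(vs, ddof=1))
    if form == "pooled":
        radicand = (var_sn + var_n) / 2.0
    elif form == "printed":
        radicand = (var_sn - var_n) / 2.0
    else:
        raise ValueError(f"unknown d_a form: {form!r}")
    if radicand <= 0:
        if form == "printed":
            return math.nan
        # pooled radicand is zero only when both samples are constant
        return math.inf if mu_sn != mu_n else 0.0
    return (mu_sn - mu_n) / math.sqrt(radicand)


def da_from_moments(mu_n: float, mu_sn: float, var_n: float, var_sn: float,
                    form: str = "pooled") -> float:
    """d_a evaluated directly from distribution moments (analytic reference)."""
    if form == "pooled":
        radicand = (var_sn + var_n) / 2.0
    elif form == "printed":
        radicand = (var_sn - var_n) / 2.0
    else:
        raise ValueError(f"unknown d_a form: {form!r}")
    if radicand <= 0:
        return math.nan if form == "printed" else (math.inf if mu_sn != mu_n else 0.0)
    return (mu_sn - mu_n) / math.sqrt(radicand)


def masked_threshold(points: Sequence[DaPoint], criterion: float = 1.0,
                     ear: str = "unspecified",
                     increasing_with_level: Optional[bool] = None) -> MaskedThreshold:
    """Fitted-curve masked threshold: level where fitted d_a crosses ``criterion``.

    A monotone logistic is fitted to (level, d_a) and the crossing of the
    criterion is found by bisection on the fitted curve.  If the fitted curve
    never reaches the criterion within the tested level range the result
    carries ``in_range=False`` and no threshold.  The threshold is reported on
    whichever level axis was swept (signal level: d_a rises with level; masker
    level: d_a falls with level) — the crossing logic only needs monotonicity.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 levels to fit the threshold curve")
    levels = np.array([p.level_db for p in points], dtype=float)
    das = np.array([p.d_a for p in points], dtype=float)
    if not np.all(np.isfinite(das)):
        raise ValueError("non-finite d_a values")
    fit = fit_sigmoid(levels, das)
    lo, hi = float(np.min(levels)), float(np.max(levels))
    f_lo, f_hi = float(fit(lo)), float(fit(hi))
    if (f_lo - criterion) * (f_hi - criterion) > 0:
        return MaskedThreshold(threshold_db=None, ear=ear, in_range=False, fit=fit)
    a, b = lo, hi
    sign = 1.0 if f_hi > f_lo else -1.0
    while b - a > 1e-9:
        mid = 0.5 * (a + b)
        if sign * (float(fit(mid)) - criterion) < 0:
            a = mid
        else:
            b = mid
    return MaskedThreshold(threshold_db=0.5 * (a + b), ear=ear, in_range=True, fit=fit)
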