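"""Injection-induced changes in ear mechanical tuning frequency.

Thoracic injection experiments track the flagellar best frequency of an
individual mosquito before and after injecting a serotonin-related
compound. Baseline tuning is measured three or more times before the
injection (t < 0); post-injection tuning is then re-measured every few
minutes. A loess curve through the post-injection points, evaluated at
one-minute intervals, gives a per-minute estimate of the tuning
frequency; subtracting the scalar baseline yields a per-minute
``dFrequency`` whose median summarises the compound's effect
(``median dFrequency``).

Two-injection protocols (serotonin followed, ten minutes later, by a
receptor antagonist) are summarised by ``min dFrequency``: the minimum
of the phase-2 smoothed curve relative to the smoothed tuning level
reached at the moment of the second injection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError, ProtocolError
from .smoothing import SmoothConfig, loess_fit, smooth_series

__all__ = [
    "FrequencyTimeSeries",
    "InjectionExperiment",
    "DeltaFrequencyResult",
    "TwoInjectionResult",
    "baseline_frequency",
    "median_delta_frequency",
    "min_delta_frequency",
    "smooth_series",
    "SmoothConfig",
]


@dataclass(frozen=True)
class FrequencyTimeSeries:
    """Best-frequency measurements around an injection at t = 0 min."""

    times_min: np.ndarray
    frequencies_hz: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        f = np.asarray(self.frequencies_hz, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "frequencies_hz", f)
        if t.shape != f.shape or t.ndim != 1:
            raise InvalidInputError("times and frequencies must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise InvalidInputError("frequencies must be finite and positive")

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.times_min < 0

    @property
    def post_mask(self) -> np.ndarray:
        return self.times_min > 0


@dataclass(frozen=True)
class InjectionExperiment:
    series: FrequencyTimeSeries
    first_compound: str
    second_compound: str | None = None
    second_injection_time_min: float | None = None
    sex: str = "male"

    def __post_init__(self) -> None:
        if (self.second_compound is None) != (self.second_injection_time_min is None):
            raise ProtocolError(
                "second_compound and second_injection_time_min must be given together"
            )


@dataclass(frozen=True)
class DeltaFrequencyResult:
    baseline_hz: float
    per_minute_deltas: list[tuple[float, float]]
    median_delta_hz: float


@dataclass(frozen=True)
class TwoInjectionResult:
    phase1_median_delta_hz: float
    reference_after_first_hz: float
    min_delta_hz: float
    min_time_min: float


def baseline_frequency(series: FrequencyTimeSeries) -> float:
    """Median of the pre-injection (t < 0) best frequencies, in Hz."""
    base = series.frequencies_hz[series.baseline_mask]
    if base.size < 3:
        raise InsufficientDataError(
            f"need >= 3 baseline (t < 0) points, got {base.size}"
        )
    return float(np.median(base))


def _minute_grid(t_start: float, t_last: float, step: float) -> np.ndarray:
    """Integer-minute grid from t_start to floor(t_last), never extrapolating."""
    t_end = math.floor(t_last / step) * step
    if t_end < t_start:
        raise InsufficientDataError("post-injection window too short for the grid")
    n = int(round((t_end - t_start) / step)) + 1
    return t_start + step * np.arange(n)


def median_delta_frequency(
    exp: InjectionExperiment,
    config: SmoothConfig | None = None,
    window_min: float | None = None,
) -> DeltaFrequencyResult:
    """Median per-minute tuning shift after a single injection.

    Smooths the post-injection points only, evaluates at t = 1, 2, ...
    minutes up to the last observation (optionally capped at
    ``window_min``), subtracts the scalar baseline, and returns all
    per-minute deltas together with their median.
    """
    if exp.second_compound is not None:
        raise ProtocolError("median_delta_frequency is for single-injection experiments")
    cfg = config or SmoothConfig()
    base = baseline_frequency(exp.series)
    post = exp.series.post_mask
    t_post = exp.series.times_min[post]
    f_post = exp.series.frequencies_hz[post]
    if t_post.size < 4:
        raise InsufficientDataError("need >= 4 post-injection points")
    t_last = float(t_post.max())
    if window_min is not None:
        t_last = min(t_last, window_min)
    step = cfg.eval_step_min
    grid = _minute_grid(step, t_last, step)
    grid = grid[grid >= t_post.min()]
    if grid.size == 0:
        raise InsufficientDataError("no in-range grid points after the injection")
    fitted = smooth_series(t_post, f_post, cfg, grid)
    deltas = [(t, v - base) for t, v in fitted]
    return DeltaFrequencyResult(
        baseline_hz=base,
        per_minute_deltas=deltas,
        median_delta_hz=float(np.median([d for _, d in deltas])),
    )


def min_delta_frequency(
    exp: InjectionExperiment,
    config: SmoothConfig | None = None,
    phase2_window_min: float = 30.0,
) -> TwoInjectionResult:
    """Two-injection summary: minimum phase-2 shift against the phase-1 level.

    Phase 1 covers (0, t2]; its loess curve (evaluated on the 1-min
    grid) gives both the phase-1 median delta against baseline and the
    reference level at t2. Phase 2 covers (t2, t2 + window]; the
    minimum of its smoothed curve minus the reference is ``min
    dFrequency`` (negative when the second compound suppresses the
    serotonin-induced shift).
    """
    if exp.second_compound is None or exp.second_injection_time_min is None:
        raise ProtocolError("min_delta_frequency requires a two-injection experiment")
    cfg = config or SmoothConfig()
    t2 = float(exp.second_injection_time_min)
    base = baseline_frequency(exp.series)
    t = exp.series.times_min
    f = exp.series.frequencies_hz

    m1 = (t > 0) & (t <= t2)
    if m1.sum() < 3:
        raise InsufficientDataError("need >= 3 points between the injections")
    t1, f1 = t[m1], f[m1]
    step = cfg.eval_step_min
    grid1 = _minute_grid(step, min(float(t1.max()), t2), step)
    grid1 = grid1[grid1 >= t1.min()]
    fitted1 = loess_fit(t1, f1, grid1, cfg.span, cfg.degree)
    phase1_median = float(np.median(fitted1 - base))
    # reference level "after serotonin injection": smoothed phase-1 value at t2
    ref = float(loess_fit(t1, f1, np.array([min(t2, float(t1.max()))]), cfg.span, cfg.degree)[0])

    m2 = (t > t2) & (t <= t2 + phase2_window_min)
    if m2.sum() < 4:
        raise InsufficientDataError("need >= 4 points after the second injection")
    t2s, f2s = t[m2], f[m2]
    g_start = math.ceil(t2s.min() / step) * step
    g_end = math.floor(min(float(t2s.max()), t2 + phase2_window_min) / step) * step
    grid2 = np.arange(g_start, g_end + step / 2, step)
    fitted2 = loess_fit(t2s, f2s, grid2, cfg.span, cfg.degree)
    i_min = int(np.argmin(fitted2))
    return TwoInjectionResult(
        phase1_median_delta_hz=phase1_median,
        reference_after_first_hz=ref,
        min_delta_hz=float(fitted2[i_min] - ref),
        min_time_min=float(grid2[i_min]),
    )
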