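"""Phonotactic-profile statistics: AUC and response-frequency range.

Groups of 30 male mosquitoes are exposed to pure tones from 350 to
750 Hz in 25-Hz steps; the number of males landing next to the speaker
during each tone, minus those already landed before its onset, gives
the net responder count per tone. Counts are normalized within each
repeat (cage) by the largest net count across all tones and all tested
days/conditions of that cage, so every repeat's strongest response maps
to 1. Two summaries are computed per profile: the trapezoidal area
under the normalized response curve (AUC, in Hz x normalized response)
and the response range — the frequency interval over which a loess fit
of the profile stays above 25% of its peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateRepeatError,
    InsufficientDataError,
    InvalidInputError,
    PairingError,
)
from .smoothing import SmoothConfig, loess_fit
from .stats import TestResult, wilcoxon_signed_rank

__all__ = [
    "ToneTrial",
    "PhonotacticProfile",
    "ResponseRange",
    "net_responders",
    "normalize_repeat",
    "profile_auc",
    "response_range",
    "compare_paired",
    "TONE_SET_HZ",
    "GROUP_SIZE",
]

TONE_SET_HZ = tuple(range(350, 751, 25))
GROUP_SIZE = 30

PROFILE_SMOOTH = SmoothConfig(span=0.75, degree=2)


@dataclass(frozen=True)
class ToneTrial:
    """Landing counts for one pure tone: before onset and during playback."""

    frequency_hz: float
    landed_before: int
    landed_during: int

    def __post_init__(self) -> None:
        for name in ("landed_before", "landed_during"):
            v = getattr(self, name)
            if not (0 <= v <= GROUP_SIZE):
                raise InvalidInputError(f"{name}={v} outside [0, {GROUP_SIZE}]")


@dataclass(frozen=True)
class PhonotacticProfile:
    """Per-tone trials for one cage (repeat) on one day/condition.

    ``responses`` holds normalized responses once :func:`normalize_repeat`
    has been applied; raw profiles leave it None.
    """

    repeat_id: str
    day_condition: str
    trials: tuple[ToneTrial, ...]
    responses: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        freqs = [t.frequency_hz for t in self.trials]
        if len(set(freqs)) != len(freqs):
            raise InvalidInputError("duplicate tone frequencies in profile")
        bad = [f for f in freqs if f not in TONE_SET_HZ]
        if bad:
            raise InvalidInputError(f"tones outside the 350-750 Hz / 25 Hz set: {bad}")

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.array([t.frequency_hz for t in self.trials], dtype=float)

    @property
    def net_counts(self) -> np.ndarray:
        return np.array([net_responders(t) for t in self.trials], dtype=float)


@dataclass(frozen=True)
class ResponseRange:
    peak_hz: float
    threshold: float
    lower_hz: float
    upper_hz: float


def net_responders(trial: ToneTrial) -> int:
    """Net landings during a tone, floored at zero.

    Males leaving the netting between counts are not treated as
    negative responders.
    """
    return max(trial.landed_during - trial.landed_before, 0)


def normalize_repeat(profiles: list[PhonotacticProfile]) -> list[PhonotacticProfile]:
    """Normalize every profile of one repeat by the repeat-wide maximum.

    The maximum is taken over all tones AND all day/conditions of the
    repeat, so responses on different days of the same cage stay
    comparable. Raises :class:`DegenerateRepeatError` when no tone in
    the whole repeat drew any net responders.
    """
    if not profiles:
        raise InvalidInputError("no profiles given")
    rid = {p.repeat_id for p in profiles}
    if len(rid) != 1:
        raise InvalidInputError(f"profiles span multiple repeats: {sorted(rid)}")
    peak = max(float(p.net_counts.max()) for p in profiles)
    if peak <= 0:
        raise DegenerateRepeatError(
            f"repeat {profiles[0].repeat_id!r} has no responders at any tone"
        )
    return [replace(p, responses=p.net_counts / peak) for p in profiles]


def _responses(profile: PhonotacticProfile) -> np.ndarray:
    if profile.responses is None:
        raise InvalidInputError("profile is not normalized; run normalize_repeat first")
    return np.asarray(profile.responses, dtype=float)


def profile_auc(profile: PhonotacticProfile) -> float:
    """Trapezoidal area under the normalized response curve (Hz units)."""
    resp = _responses(profile)
    freqs = profile.frequencies_hz
    if freqs.size < 2:
        raise InsufficientDataError("AUC requires at least two tones")
    order = np.argsort(freqs)
    return float(np.trapezoid(resp[order], freqs[order]))


def response_range(
    profile: PhonotacticProfile,
    config: SmoothConfig | None = None,
    threshold_frac: float = 0.25,
    grid_step_hz: float = 1.0,
) -> ResponseRange:
    """Frequency range over which the smoothed profile exceeds 25% of peak.

    The loess-fitted profile is evaluated on a fine grid over the tone
    range. Scanning up the left tail, the lower boundary is the last
    grid frequency before which the curve surpasses the threshold;
    scanning down the right tail, the upper boundary is the first
    frequency beyond which it falls below the threshold, minus one grid
    step. A curve that never drops below threshold at an end keeps that
    end of the tone range as its boundary. Peak ties break toward the
    lowest frequency.
    """
    cfg = config or PROFILE_SMOOTH
    resp = _responses(profile)
    freqs = profile.frequencies_hz
    order = np.argsort(freqs)
    freqs, resp = freqs[order], resp[order]
    grid = np.arange(freqs.min(), freqs.max() + grid_step_hz / 2, grid_step_hz)
    fitted = loess_fit(freqs, resp, grid, cfg.span, cfg.degree)
    peak_i = int(np.argmax(fitted))
    peak_val = float(fitted[peak_i])
    if peak_val <= 0:
        raise InvalidInputError("smoothed profile has no positive response")
    peak_hz = float(grid[peak_i])
    thr = threshold_frac * peak_val

    below_left = np.nonzero((grid < peak_hz) & (fitted < thr))[0]
    lower = float(grid[below_left.max()] + grid_step_hz) if below_left.size else float(grid[0])
    below_right = np.nonzero((grid > peak_hz) & (fitted < thr))[0]
    upper = float(grid[below_right.min()] - grid_step_hz) if below_right.size else float(grid[-1])
    return ResponseRange(peak_hz=peak_hz, threshold=thr, lower_hz=lower, upper_hz=upper)


def compare_paired(metric_before: np.ndarray, metric_after: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired per-repeat summaries."""
    x = np.asarray(metric_before, dtype=float)
    y = np.asarray(metric_after, dtype=float)
    if x.size != y.size:
        raise PairingError(f"unpaired lengths {x.size} vs {y.size}")
    if x.size < 5:
        raise InsufficientDataError("paired comparison requires n >= 5 repeats")
    return wilcoxon_signed_rank(x, y)
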