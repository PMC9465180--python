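"""Local regression (loess) smoothing with tricube weights.

The smoother is the classical loess of Cleveland: at every evaluation
point the ``q = floor(span * n)`` nearest observations are fit with a
weighted polynomial (degree 1 or 2), the weights following the tricube
kernel scaled by the distance to the q-th nearest neighbour. The fitted
value at the evaluation point is the polynomial's intercept. No
robustness iterations are applied (Gaussian family), and evaluation is
restricted to the observed data range — the pharmacological time-series
analysis this package serves never extrapolates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ExtrapolationError, InsufficientDataError, InvalidParameterError

__all__ = ["SmoothConfig", "smooth_series", "loess_fit"]


@dataclass(frozen=True)
class SmoothConfig:
    """Loess configuration.

    span
        Fraction of observations entering each local fit, in (0, 1].
    degree
        Local polynomial degree, 1 (linear) or 2 (quadratic).
    eval_step_min
        Grid spacing in minutes used by the injection time-series
        analysis when it builds its evaluation grid.
    """

    span: float = 0.75
    degree: int = 2
    eval_step_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.span <= 1.0):
            raise InvalidParameterError(f"span must be in (0, 1], got {self.span}")
        if self.degree not in (1, 2):
            raise InvalidParameterError(f"degree must be 1 or 2, got {self.degree}")
        if self.eval_step_min <= 0:
            raise InvalidParameterError("eval_step_min must be positive")


def _local_fit(x: np.ndarray, y: np.ndarray, x0: float, q: int, degree: int) -> float:
    dist = np.abs(x - x0)
    h = np.partition(dist, q - 1)[q - 1]
    if h == 0.0:
        # all q nearest points coincide with x0; average them
        return float(y[dist == 0.0].mean())
    w = np.clip(1.0 - (dist / h) ** 3, 0.0, None) ** 3
    mask = w > 0.0
    if mask.sum() < degree + 1:
        # fall back to including the boundary points at zero->tiny weight
        mask = dist <= h
        w = np.where(mask & (w == 0.0), 1e-9, w)
    design = np.vander(x[mask] - x0, degree + 1, increasing=True)
    sw = np.sqrt(w[mask])
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y[mask] * sw, rcond=None)
    return float(beta[0])


def loess_fit(
    x: np.ndarray, y: np.ndarray, eval_x: np.ndarray, span: float, degree: int
) -> np.ndarray:
    """Evaluate a tricube-weighted local polynomial fit of ``y(x)`` at ``eval_x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    eval_x = np.asarray(eval_x, dtype=float)
    n = x.size
    q = int(np.floor(span * n))
    q = min(max(q, degree + 2), n)
    return np.array([_local_fit(x, y, float(xe), q, degree) for xe in eval_x])


def smooth_series(
    times: np.ndarray,
    values: np.ndarray,
    config: SmoothConfig,
    eval_grid: np.ndarray,
) -> list[tuple[float, float]]:
    """Loess-smooth ``values`` over ``times`` and evaluate on ``eval_grid``.

    Returns ``[(t, fitted value), ...]``. The grid must lie within the
    observed time range; points outside raise :class:`ExtrapolationError`
    naming the offenders. Deterministic for fixed inputs.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    eval_grid = np.asarray(eval_grid, dtype=float)
    if times.size != values.size:
        raise InvalidParameterError("times and values must have equal length")
    if times.size < config.degree + 2:
        raise InsufficientDataError(
            f"need at least {config.degree + 2} points for degree {config.degree}, "
            f"got {times.size}"
        )
    lo, hi = times.min(), times.max()
    outside = eval_grid[(eval_grid < lo) | (eval_grid > hi)]
    if outside.size:
        raise ExtrapolationError(
            f"grid points outside data range [{lo:g}, {hi:g}]: {outside.tolist()}"
        )
    fitted = loess_fit(times, values, eval_grid, config.span, config.degree)
    return [(float(t), float(v)) for t, v in zip(eval_grid, fitted)]
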