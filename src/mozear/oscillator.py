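"""Forced damped harmonic-oscillator fits of flagellar velocity spectra.

The mosquito flagellum behaves, to first order, as a forced damped
harmonic oscillator. Its velocity amplitude under broadband (white
noise) acoustic stimulation is modelled as

    v(omega) = A * omega**e / sqrt((omega0**2 - omega**2)**2
                                   + (omega * omega0 / Q)**2)

with ``A = F0/m`` the force-to-mass amplitude ratio, ``omega0`` the
natural angular frequency, ``Q`` the quality factor and ``e`` the
velocity exponent (1 for the textbook velocity response, 2 as commonly
typeset in the mosquito-hearing literature; both are supported and the
extracted best frequency ``f0 = omega0 / (2*pi)`` does not depend on the
choice). Fitting this model to a laser-Doppler-vibrometry velocity
spectrum over the 125-1000 Hz band yields the mechanical tuning (best)
frequency of the ear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    EmptyBandError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    NotConvergedError,
)

__all__ = [
    "VelocitySpectrum",
    "OscillatorParams",
    "OscillatorFit",
    "FitConfig",
    "predict_velocity",
    "band_filter",
    "fit_oscillator",
    "best_frequency",
]

DEFAULT_BAND = (125.0, 1000.0)
F0_BOUNDS = (1e-6, 2000.0)
Q_BOUNDS = (0.1, 50.0)


@dataclass(frozen=True)
class VelocitySpectrum:
    """Velocity amplitude per frequency bin from one white-noise recording."""

    frequencies_hz: np.ndarray
    velocities: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "velocities", v)
        if f.ndim != 1 or v.shape != f.shape:
            raise InvalidInputError("frequencies and velocities must be equal-length 1-D")
        if not np.all(np.isfinite(f)) or not np.all(f > 0):
            raise InvalidInputError("frequencies must be finite and positive")
        if np.any(np.diff(f) <= 0):
            raise InvalidInputError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise InvalidInputError("velocities must be finite and nonnegative")

    def __len__(self) -> int:
        return int(self.frequencies_hz.size)


@dataclass(frozen=True)
class OscillatorParams:
    """Fitted oscillator parameters.

    The damping constant is never stored: gamma = m*omega0/Q, and m is
    not separately identifiable from the spectrum (only A = F0/m is).
    """

    amplitude_ratio: float
    natural_frequency_hz: float
    quality_factor: float
    velocity_exponent: int = 2

    def __post_init__(self) -> None:
        if self.amplitude_ratio <= 0:
            raise InvalidParameterError("amplitude_ratio must be > 0")
        if self.natural_frequency_hz <= 0:
            raise InvalidParameterError("natural_frequency_hz must be > 0")
        if self.quality_factor <= 0:
            raise InvalidParameterError("quality_factor must be > 0")
        if self.velocity_exponent not in (1, 2):
            raise InvalidParameterError("velocity_exponent must be 1 or 2")


@dataclass(frozen=True)
class OscillatorFit:
    params: OscillatorParams | None
    sse: float
    n_points: int
    band_hz: tuple[float, float]
    converged: bool


@dataclass(frozen=True)
class FitConfig:
    """Controls for :func:`fit_oscillator`."""

    band: tuple[float, float] = DEFAULT_BAND
    velocity_exponent: int = 2
    max_iterations: int = 2000
    tolerance: float = 1e-12
    log_loss: bool = False


def predict_velocity(
    params: OscillatorParams, frequencies_hz: np.ndarray
) -> np.ndarray:
    """Model velocity amplitude at the given stimulus frequencies (Hz)."""
    f = np.asarray(frequencies_hz, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise InvalidInputError("frequencies must be positive and finite")
    w = 2.0 * np.pi * f
    w0 = 2.0 * np.pi * params.natural_frequency_hz
    denom = np.sqrt((w0**2 - w**2) ** 2 + (w * w0 / params.quality_factor) ** 2)
    return params.amplitude_ratio * w**params.velocity_exponent / denom


def band_filter(
    spectrum: VelocitySpectrum,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
) -> VelocitySpectrum:
    """Keep only bins with ``low_hz <= f <= high_hz`` (closed interval).

    Bins below 125 Hz are dominated by recording noise in this
    preparation, hence the default band.
    """
    if low_hz >= high_hz:
        raise InvalidParameterError("low_hz must be < high_hz")
    mask = (spectrum.frequencies_hz >= low_hz) & (spectrum.frequencies_hz <= high_hz)
    if not mask.any():
        raise EmptyBandError(f"no frequency bins inside band [{low_hz:g}, {high_hz:g}] Hz")
    return VelocitySpectrum(
        spectrum.frequencies_hz[mask], spectrum.velocities[mask], dict(spectrum.meta)
    )


def _solve_amplitude(f: np.ndarray, v: np.ndarray, f0: float, q: float, e: int) -> float:
    """Closed-form least-squares amplitude given (f0, Q): A = <v,g>/<g,g>."""
    g = predict_velocity(OscillatorParams(1.0, f0, q, e), f)
    gg = float(g @ g)
    if gg == 0.0:
        return 1.0
    return max(float(v @ g) / gg, 1e-30)


def _initial_f0(f: np.ndarray, v: np.ndarray) -> float:
    """Peak of a 5-bin moving-average-smoothed spectrum."""
    if v.size >= 5:
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(v, kernel, mode="same")
    else:
        smooth = v
    return float(f[int(np.argmax(smooth))])


def fit_oscillator(
    spectrum: VelocitySpectrum, fit_config: FitConfig | None = None
) -> OscillatorFit:
    """Least-squares oscillator fit over the configured frequency band.

    Returns ``converged=False`` (never raises) when the optimizer fails,
    the fitted parameters sit on a bound, or the in-band spectrum is
    degenerate (constant). Raises :class:`InsufficientDataError` when
    fewer than 8 bins survive band filtering.
    """
    cfg = fit_config or FitConfig()
    banded = band_filter(spectrum, *cfg.band)
    f = banded.frequencies_hz
    v = banded.velocities
    n = f.size
    if n < 8:
        raise InsufficientDataError(f"only {n} bins inside band {cfg.band}; need >= 8")
    band = (float(cfg.band[0]), float(cfg.band[1]))
    e = cfg.velocity_exponent
    if np.ptp(v) == 0.0:
        return OscillatorFit(None, float(np.sum((v - v.mean()) ** 2)), n, band, False)

    f0_init = float(np.clip(_initial_f0(f, v), F0_BOUNDS[0] * 2, F0_BOUNDS[1] * 0.999))
    q_init = 1.5
    a_init = _solve_amplitude(f, v, f0_init, q_init, e)

    def residuals(x: np.ndarray) -> np.ndarray:
        a, f0, q = np.exp(x[0]), x[1], x[2]
        pred = predict_velocity(OscillatorParams(a, f0, q, e), f)
        if cfg.log_loss:
            return np.log(np.maximum(pred, 1e-300)) - np.log(np.maximum(v, 1e-300))
        return pred - v

    x0 = np.array([np.log(a_init), f0_init, q_init])
    lower = np.array([-np.inf, F0_BOUNDS[0], Q_BOUNDS[0]])
    upper = np.array([np.inf, F0_BOUNDS[1], Q_BOUNDS[1]])
    try:
        res = least_squares(
            residuals,
            x0,
            bounds=(lower, upper),
            xtol=cfg.tolerance,
            ftol=cfg.tolerance,
            gtol=cfg.tolerance,
            max_nfev=cfg.max_iterations,
        )
    except Exception:
        return OscillatorFit(None, float("inf"), n, band, False)

    a_hat, f0_hat, q_hat = float(np.exp(res.x[0])), float(res.x[1]), float(res.x[2])
    pred = predict_velocity(OscillatorParams(a_hat, f0_hat, q_hat, e), f)
    sse = float(np.sum((pred - v) ** 2))
    at_bound = (
        f0_hat <= F0_BOUNDS[0] * 1.001
        or f0_hat >= F0_BOUNDS[1] * 0.999
        or q_hat <= Q_BOUNDS[0] * 1.001
        or q_hat >= Q_BOUNDS[1] * 0.999
    )
    converged = bool(res.success) and not at_bound
    params = OscillatorParams(a_hat, f0_hat, q_hat, e)
    return OscillatorFit(params, sse, n, band, converged)


def best_frequency(fit: OscillatorFit) -> float:
    """Mechanical best frequency f0 = omega0 / (2*pi), in Hz."""
    if not fit.converged or fit.params is None:
        raise NotConvergedError("best_frequency requires a converged fit")
    return fit.params.natural_frequency_hz
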