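"""Seeded synthetic-data generators with recorded ground truth.

Raw recordings behind this kind of study (per-animal vibrometry
spectra, injection time courses, cage-level phonotaxis counts, qPCR
plates, ELISA plates) are rarely deposited, so every pipeline stage
here is validated against synthetic inputs whose generating parameters
are known. Each generator is a pure function of ``(seed, parameters)``
— identical calls reproduce identical data — and returns the generated
object together with a :class:`SyntheticTruth` recording exactly what
went in.

Noise models are the simplest consistent with each measurement type:
lognormal multiplicative noise for velocity spectra (vibrometry noise
scales with signal), additive Gaussian noise for best frequencies and
Ct values, and binomial sampling for landing counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .errors import InvalidParameterError
from .expression import CtRecord, ElisaPlate, StandardCurve, four_pl
from .injection import FrequencyTimeSeries, InjectionExperiment
from .oscillator import OscillatorParams, VelocitySpectrum, predict_velocity
from .phonotaxis import GROUP_SIZE, TONE_SET_HZ, PhonotacticProfile, ToneTrial

__all__ = [
    "SyntheticTruth",
    "gen_spectrum",
    "gen_injection_series",
    "gen_phonotaxis_counts",
    "gen_ct_table",
    "gen_elisa_plate",
]


@dataclass(frozen=True)
class SyntheticTruth:
    generator: str
    seed: int
    parameters: dict[str, Any]


def gen_spectrum(
    seed: int,
    f0_hz: float = 450.0,
    q: float = 1.8,
    amplitude: float = 1.0,
    velocity_exponent: int = 2,
    noise_sigma: float = 0.05,
    grid_hz: np.ndarray | None = None,
    low_freq_noise: float = 0.5,
    meta: dict[str, Any] | None = None,
) -> tuple[VelocitySpectrum, SyntheticTruth]:
    """Oscillator spectrum with multiplicative lognormal noise.

    A noise shelf is added below 125 Hz to mimic the low-frequency
    contamination seen in vibrometry recordings (and to exercise band
    filtering). ``noise_sigma`` is the sigma of the lognormal factor.
    """
    rng = np.random.default_rng(seed)
    f = np.arange(1.0, 2000.0 + 0.5) if grid_hz is None else np.asarray(grid_hz, float)
    params = OscillatorParams(amplitude, f0_hz, q, velocity_exponent)
    clean = predict_velocity(params, f)
    noisy = clean * rng.lognormal(mean=0.0, sigma=noise_sigma, size=f.size) \
        if noise_sigma > 0 else clean.copy()
    shelf_mask = f < 125.0
    if low_freq_noise > 0 and shelf_mask.any():
        scale = low_freq_noise * max(clean.max(), 1e-12)
        noisy[shelf_mask] += scale * rng.random(shelf_mask.sum())
    truth = SyntheticTruth(
        "spectrum", seed,
        {"f0_hz": f0_hz, "q": q, "amplitude": amplitude,
         "velocity_exponent": velocity_exponent, "noise_sigma": noise_sigma,
         "low_freq_noise": low_freq_noise},
    )
    return VelocitySpectrum(f, noisy, meta or {}), truth


def _effect(profile: str, t: np.ndarray, magnitude: float, onset: float,
            decay_tau: float, ramp_duration: float) -> np.ndarray:
    active = t >= onset
    if profile == "step":
        return np.where(active, magnitude, 0.0)
    if profile == "step-decay":
        return np.where(active, magnitude * np.exp(-(t - onset) / decay_tau), 0.0)
    if profile == "ramp":
        frac = np.clip((t - onset) / ramp_duration, 0.0, 1.0)
        return np.where(active, magnitude * frac, 0.0)
    raise InvalidParameterError(f"unknown effect profile {profile!r}")


def gen_injection_series(
    seed: int,
    baseline_hz: float = 450.0,
    effect_hz: float = 75.0,
    effect_profile: str = "step",
    noise_sigma_hz: float = 8.0,
    duration_min: float = 35.0,
    first_compound: str = "serotonin",
    second_compound: str | None = None,
    second_effect_hz: float = 0.0,
    second_injection_time_min: float = 10.0,
    decay_tau_min: float = 30.0,
    ramp_duration_min: float = 35.0,
    sex: str = "male",
) -> tuple[InjectionExperiment, SyntheticTruth]:
    """Injection time course: 3 baseline points, then points every 2-3 min.

    The first injection (at t = 0) shifts tuning by ``effect_hz``
    following the chosen profile (step, step with exponential decay, or
    ramp). A two-injection protocol adds ``second_effect_hz`` as a step
    from the second injection onward (default 10 min after the first,
    sampled for a further 35 min as in the two-injection recordings).
    """
    rng = np.random.default_rng(seed)
    t_base = np.array([-5.0, -3.0, -1.0])
    post_end = duration_min if second_compound is None \
        else second_injection_time_min + 35.0
    times = []
    t = 0.0
    while True:
        t += rng.uniform(2.0, 3.0)
        if t > post_end:
            break
        times.append(t)
    t_post = np.array(times)
    effect = _effect(effect_profile, t_post, effect_hz, 0.0,
                     decay_tau_min, ramp_duration_min)
    if second_compound is not None:
        effect = effect + np.where(
            t_post >= second_injection_time_min, second_effect_hz, 0.0
        )
    all_t = np.concatenate([t_base, t_post])
    noise = rng.normal(0.0, noise_sigma_hz, size=all_t.size) if noise_sigma_hz > 0 \
        else np.zeros(all_t.size)
    freqs = baseline_hz + np.concatenate([np.zeros(3), effect]) + noise
    freqs = np.maximum(freqs, 1.0)
    series = FrequencyTimeSeries(all_t, freqs)
    exp = InjectionExperiment(
        series=series,
        first_compound=first_compound,
        second_compound=second_compound,
        second_injection_time_min=(
            second_injection_time_min if second_compound is not None else None
        ),
        sex=sex,
    )
    truth = SyntheticTruth(
        "injection", seed,
        {"baseline_hz": baseline_hz, "effect_hz": effect_hz,
         "effect_profile": effect_profile, "noise_sigma_hz": noise_sigma_hz,
         "second_compound": second_compound, "second_effect_hz": second_effect_hz,
         "second_injection_time_min": second_injection_time_min},
    )
    return exp, truth


def gen_phonotaxis_counts(
    seed: int,
    n_repeats: int = 10,
    center_hz: float = 625.0,
    sd_hz: float = 75.0,
    p_max: float = 0.6,
    pre_landed_rate: float = 0.02,
    day_conditions: tuple[str, ...] = ("glucose-day0",),
    condition_scale: dict[str, float] | None = None,
) -> tuple[list[PhonotacticProfile], SyntheticTruth]:
    """Cage-level phonotaxis counts from a Gaussian tone-preference curve.

    Each of the 17 tones draws ``Binomial(30, p(f))`` responders with
    ``p(f) = p_max * exp(-(f - center)^2 / (2 sd^2))``, optionally
    scaled per day/condition (emulating e.g. reduced responsiveness
    after drug-doped feeding). Pre-landed counts are small binomials
    subtracted before normalization, as in the assay's scoring rule.
    """
    if not (0.0 <= p_max <= 1.0):
        raise InvalidParameterError("p_max must be in [0, 1]")
    rng = np.random.default_rng(seed)
    scales = condition_scale or {}
    tones = np.array(TONE_SET_HZ, dtype=float)
    profiles = []
    for r in range(n_repeats):
        for cond in day_conditions:
            scale = scales.get(cond, 1.0)
            p = scale * p_max * np.exp(-((tones - center_hz) ** 2) / (2 * sd_hz**2))
            p = np.clip(p, 0.0, 1.0)
            during = rng.binomial(GROUP_SIZE, p)
            before = rng.binomial(GROUP_SIZE, pre_landed_rate, size=tones.size)
            trials = tuple(
                ToneTrial(float(f), int(b), int(min(d + b, GROUP_SIZE)))
                for f, b, d in zip(tones, before, during)
            )
            profiles.append(PhonotacticProfile(f"cage{r:02d}", cond, trials))
    truth = SyntheticTruth(
        "phonotaxis", seed,
        {"n_repeats": n_repeats, "center_hz": center_hz, "sd_hz": sd_hz,
         "p_max": p_max, "pre_landed_rate": pre_landed_rate,
         "day_conditions": list(day_conditions),
         "condition_scale": dict(scales)},
    )
    return profiles, truth


def gen_ct_table(
    seed: int,
    true_folds: dict[str, dict[str, float]] | None = None,
    n_repeats: int = 7,
    sex: str = "male",
    rps7_ct: float = 20.0,
    head_delta_ct: float = 6.0,
    noise_sigma_ct: float = 0.05,
) -> tuple[list[CtRecord], SyntheticTruth]:
    """Triplicate Ct table with known fold expression per gene and tissue.

    ``true_folds[gene][tissue]`` is the fold expression relative to
    head (head implicitly 1). Gene Ct in a tissue is the housekeeping
    level plus the head dCt minus log2(fold), plus technical noise —
    so the ddCt pipeline should recover ``fold`` up to noise.
    """
    folds = true_folds or {"5-HT7": {"JO": 4.0, "body": 1.0}}
    for gene, per_tissue in folds.items():
        for tissue, fold in per_tissue.items():
            if fold <= 0:
                raise InvalidParameterError(f"fold for {gene}/{tissue} must be > 0")
    rng = np.random.default_rng(seed)
    tissues = ["head"] + sorted({t for per in folds.values() for t in per})
    records = []
    for rep in range(1, n_repeats + 1):
        for tissue in tissues:
            rps7_noise = rng.normal(0, noise_sigma_ct, 3) if noise_sigma_ct > 0 else np.zeros(3)
            records.append(CtRecord(sex, rep, tissue, "rps7",
                                    tuple(rps7_ct + rps7_noise)))
            for gene, per_tissue in folds.items():
                fold = 1.0 if tissue == "head" else per_tissue.get(tissue, 1.0)
                true_ct = rps7_ct + head_delta_ct - np.log2(fold)
                noise = rng.normal(0, noise_sigma_ct, 3) if noise_sigma_ct > 0 else np.zeros(3)
                records.append(CtRecord(sex, rep, tissue, gene, tuple(true_ct + noise)))
    truth = SyntheticTruth(
        "ct_table", seed,
        {"true_folds": folds, "n_repeats": n_repeats, "rps7_ct": rps7_ct,
         "head_delta_ct": head_delta_ct, "noise_sigma_ct": noise_sigma_ct},
    )
    return records, truth


# Standards sit within about one decade either side of the IC50 (c):
# outside that window the 4PL is nearly flat and read noise cannot be
# inverted into concentration with useful precision.
DEFAULT_4PL = StandardCurve(a=2.0, b=1.3, c=45.0, d=0.05,
                            converged=True, max_backcalc_error=0.0)
DEFAULT_STANDARDS_NG_ML = (7.5, 18.0, 45.0, 112.0, 270.0)


def gen_elisa_plate(
    seed: int,
    sample_concentrations_ng_ml: dict[str, float] | None = None,
    curve: StandardCurve = DEFAULT_4PL,
    standards_ng_ml: tuple[float, ...] = DEFAULT_STANDARDS_NG_ML,
    noise_sigma_abs: float = 0.01,
    a620: float = 0.04,
    dilution_factor: float = 0.1,
) -> tuple[ElisaPlate, SyntheticTruth]:
    """ELISA plate: 4PL standard responses plus diluted samples.

    ``sample_concentrations_ng_ml`` holds the *undiluted* truths; the
    plate sees each sample at ``dilution_factor`` times that
    concentration, mirroring the 0.1x homogenate dilution that the
    quantification step corrects by x10.
    """
    rng = np.random.default_rng(seed)
    samples_truth = sample_concentrations_ng_ml or {"ringer-1": 120.0, "amtp-1": 60.0}

    def absorb(conc: float) -> tuple[float, float]:
        corrected = float(four_pl(np.array([conc]), curve.a, curve.b, curve.c, curve.d)[0])
        noise = rng.normal(0.0, noise_sigma_abs) if noise_sigma_abs > 0 else 0.0
        return corrected + a620 + noise, a620

    standards = tuple((c, *absorb(c)) for c in standards_ng_ml)
    samples = tuple(
        (sid, *absorb(conc * dilution_factor)) for sid, conc in samples_truth.items()
    )
    plate = ElisaPlate(standards=standards, samples=samples,
                       dilution_factor=dilution_factor)
    truth = SyntheticTruth(
        "elisa", seed,
        {"samples_ng_ml": dict(samples_truth),
         "curve": {"a": curve.a, "b": curve.b, "c": curve.c, "d": curve.d},
         "standards_ng_ml": list(standards_ng_ml),
         "noise_sigma_abs": noise_sigma_abs, "dilution_factor": dilution_factor},
    )
    return plate, truth
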