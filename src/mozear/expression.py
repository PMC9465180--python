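"""Relative transcript quantification and ELISA serotonin quantification.

qPCR side: technical triplicate Ct values are collapsed to their
median; ``dCt = Ct_gene - Ct_rps7`` within each (sex, repeat, tissue)
group normalizes against the housekeeping gene; ``ddCt = dCt_tissue -
dCt_head`` within each (sex, repeat, gene) group references expression
to head tissue, so every head sample has ddCt = 0 and fold expression
``2**(-ddCt)`` = 1. Fold assumes 100% amplification efficiency.

ELISA side: plate absorbance is read at 450 nm with 620 nm as
reference; a four-parameter logistic (4PL) standard curve maps
corrected absorbance to serotonin concentration (ng/ml), and sample
estimates are divided by the dilution factor (x10 at the 0.1x dilution
used for mosquito homogenates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    FitQualityError,
    InsufficientDataError,
    InvalidInputError,
    MissingReferenceError,
    NotConvergedError,
)

__all__ = [
    "CtRecord",
    "ElisaPlate",
    "StandardCurve",
    "collapse_technical",
    "collapse_ct_table",
    "delta_ct",
    "delta_delta_ct",
    "four_pl",
    "inverse_four_pl",
    "fit_standard_curve",
    "quantify_samples",
    "REFERENCE_GENE",
    "REFERENCE_TISSUE",
]

REFERENCE_GENE = "rps7"
REFERENCE_TISSUE = "head"
TISSUES = ("JO", "head", "body")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well triplet: sex / repeat / tissue / gene with 3 technical Cts."""

    sex: str
    repeat: int
    tissue: str
    gene: str
    technical_cts: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.technical_cts) != 3:
            raise InvalidInputError("exactly 3 technical Ct values expected")


def collapse_technical(record: CtRecord, missing_policy: str = "error") -> float:
    """Median of the technical triplicate.

    ``missing_policy="mean2"`` averages the remaining two values when
    exactly one Ct is missing/non-finite; the default raises.
    """
    cts = np.asarray(record.technical_cts, dtype=float)
    finite = cts[np.isfinite(cts)]
    if finite.size < 3:
        if missing_policy == "mean2" and finite.size == 2:
            return float(finite.mean())
        raise InvalidInputError(
            f"non-finite technical Ct in {record.gene}/{record.tissue}: {record.technical_cts}"
        )
    if np.any(finite <= 0) or np.any(finite >= 45):
        raise InvalidInputError(f"Ct values outside (0, 45): {record.technical_cts}")
    return float(np.median(finite))


def collapse_ct_table(records: list[CtRecord], missing_policy: str = "error") -> pd.DataFrame:
    """Collapse a list of CtRecords to a tidy table with one ct per row."""
    rows = [
        {
            "sex": r.sex,
            "repeat": r.repeat,
            "tissue": r.tissue,
            "gene": r.gene,
            "ct": collapse_technical(r, missing_policy),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def delta_ct(table: pd.DataFrame, reference_gene: str = REFERENCE_GENE) -> pd.DataFrame:
    """dCt = Ct_gene - Ct_reference within each (sex, repeat, tissue) group."""
    required = {"sex", "repeat", "tissue", "gene", "ct"}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"collapsed Ct table must have columns {sorted(required)}")
    out = []
    for (sex, rep, tissue), grp in table.groupby(["sex", "repeat", "tissue"], sort=True):
        ref = grp.loc[grp["gene"] == reference_gene, "ct"]
        if ref.empty:
            raise MissingReferenceError(
                f"no {reference_gene} row in group sex={sex}, repeat={rep}, tissue={tissue}"
            )
        ref_ct = float(ref.median())
        genes = grp[grp["gene"] != reference_gene]
        for _, row in genes.iterrows():
            out.append(
                {
                    "sex": sex,
                    "repeat": rep,
                    "tissue": tissue,
                    "gene": row["gene"],
                    "delta_ct": float(row["ct"]) - ref_ct,
                }
            )
    return pd.DataFrame(out)


def delta_delta_ct(
    dct_table: pd.DataFrame, reference_tissue: str = REFERENCE_TISSUE
) -> pd.DataFrame:
    """ddCt against the reference tissue; fold = 2**(-ddCt).

    Head rows (the reference) get ddCt = 0 and fold = 1 by construction.
    """
    out = []
    for (sex, rep, gene), grp in dct_table.groupby(["sex", "repeat", "gene"], sort=True):
        ref = grp.loc[grp["tissue"] == reference_tissue, "delta_ct"]
        if ref.empty:
            raise MissingReferenceError(
                f"no {reference_tissue} dCt in group sex={sex}, repeat={rep}, gene={gene}"
            )
        ref_dct = float(ref.iloc[0])
        for _, row in grp.iterrows():
            ddct = float(row["delta_ct"]) - ref_dct
            if row["tissue"] == reference_tissue:
                ddct = 0.0
            out.append(
                {
                    "sex": sex,
                    "repeat": rep,
                    "tissue": row["tissue"],
                    "gene": gene,
                    "delta_ct": float(row["delta_ct"]),
                    "delta_delta_ct": ddct,
                    "fold": float(2.0 ** (-ddct)),
                }
            )
    return pd.DataFrame(out)


# --- ELISA ---------------------------------------------------------------


@dataclass(frozen=True)
class ElisaPlate:
    """Standards and samples from one ELISA plate.

    standards: list of (known concentration ng/ml, abs450, abs620)
    samples:   list of (sample id, abs450, abs620)
    """

    standards: tuple[tuple[float, float, float], ...]
    samples: tuple[tuple[str, float, float], ...]
    dilution_factor: float = 0.1

    def __post_init__(self) -> None:
        concs = [s[0] for s in self.standards]
        if len(set(concs)) < 4:
            raise InsufficientDataError("need >= 4 standards with distinct concentrations")
        if self.dilution_factor <= 0:
            raise InvalidInputError("dilution_factor must be positive")


@dataclass(frozen=True)
class StandardCurve:
    """4PL curve y = d + (a - d) / (1 + (x / c)**b) on corrected absorbance."""

    a: float  # response at zero concentration
    b: float  # slope (negative for a competitive, decreasing curve)
    c: float  # inflection concentration (IC50)
    d: float  # response at infinite concentration
    converged: bool
    max_backcalc_error: float


def four_pl(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


def inverse_four_pl(y: np.ndarray, curve: StandardCurve) -> np.ndarray:
    """Back-calculate concentration from corrected absorbance; NaN when outside range."""
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (curve.a - curve.d) / (y - curve.d) - 1.0
        x = curve.c * np.where(ratio > 0, ratio, np.nan) ** (1.0 / curve.b)
    return x


def fit_standard_curve(
    standards: tuple[tuple[float, float, float], ...],
    backcalc_gate: float = 0.15,
) -> StandardCurve:
    """Fit the 4PL standard curve on blank-corrected absorbance.

    The fit is gated on back-calculation: every standard's estimated
    concentration must lie within ``backcalc_gate`` (relative) of its
    nominal value, otherwise a :class:`FitQualityError` is raised.
    """
    conc = np.array([s[0] for s in standards], dtype=float)
    resp = np.array([s[1] - s[2] for s in standards], dtype=float)
    if np.unique(conc).size < 4:
        raise InsufficientDataError("need >= 4 distinct standard concentrations")
    order = np.argsort(conc)
    trend = np.diff(resp[order])
    if not (np.all(trend <= 0) or np.all(trend >= 0)):
        # allow mild noise: require a dominant monotone direction
        if abs(trend.sum()) < 0.5 * np.abs(trend).sum():
            raise FitQualityError("standard responses are not monotone in concentration")
    decreasing = resp[order][-1] < resp[order][0]
    a0, d0 = (resp.max(), resp.min()) if decreasing else (resp.min(), resp.max())
    b0 = 1.0 if decreasing else -1.0
    c0 = float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0
    try:
        popt, _ = curve_fit(
            four_pl, conc, resp, p0=[a0, b0, c0, d0],
            maxfev=20000,
            bounds=([-np.inf, -50, 1e-9, -np.inf], [np.inf, 50, np.inf, np.inf]),
        )
    except RuntimeError as exc:
        raise NotConvergedError(f"4PL fit did not converge: {exc}") from exc
    curve = StandardCurve(*map(float, popt), converged=True, max_backcalc_error=np.nan)
    back = inverse_four_pl(resp, curve)
    pos = conc > 0
    rel = np.abs(back[pos] - conc[pos]) / conc[pos]
    max_err = float(np.nanmax(rel)) if rel.size else 0.0
    if not np.all(np.isfinite(back[pos])) or max_err > backcalc_gate:
        raise FitQualityError(
            f"standard back-calculation error {max_err:.3f} exceeds gate {backcalc_gate}"
        )
    return StandardCurve(curve.a, curve.b, curve.c, curve.d, True, max_err)


def quantify_samples(plate: ElisaPlate, curve: StandardCurve) -> pd.DataFrame:
    """Concentration per sample (ng/ml), corrected for the plate dilution.

    Samples whose corrected absorbance falls outside the curve's
    invertible range are reported with NaN concentration and a censored
    flag rather than dropped.
    """
    if not curve.converged:
        raise NotConvergedError("standard curve did not converge")
    rows = []
    for sample_id, a450, a620 in plate.samples:
        corrected = a450 - a620
        est = float(inverse_four_pl(np.array([corrected]), curve)[0])
        censored = not np.isfinite(est)
        value = est / plate.dilution_factor if not censored else np.nan
        rows.append(
            {
                "sample_id": sample_id,
                "corrected_absorbance": corrected,
                "concentration_ng_ml": value,
                "censored": censored,
            }
        )
    return pd.DataFrame(rows)
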