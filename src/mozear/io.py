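"""CSV readers/writers for the pipeline's tabular interchange formats.

Schemas
-------
spectrum:   frequency_hz,velocity (one file per recording; optional
            sidecar JSON with animal_id/sex/label metadata)
series:     animal_id,time_min,frequency_hz
series meta: animal_id,sex,compound1,compound2,t2_min
trials:     repeat_id,day_condition,frequency_hz,landed_before,landed_during
ct:         sex,repeat,tissue,gene,ct1,ct2,ct3
elisa:      role,id,concentration_ng_ml,abs450,abs620
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .expression import CtRecord, ElisaPlate
from .injection import FrequencyTimeSeries, InjectionExperiment
from .oscillator import VelocitySpectrum
from .phonotaxis import PhonotacticProfile, ToneTrial

FLOAT_FORMAT = "%.6g"  # fixed precision so re-runs are byte-identical


def read_spectrum(path: str | Path) -> VelocitySpectrum:
    path = Path(path)
    df = pd.read_csv(path)
    _require(df, {"frequency_hz", "velocity"}, path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return VelocitySpectrum(df["frequency_hz"].to_numpy(),
                            df["velocity"].to_numpy(), meta)


def write_spectrum(spectrum: VelocitySpectrum, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"frequency_hz": spectrum.frequencies_hz, "velocity": spectrum.velocities}
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if spectrum.meta:
        path.with_suffix(".json").write_text(json.dumps(spectrum.meta, indent=1))


def read_experiments(series_path: str | Path, meta_path: str | Path) -> list[InjectionExperiment]:
    series = pd.read_csv(series_path)
    meta = pd.read_csv(meta_path)
    _require(series, {"animal_id", "time_min", "frequency_hz"}, series_path)
    _require(meta, {"animal_id", "sex", "compound1"}, meta_path)
    out = []
    for _, row in meta.iterrows():
        sub = series[series["animal_id"] == row["animal_id"]].sort_values("time_min")
        if sub.empty:
            raise InvalidInputError(f"no series rows for animal {row['animal_id']!r}")
        second = row.get("compound2")
        has_second = isinstance(second, str) and second != ""
        out.append(
            InjectionExperiment(
                series=FrequencyTimeSeries(sub["time_min"].to_numpy(),
                                           sub["frequency_hz"].to_numpy()),
                first_compound=str(row["compound1"]),
                second_compound=str(second) if has_second else None,
                second_injection_time_min=float(row["t2_min"]) if has_second else None,
                sex=str(row["sex"]),
            )
        )
    return out


def write_experiments(
    experiments: list[InjectionExperiment],
    animal_ids: list[str],
    series_path: str | Path,
    meta_path: str | Path,
) -> None:
    srows, mrows = [], []
    for aid, exp in zip(animal_ids, experiments):
        for t, f in zip(exp.series.times_min, exp.series.frequencies_hz):
            srows.append({"animal_id": aid, "time_min": t, "frequency_hz": f})
        mrows.append(
            {
                "animal_id": aid,
                "sex": exp.sex,
                "compound1": exp.first_compound,
                "compound2": exp.second_compound or "",
                "t2_min": exp.second_injection_time_min
                if exp.second_injection_time_min is not None else "",
            }
        )
    pd.DataFrame(srows).to_csv(series_path, index=False, float_format=FLOAT_FORMAT)
    pd.DataFrame(mrows).to_csv(meta_path, index=False, float_format=FLOAT_FORMAT)


def read_trials(path: str | Path) -> list[PhonotacticProfile]:
    df = pd.read_csv(path)
    _require(df, {"repeat_id", "day_condition", "frequency_hz",
                  "landed_before", "landed_during"}, path)
    profiles = []
    for (rid, cond), grp in df.groupby(["repeat_id", "day_condition"], sort=True):
        trials = tuple(
            ToneTrial(float(r["frequency_hz"]), int(r["landed_before"]),
                      int(r["landed_during"]))
            for _, r in grp.sort_values("frequency_hz").iterrows()
        )
        profiles.append(PhonotacticProfile(str(rid), str(cond), trials))
    return profiles


def write_trials(profiles: list[PhonotacticProfile], path: str | Path) -> None:
    rows = [
        {
            "repeat_id": p.repeat_id,
            "day_condition": p.day_condition,
            "frequency_hz": t.frequency_hz,
            "landed_before": t.landed_before,
            "landed_during": t.landed_during,
        }
        for p in profiles
        for t in p.trials
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_ct_table(path: str | Path) -> list[CtRecord]:
    df = pd.read_csv(path)
    _require(df, {"sex", "repeat", "tissue", "gene", "ct1", "ct2", "ct3"}, path)
    return [
        CtRecord(str(r["sex"]), int(r["repeat"]), str(r["tissue"]), str(r["gene"]),
                 (float(r["ct1"]), float(r["ct2"]), float(r["ct3"])))
        for _, r in df.iterrows()
    ]


def write_ct_table(records: list[CtRecord], path: str | Path) -> None:
    rows = [
        {"sex": r.sex, "repeat": r.repeat, "tissue": r.tissue, "gene": r.gene,
         "ct1": r.technical_cts[0], "ct2": r.technical_cts[1], "ct3": r.technical_cts[2]}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_elisa_plate(path: str | Path, dilution_factor: float = 0.1) -> ElisaPlate:
    df = pd.read_csv(path)
    _require(df, {"role", "id", "concentration_ng_ml", "abs450", "abs620"}, path)
    std = df[df["role"] == "standard"]
    smp = df[df["role"] == "sample"]
    return ElisaPlate(
        standards=tuple(
            (float(r["concentration_ng_ml"]), float(r["abs450"]), float(r["abs620"]))
            for _, r in std.iterrows()
        ),
        samples=tuple(
            (str(r["id"]), float(r["abs450"]), float(r["abs620"]))
            for _, r in smp.iterrows()
        ),
        dilution_factor=dilution_factor,
    )


def write_elisa_plate(plate: ElisaPlate, path: str | Path) -> None:
    rows = [
        {"role": "standard", "id": f"std-{i}", "concentration_ng_ml": c,
         "abs450": a450, "abs620": a620}
        for i, (c, a450, a620) in enumerate(plate.standards)
    ] + [
        {"role": "sample", "id": sid, "concentration_ng_ml": np.nan,
         "abs450": a450, "abs620": a620}
        for sid, a450, a620 in plate.samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _require(df: pd.DataFrame, cols: set[str], path: str | Path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
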