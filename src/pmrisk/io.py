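"""Table, spectrum and configuration file formats.

Plain delimiter-separated text throughout: campaign tables with ISO dates
and a units comment line, two-column spectrum files with a small key-value
header, age-group and risk-constant tables with documented columns, and a
YAML run configuration. Loading validates: unknown analyte columns and
negative concentrations are rejected with the offending name/row.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .epr import EPRSpectrum
from .risk import AgeGroupParams, RiskConstants
from .synthetic import CampaignSample

__all__ = [
    "ANALYTE_UNITS",
    "MET_COLUMNS",
    "RunConfig",
    "save_campaign",
    "load_campaign",
    "save_spectrum",
    "load_spectrum",
    "save_age_table",
    "load_age_table",
    "save_risk_constants",
    "load_risk_constants",
    "load_run_config",
    "save_run_config",
]

#: accepted analyte columns and their units
ANALYTE_UNITS: dict[str, str] = {
    "SCCP": "pg/m3",
    "MCCP": "pg/m3",
    "LCCP": "pg/m3",
    "CPs": "pg/m3",
    "EPFR": "spins/m3",
    "PM2.5": "ug/m3",
    "PM10": "ug/m3",
    "SO2": "ug/m3",
    "NO2": "ug/m3",
    "O3": "ug/m3",
    "CO": "mg/m3",
}
MET_COLUMNS: dict[str, str] = {
    "TEMP": "degC",
    "RH": "%",
    "WS": "m/s",
    "WD": "deg",
    "SUN": "h",
}


def save_campaign(samples: Sequence[CampaignSample], path: str | Path) -> Path:
    """Write the campaign as CSV with ISO-8601 dates and a units header line."""
    path = Path(path)
    rows = [{"date": s.date.isoformat(), **s.conc, **s.met} for s in samples]
    frame = pd.DataFrame(rows)
    units = ["date=ISO-8601"]
    for col in frame.columns:
        if col in ANALYTE_UNITS:
            units.append(f"{col}={ANALYTE_UNITS[col]}")
        elif col in MET_COLUMNS:
            units.append(f"{col}={MET_COLUMNS[col]}")
    with open(path, "w") as fh:
        fh.write("# units: " + ", ".join(units) + "\n")
        frame.to_csv(fh, index=False)
    return path


def load_campaign(path: str | Path) -> list[CampaignSample]:
    """Read a campaign CSV back into typed, validated samples.

    Unknown columns raise with the accepted names listed; a negative
    concentration raises with its row number. Missing cells stay as explicit
    NaN gaps.
    """
    frame = pd.read_csv(path, comment="#")
    if "date" not in frame.columns:
        raise ValueError("campaign table must have a 'date' column")
    known = set(ANALYTE_UNITS) | set(MET_COLUMNS)
    unknown = [c for c in frame.columns if c != "date" and c not in known]
    if unknown:
        raise ValueError(
            f"unknown columns {unknown}; accepted analytes: {sorted(ANALYTE_UNITS)}, "
            f"meteorology: {sorted(MET_COLUMNS)}"
        )
    analyte_cols = [c for c in frame.columns if c in ANALYTE_UNITS]
    for col in analyte_cols:
        neg = frame.index[frame[col] < 0]
        if len(neg):
            raise ValueError(
                f"negative {col} concentration at row {int(neg[0])}"
            )
    samples = []
    for _, row in frame.iterrows():
        conc = {c: float(row[c]) for c in analyte_cols if pd.notna(row[c])}
        met = {c: float(row[c]) for c in MET_COLUMNS if c in frame.columns and pd.notna(row[c])}
        samples.append(
            CampaignSample(date=dt.date.fromisoformat(str(row["date"])), conc=conc, met=met)
        )
    return samples


def save_spectrum(spec: EPRSpectrum, path: str | Path) -> Path:
    """Two-column (field mT, intensity) text file with a key-value header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# freq_GHz: {spec.freq_GHz!r}\n")
        fh.write(f"# punch_area_cm2: {spec.punch_area_cm2!r}\n")
        fh.write(f"# n_punches: {spec.n_punches}\n")
        fh.write(f"# filter_exposed_area_cm2: {spec.filter_exposed_area_cm2!r}\n")
        fh.write(f"# air_volume_m3: {spec.air_volume_m3!r}\n")
        fh.write("field_mT\tintensity\n")
        for b, y in zip(spec.field_mT, spec.intensity):
            fh.write(f"{float(b)!r}\t{float(y)!r}\n")
    return path


def load_spectrum(path: str | Path) -> EPRSpectrum:
    """Inverse of :func:`save_spectrum`."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = float(val)
        else:
            data_start = i
            break
    body = [ln.split() for ln in lines[data_start + 1 :] if ln.strip()]
    arr = np.array(body, dtype=float)
    return EPRSpectrum(
        field_mT=arr[:, 0],
        intensity=arr[:, 1],
        freq_GHz=meta["freq_GHz"],
        punch_area_cm2=meta.get("punch_area_cm2", C.DEFAULT_PUNCH_AREA_CM2),
        n_punches=int(meta.get("n_punches", C.DEFAULT_N_PUNCHES)),
        filter_exposed_area_cm2=meta.get(
            "filter_exposed_area_cm2", C.DEFAULT_FILTER_EXPOSED_AREA_CM2
        ),
        air_volume_m3=meta.get("air_volume_m3", C.DEFAULT_AIR_VOLUME_M3),
    )


def save_age_table(groups: Sequence[AgeGroupParams], path: str | Path) -> Path:
    """Exposure-factor table: label, IR m3/day, BW kg, T day-fraction."""
    path = Path(path)
    frame = pd.DataFrame(
        [{"label": g.label, "IR_m3_day": g.IR, "BW_kg": g.BW, "T_fraction": g.T} for g in groups]
    )
    with open(path, "w") as fh:
        fh.write("# units: IR_m3_day=m3/day, BW_kg=kg, T_fraction=day fraction outdoors\n")
        frame.to_csv(fh, index=False)
    return path


def load_age_table(path: str | Path) -> list[AgeGroupParams]:
    frame = pd.read_csv(path, comment="#")
    required = {"label", "IR_m3_day", "BW_kg", "T_fraction"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"age table missing columns: {sorted(missing)}")
    return [
        AgeGroupParams(
            label=str(r["label"]), IR=float(r["IR_m3_day"]),
            BW=float(r["BW_kg"]), T=float(r["T_fraction"]),
        )
        for _, r in frame.iterrows()
    ]


def save_risk_constants(constants: RiskConstants, path: str | Path) -> Path:
    """Name/value table of the toxicological and cigarette constants."""
    path = Path(path)
    rows = [
        ("tdi_ug_per_kg_day", constants.tdi_ug_per_kg_day),
        ("rc_cig_spins_per_g", constants.rc_cig_spins_per_g),
        ("tar_g_per_cigarette", constants.tar_g_per_cigarette),
    ] + [(f"noael_mg_per_kg_day_{k}", v) for k, v in constants.noael_mg_per_kg_day.items()]
    with open(path, "w") as fh:
        fh.write("# units: as per name suffix (ug/kg/day, mg/kg/day, spins/g, g)\n")
        pd.DataFrame(rows, columns=["name", "value"]).to_csv(fh, index=False)
    return path


def load_risk_constants(path: str | Path) -> RiskConstants:
    frame = pd.read_csv(path, comment="#").set_index("name")["value"]
    prefix = "noael_mg_per_kg_day_"
    noael = {
        name[len(prefix):]: float(v) for name, v in frame.items() if name.startswith(prefix)
    }
    return RiskConstants(
        tdi_ug_per_kg_day=float(frame["tdi_ug_per_kg_day"]),
        noael_mg_per_kg_day=noael,
        rc_cig_spins_per_g=float(frame["rc_cig_spins_per_g"]),
        tar_g_per_cigarette=float(frame["tar_g_per_cigarette"]),
    )


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration (see :func:`pmrisk.report.run_report`)."""

    out_dir: str = "pmrisk_output"
    seed: int = 0
    n_days: int = 104
    campaign_path: str | None = None  # load instead of generate when set
    age_table_path: str | None = None
    constants_path: str | None = None
    mmad_um: float = 1.0
    size_gsd: float = 1.0
    pmf_k: int = 5
    pmf_n_starts: int = 10
    pmf_K_cp: float = 0.10  # CPs, EPFR relative uncertainty
    pmf_K_pollutant: float = 0.15  # regulated pollutants
    mc_n_iter: int = 10_000
    n_epr_samples: int = 10
    epr_noise_snr: float = 50.0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        for p in (self.campaign_path, self.age_table_path, self.constants_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def save_run_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return path


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)
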