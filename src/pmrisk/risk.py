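"""Inhalation risk metrics for PM2.5-bound chlorinated paraffins and radicals.

Five metrics, all linear in the airborne concentration:

* EDI  = C * IR * T / BW        estimated daily intake, pg/kg bw/day
* HQ   = EDI / TDI              hazard quotient (TDI converted to pg)
* MOE  = NOAEL / EDI            margin of exposure (NOAEL converted to pg)
* DED  = RC * IR * EF / BW      daily radical dose, spins/kg bw/day (EF = T)
* EQ   = RC * IR / (RC_cig * C_tar)   cigarette equivalents per day
        (deliberately has no body-weight or outdoor-time term)

Regional (head airway / tracheobronchial / alveolar) variants are the
whole-body values scaled by the ICRP deposition fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import constants as C
from .deposition import DepositionFractions

__all__ = [
    "AgeGroupParams",
    "RiskConstants",
    "default_age_groups",
    "edi",
    "hq",
    "moe",
    "ded",
    "eq_cigarettes",
    "apply_deposition",
    "assess_campaign",
    "MOE_HIGH_RISK_THRESHOLD",
]

#: MOE values below this are conventionally flagged as high risk.
MOE_HIGH_RISK_THRESHOLD = 1000.0

REGIONS = ("HA", "TB", "AR")


@dataclass(frozen=True)
class AgeGroupParams:
    """Exposure factors for one life-stage group.

    IR: long-term inhalation rate, m3/day. BW: body weight, kg.
    T: fraction of the day spent outdoors (the exposure fraction EF).
    """

    label: str
    IR: float
    BW: float
    T: float

    def __post_init__(self) -> None:
        if not 0 < self.IR <= 40:
            raise ValueError(f"{self.label}: IR={self.IR} outside (0, 40] m3/day")
        if not 1 < self.BW <= 200:
            raise ValueError(f"{self.label}: BW={self.BW} outside (1, 200] kg")
        if not 0 <= self.T <= 1:
            raise ValueError(f"{self.label}: T={self.T} outside [0, 1]")


@dataclass(frozen=True)
class RiskConstants:
    """Toxicological and cigarette-benchmark reference values."""

    tdi_ug_per_kg_day: float = C.TDI_UG_PER_KG_DAY
    noael_mg_per_kg_day: Mapping[str, float] = field(
        default_factory=lambda: dict(C.NOAEL_MG_PER_KG_DAY)
    )
    rc_cig_spins_per_g: float = C.RC_CIGARETTE_SPINS_PER_G
    tar_g_per_cigarette: float = C.TAR_G_PER_CIGARETTE

    def __post_init__(self) -> None:
        if self.tdi_ug_per_kg_day <= 0:
            raise ValueError("TDI must be positive")
        if self.rc_cig_spins_per_g <= 0 or self.tar_g_per_cigarette <= 0:
            raise ValueError("cigarette constants must be positive")
        if any(v <= 0 for v in self.noael_mg_per_kg_day.values()):
            raise ValueError("NOAELs must be positive")

    @property
    def spins_per_cigarette(self) -> float:
        return self.rc_cig_spins_per_g * self.tar_g_per_cigarette


def default_age_groups() -> list[AgeGroupParams]:
    """The shipped 17-group exposure-factor table (replaceable defaults)."""
    return [AgeGroupParams(*row) for row in C.DEFAULT_AGE_GROUPS]


def _check_17(age_groups: Sequence[AgeGroupParams]) -> None:
    labels = [g.label for g in age_groups]
    if len(labels) != 17 or len(set(labels)) != 17:
        raise ValueError(f"expected 17 unique age groups, got {len(labels)}")


def edi(conc_pg_m3: float, p: AgeGroupParams) -> float:
    """Estimated daily intake, pg/kg bw/day."""
    if conc_pg_m3 < 0:
        raise ValueError("concentration must be nonnegative")
    if p.BW <= 0:
        raise ValueError("body weight must be positive")
    return conc_pg_m3 * p.IR * p.T / p.BW


def hq(edi_pg_kg_day: float, constants: RiskConstants | None = None) -> float:
    """Hazard quotient: EDI over the tolerable daily intake (unitless)."""
    constants = constants or RiskConstants()
    tdi_pg = constants.tdi_ug_per_kg_day * C.PG_PER_UG
    if tdi_pg <= 0:
        raise ValueError("TDI must be positive")
    return edi_pg_kg_day / tdi_pg


def moe(
    edi_pg_kg_day: float,
    analyte_class: str,
    constants: RiskConstants | None = None,
) -> tuple[float, bool]:
    """Margin of exposure and a high-risk flag (MOE < 1000).

    A zero intake yields an infinite MOE, flagged as non-risk but reported
    as ``math.inf`` rather than hidden.
    """
    constants = constants or RiskConstants()
    try:
        noael_pg = constants.noael_mg_per_kg_day[analyte_class] * C.PG_PER_MG
    except KeyError:
        raise KeyError(
            f"no NOAEL for class {analyte_class!r}; known: "
            f"{sorted(constants.noael_mg_per_kg_day)}"
        ) from None
    if edi_pg_kg_day < 0:
        raise ValueError("EDI must be nonnegative")
    if edi_pg_kg_day == 0:
        return math.inf, False
    value = noael_pg / edi_pg_kg_day
    return value, value < MOE_HIGH_RISK_THRESHOLD


def ded(rc_spins_m3: float, p: AgeGroupParams) -> float:
    """Daily radical exposure dose, spins/kg bw/day."""
    if rc_spins_m3 < 0:
        raise ValueError("radical concentration must be nonnegative")
    return rc_spins_m3 * p.IR * p.T / p.BW


def eq_cigarettes(
    rc_spins_m3: float,
    p: AgeGroupParams,
    constants: RiskConstants | None = None,
) -> float:
    """Cigarette-equivalent radical intake per day.

    Note the metric is not body-weight standardised and carries no
    outdoor-time factor, so it tracks the ventilation rate alone.
    """
    constants = constants or RiskConstants()
    if rc_spins_m3 < 0:
        raise ValueError("radical concentration must be nonnegative")
    denom = constants.spins_per_cigarette
    if denom == 0:
        raise ValueError("cigarette spin content must be nonzero")
    return rc_spins_m3 * p.IR / denom


def apply_deposition(table: pd.DataFrame, df: DepositionFractions) -> pd.DataFrame:
    """Add regional rows (region = HA/TB/AR) to a whole-body risk table.

    Each regional value is DF_region times the whole-body value, so the three
    regions sum to at most the inhalable fraction of the whole-body value.
    HQ and MOE are ratios against fixed references and are reported
    whole-body only.
    """
    body = table[table["region"] == "whole-body"]
    frames = [table]
    for region in REGIONS:
        frac = getattr(df, region)
        regional = body.copy()
        regional["region"] = region
        regional["value"] = body["value"] * frac
        regional.loc[~np.isfinite(regional["value"]), "value"] = np.nan
        frames.append(regional[~regional["metric"].isin(["HQ", "MOE"])])
    return pd.concat(frames, ignore_index=True)


def _metric_rows(
    label: str,
    analyte: str,
    conc: float,
    stat: str,
    p: AgeGroupParams,
    constants: RiskConstants,
    is_radical: bool,
) -> list[dict]:
    rows = []

    def add(metric: str, value: float) -> None:
        rows.append(
            {
                "group": label,
                "analyte": analyte,
                "statistic": stat,
                "metric": metric,
                "region": "whole-body",
                "value": value,
            }
        )

    if is_radical:
        add("DED", ded(conc, p))
        add("EQ", eq_cigarettes(conc, p, constants))
    else:
        e = edi(conc, p)
        add("EDI", e)
        add("HQ", hq(e, constants))
        if analyte in constants.noael_mg_per_kg_day:
            add("MOE", moe(e, analyte, constants)[0])
    return rows


def assess_campaign(
    concentrations: pd.DataFrame,
    age_groups: Sequence[AgeGroupParams] | None = None,
    constants: RiskConstants | None = None,
    df: DepositionFractions | None = None,
    radical_analytes: Iterable[str] = ("EPFR",),
) -> pd.DataFrame:
    """Full 17-group risk table from a campaign concentration table.

    Parameters
    ----------
    concentrations:
        Samples x analytes, CP classes in pg/m3 and radicals in spins/m3.
        Both the campaign mean and median are pushed through every metric;
        rows are labelled with which statistic they carry.
    df:
        Deposition fractions; when given, regional EDI/DED/EQ rows are added.

    Returns a tidy long table (group, analyte, statistic, metric, region,
    value). Analytes that are entirely missing raise rather than silently
    producing zeros.
    """
    age_groups = list(age_groups) if age_groups is not None else default_age_groups()
    _check_17(age_groups)
    constants = constants or RiskConstants()
    radical_set = set(radical_analytes)

    rows: list[dict] = []
    for analyte in concentrations.columns:
        series = concentrations[analyte].dropna()
        if series.empty:
            raise ValueError(f"analyte {analyte!r} has no observations")
        stats = {"mean": float(series.mean()), "median": float(series.median())}
        for p in age_groups:
            for stat, conc in stats.items():
                rows.extend(
                    _metric_rows(
                        p.label, analyte, conc, stat, p, constants,
                        analyte in radical_set,
                    )
                )
    table = pd.DataFrame(rows)
    if df is not None:
        table = apply_deposition(table, df)
    return table
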