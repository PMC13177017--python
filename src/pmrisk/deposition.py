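"""ICRP respiratory-tract deposition of inhaled particles.

Empirical closed forms for the inhalable fraction (IF) and the regional
deposition fractions in the head airways (HA), tracheobronchial tree (TB)
and alveolar region (AR) as functions of aerodynamic diameter, plus a
mass-weighted average over a lognormal size distribution.

The raw empirical fits can exceed the inhalable budget by a few tenths of a
percent at the coarse end; regional fractions are therefore rescaled onto IF
whenever their sum overshoots it, so DF_HA + DF_TB + DF_AR <= IF <= 1 holds
everywhere by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C

__all__ = [
    "ParticleSizeSpec",
    "DepositionFractions",
    "inhalable_fraction",
    "regional_fractions",
    "size_averaged_fractions",
    "fraction_table",
]


@dataclass(frozen=True)
class ParticleSizeSpec:
    """Lognormal aerodynamic size distribution: mass median diameter + GSD."""

    mmad_um: float = 1.0
    gsd: float = 1.0
    n_quadrature: int = 17

    def __post_init__(self) -> None:
        if self.mmad_um <= 0:
            raise ValueError("MMAD must be positive")
        if self.gsd < 1.0:
            raise ValueError("GSD must be >= 1")
        if self.n_quadrature < 3:
            raise ValueError("need at least 3 quadrature nodes")


@dataclass(frozen=True)
class DepositionFractions:
    """Inhalable fraction and the three regional deposition fractions."""

    IF: float
    HA: float
    TB: float
    AR: float

    def __post_init__(self) -> None:
        for name in ("IF", "HA", "TB", "AR"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.HA + self.TB + self.AR > self.IF * (1 + 1e-9):
            raise ValueError("regional fractions exceed the inhalable fraction")

    @property
    def total(self) -> float:
        return self.HA + self.TB + self.AR

    def as_dict(self) -> dict[str, float]:
        return {"IF": self.IF, "HA": self.HA, "TB": self.TB, "AR": self.AR}


def inhalable_fraction(dp_um: float) -> float:
    """Fraction of ambient particles of diameter ``dp_um`` entering the airways.

    Tends to 1 for fine particles and to 0.5 for very coarse ones.
    """
    dp = float(dp_um)
    if dp <= 0:
        raise ValueError("particle diameter must be positive")
    return 1.0 - 0.5 * (1.0 - 1.0 / (1.0 + C.IF_A * dp**C.IF_B))


def regional_fractions(dp_um: float) -> DepositionFractions:
    """Regional deposition fractions for a monodisperse aerosol.

    HA deposition combines inertial impaction (coarse) and diffusion
    (ultrafine); TB and AR are double-lognormal fits peaking in the
    ultrafine and fine ranges respectively.
    """
    dp = float(dp_um)
    if dp <= 0:
        raise ValueError("particle diameter must be positive")
    ln_dp = np.log(dp)
    IF = inhalable_fraction(dp)
    ha = IF * (
        1.0 / (1.0 + np.exp(C.HA_A1 + C.HA_B1 * ln_dp))
        + 1.0 / (1.0 + np.exp(C.HA_A2 - C.HA_B2 * ln_dp))
    )
    tb = (C.TB_C / dp) * (
        np.exp(-C.TB_A1 * (ln_dp + C.TB_M1) ** 2)
        + C.TB_S2 * np.exp(-C.TB_A2 * (ln_dp - C.TB_M2) ** 2)
    )
    ar = (C.AR_C / dp) * (
        np.exp(-C.AR_A1 * (ln_dp + C.AR_M1) ** 2)
        + C.AR_S2 * np.exp(-C.AR_A2 * (ln_dp - C.AR_M2) ** 2)
    )
    ha, tb, ar = (float(np.clip(v, 0.0, IF)) for v in (ha, tb, ar))
    total = ha + tb + ar
    if total > IF:  # empirical fits can overshoot the budget marginally
        scale = IF / total
        ha, tb, ar = ha * scale, tb * scale, ar * scale
    return DepositionFractions(IF=IF, HA=ha, TB=tb, AR=ar)


def size_averaged_fractions(size: ParticleSizeSpec) -> DepositionFractions:
    """Mass-weighted deposition fractions over a lognormal size distribution.

    Gauss-Hermite quadrature in ln(dp); a GSD of 1 collapses to the point
    evaluation at the MMAD.
    """
    if size.gsd == 1.0:
        return regional_fractions(size.mmad_um)
    nodes, weights = np.polynomial.hermite_e.hermegauss(size.n_quadrature)
    sigma = np.log(size.gsd)
    dps = size.mmad_um * np.exp(sigma * nodes)
    w = weights / weights.sum()
    acc = {"IF": 0.0, "HA": 0.0, "TB": 0.0, "AR": 0.0}
    for dp, wi in zip(dps, w):
        f = regional_fractions(float(dp))
        for key, val in f.as_dict().items():
            acc[key] += wi * val
    return DepositionFractions(**acc)


def fraction_table(dp_grid_um: np.ndarray):
    """Deposition fractions on a diameter grid, as a tidy DataFrame for inspection."""
    import pandas as pd

    rows = []
    for dp in np.asarray(dp_grid_um, dtype=float):
        f = regional_fractions(float(dp))
        rows.append({"dp_um": float(dp), **f.as_dict(), "total": f.total})
    return pd.DataFrame(rows)
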