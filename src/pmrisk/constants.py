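"""Physical constants, unit conversions and shipped default parameter tables.

Everything that downstream modules treat as "the stated world" lives here:
CODATA constants for the g-factor relation, exact power-of-ten unit
conversions, the ICRP respiratory-deposition coefficient table, the default
17-group exposure-factor table and the toxicological reference values.
"""

from __future__ import annotations

import numpy as np

# --- CODATA 2018 ---------------------------------------------------------
PLANCK_H = 6.62607015e-34  # J s (exact)
BOHR_MAGNETON = 9.2740100783e-24  # J/T

# --- exact unit conversions ----------------------------------------------
PG_PER_UG = 1e6
PG_PER_MG = 1e9
PG_PER_NG = 1e3
MT_PER_T = 1e3

# --- toxicological reference values --------------------------------------
#: Tolerable daily intake for chlorinated paraffins, µg/kg bw/day.
TDI_UG_PER_KG_DAY = 100.0
#: No-observed-adverse-effect levels, mg/kg bw/day, by CP class.
NOAEL_MG_PER_KG_DAY = {"SCCP": 10.0, "MCCP": 23.0, "LCCP": 100.0}
#: Radical load of cigarette tar, spins per gram of tar.
RC_CIGARETTE_SPINS_PER_G = 4.75e16
#: Tar yield per cigarette, grams.
TAR_G_PER_CIGARETTE = 0.013

# --- sampler geometry -----------------------------------------------------
#: 24 h at 1.05 m3/min with a high-volume sampler.
DEFAULT_AIR_VOLUME_M3 = 1.05 * 60 * 24  # 1512 m3
#: Exposed area of an 8"x10" high-volume quartz filter, cm2 (configurable;
#: not stated by any primary source we rely on).
DEFAULT_FILTER_EXPOSED_AREA_CM2 = 406.5
DEFAULT_PUNCH_AREA_CM2 = 1.2
DEFAULT_N_PUNCHES = 3

# --- g-factor classification bounds --------------------------------------
G_CARBON_MAX = 2.0030  # below: carbon-centered radicals
G_OXYGEN_MIN = 2.0040  # above: oxygen-centered radicals

# --- ICRP-66 empirical deposition coefficients ----------------------------
# Centralised so an alternative parameterisation can be swapped in one place.
# Inhalable fraction: IF = 1 - 0.5*(1 - 1/(1 + IF_A * dp**IF_B))
IF_A = 7.6e-4
IF_B = 2.8
# Head-airway: DF_HA = IF * (1/(1+exp(HA_A1 + HA_B1*ln dp))
#                           + 1/(1+exp(HA_A2 - HA_B2*ln dp)))
HA_A1, HA_B1 = 6.84, 1.183
HA_A2, HA_B2 = 0.924, 1.885
# Tracheobronchial: DF_TB = (TB_C/dp)*(exp(-TB_A1*(ln dp + TB_M1)**2)
#                                      + TB_S2*exp(-TB_A2*(ln dp - TB_M2)**2))
TB_C = 0.00352
TB_A1, TB_M1 = 0.234, 3.40
TB_S2, TB_A2, TB_M2 = 63.9, 0.819, 1.61
# Alveolar: DF_AR = (AR_C/dp)*(exp(-AR_A1*(ln dp + AR_M1)**2)
#                              + AR_S2*exp(-AR_A2*(ln dp - AR_M2)**2))
AR_C = 0.0155
AR_A1, AR_M1 = 0.416, 2.84
AR_S2, AR_A2, AR_M2 = 19.11, 0.482, 1.362

# --- default 17-group exposure-factor table -------------------------------
# (label, inhalation rate m3/day, body weight kg, outdoor-time fraction).
# Handbook-typical long-term values; the primary-source table is not public,
# so these are replaceable defaults chosen once (see docs/methods.md).
# T = 0.1 everywhere: ~10% of the day spent outdoors.
DEFAULT_AGE_GROUPS: tuple[tuple[str, float, float, float], ...] = (
    ("0-3 months", 3.1, 6.1, 0.1),
    ("3-6 months", 3.9, 7.5, 0.1),
    ("6-9 months", 4.5, 8.6, 0.1),
    ("9 months-1 year", 5.2, 9.2, 0.1),
    ("1-2 years", 6.8, 11.3, 0.1),
    ("2-3 years", 7.4, 13.3, 0.1),
    ("3-4 years", 8.2, 15.3, 0.1),
    ("4-5 years", 8.8, 17.1, 0.1),
    ("5-6 years", 9.3, 18.9, 0.1),
    ("6-9 years", 10.4, 24.3, 0.1),
    ("9-12 years", 12.1, 33.9, 0.1),
    ("12-15 years", 13.3, 46.4, 0.1),
    ("15-18 years", 14.1, 56.3, 0.1),
    ("18-44 years", 15.7, 60.6, 0.1),
    ("45-59 years", 15.9, 63.1, 0.1),
    ("60-79 years", 14.2, 60.5, 0.1),
    ("over 80 years", 12.6, 55.7, 0.1),
)

# --- printed campaign summary statistics (pg/m3 unless noted) -------------
# Used by the synthetic generator defaults and the acceptance targets as
# *inputs*: class arithmetic means and min/max of the measured campaign.
CLASS_MEAN_PG_M3 = {"SCCP": 5.99e2, "MCCP": 5.31e2, "LCCP": 37.9}
TOTAL_CP_MEAN_PG_M3 = 1.17e3
CLASS_RANGE_PG_M3 = {
    "SCCP": (1.60e2, 2.76e3),
    "MCCP": (92.1, 1.74e3),
    "LCCP": (2.05, 2.22e2),
}
EPFR_MEAN_SPINS_M3 = 1.43e13
EPFR_RANGE_SPINS_M3 = (1.03e12, 6.11e13)
G_FACTOR_RANGE = (2.0033, 2.0040)
G_FACTOR_MEAN = 2.0036


def lognormal_sigma_from_range(lo: float, hi: float, n: int = 104) -> float:
    """Log-scale sigma implied by an observed (min, max) of ``n`` lognormal draws.

    The expected span of n standard-normal draws is roughly 2 * z, with z the
    (1 - 1/(2n)) quantile; for n = 104 this gives span ~ 5.2 sigma, the familiar
    "range rule" for ~100 observations.
    """
    from scipy.stats import norm

    z = norm.ppf(1.0 - 1.0 / (2.0 * n))
    return float(np.log(hi / lo) / (2.0 * z))


def lognormal_median_from_mean(mean: float, sigma: float) -> float:
    """Median m of a lognormal with arithmetic mean ``mean`` and log-sd ``sigma``."""
    return float(mean / np.exp(0.5 * sigma**2))
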