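"""Descriptive and inferential statistics for a sampling campaign.

Composition shares of the CP classes, congener-profile containers,
Kruskal-Wallis comparisons (classes, monthly bins), and an FDR-controlled
Spearman correlation screen across pollutants and meteorology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CongenerProfile",
    "composition_shares",
    "kruskal_wallis",
    "spearman_fdr",
    "monthly_trend",
]


@dataclass(frozen=True)
class CongenerProfile:
    """Congener-group abundance profile for one CP class in one sample.

    ``shares`` maps carbon-chain length (e.g. "C13") to its fraction of the
    class total; ``chlorine_shares`` does the same over chlorine numbers.
    ``chlorine_content`` is the percent chlorine by mass.
    """

    cp_class: str
    shares: Mapping[str, float]
    chlorine_shares: Mapping[str, float] = field(default_factory=dict)
    chlorine_content: float = 50.0

    def __post_init__(self) -> None:
        if self.cp_class not in {"SCCP", "MCCP", "LCCP"}:
            raise ValueError(f"unknown CP class {self.cp_class!r}")
        for name, m in (("shares", self.shares), ("chlorine_shares", self.chlorine_shares)):
            if m and abs(sum(m.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1 within 1e-6")
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.chlorine_content < 100:
            raise ValueError("chlorine content must be a percent in (0, 100)")


def composition_shares(means: Mapping[str, float]) -> dict[str, float]:
    """Percent share of each class in the summed mean concentration.

    Invariant to a common rescaling of all means; shares sum to 100.
    """
    vals = np.array(list(means.values()), dtype=float)
    if np.any(vals < 0):
        raise ValueError("mean concentrations must be nonnegative")
    total = vals.sum()
    if total == 0:
        raise ValueError("all means are zero; shares undefined")
    return {k: 100.0 * v / total for k, v in means.items()}


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from the chi-square approximation.

    Identical groups give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]) and np.all(
        arrays[0] == arrays[0][0]
    ):
        return 0.0, 1.0
    try:
        h, p = sps.kruskal(*arrays)
    except ValueError:  # all observations identical across groups
        return 0.0, 1.0
    return float(h), float(p)


def _spearman_p_fieller(r: float, n: int) -> float:
    """Two-sided Spearman p-value via Fisher's z with Fieller's variance.

    var(z) = 1.06/(n-3) for rank correlations. Slightly conservative at
    moderate n, unlike the Student-t approximation which is anticonservative
    near p ~ 0.05 and would erode the nominal FDR guarantee downstream.
    """
    if abs(r) >= 1.0:
        return 0.0
    z = np.arctanh(r) / np.sqrt(1.06 / (n - 3))
    return float(2.0 * sps.norm.sf(abs(z)))


def spearman_fdr(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Spearman screen with Benjamini-Hochberg control.

    The multiplicity family is every off-diagonal upper-triangle pair of the
    requested columns. Mid-ranks handle ties; p-values come from Fisher's z
    with Fieller's rank-correlation variance. Constant columns have no
    defined correlation: their pairs carry NaN and are excluded from the BH
    family rather than faked.

    Returns a long table (var1, var2, r, p, q, significant).
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two variables")
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            sub = table[[cols[i], cols[j]]].dropna()
            if len(sub) < 4:
                raise ValueError(
                    f"fewer than 4 complete pairs for ({cols[i]}, {cols[j]})"
                )
            x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                r, p = np.nan, np.nan
            else:
                r = float(sps.spearmanr(x, y).statistic)
                p = _spearman_p_fieller(r, len(sub))
            rows.append({"var1": cols[i], "var2": cols[j], "r": r, "p": p})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        _, q, _, _ = multipletests(out.loc[valid, "p"], method="fdr_bh")
        out.loc[valid, "q"] = q
    out["significant"] = out["q"] < alpha
    return out


def monthly_trend(values: pd.Series, dates: pd.Series) -> tuple[float, float]:
    """Kruskal-Wallis test of a concentration series across calendar months.

    The temporal-dynamics comparison: bins by month of the sample date and
    asks whether the distribution differs across bins.
    """
    months = pd.to_datetime(dates).dt.to_period("M")
    groups = [g.to_numpy() for _, g in pd.Series(values.to_numpy(), index=None).groupby(
        months.to_numpy()
    )]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise ValueError("need at least two months with >= 2 samples each")
    return kruskal_wallis(*groups)
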