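"""Nested variance partition of IC values.

Decomposes the variation of per-day IC estimates for one chemical at one
effect level into between-donor, between-clone-within-donor and
within-clone (day-to-day, i.e. technical) sums of squares — the sequential
decomposition of a linear model with donor entered before clone nested in
donor. The identity

    SS_donor + SS_clone + SS_within = Σ (y − ȳ)²

holds exactly, balanced or not:

    SS_donor  = Σ_d n_d (ȳ_d − ȳ)²
    SS_clone  = Σ_c n_c (ȳ_c − ȳ_{d(c)})²
    SS_within = Σ (y − ȳ_c)²
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VarPartRow", "nested_ss", "percentages_from_ss", "build_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VarPartRow:
    """One chemical × effect level row of the variance-partition table."""

    chemical: str
    level: int                 # ICxx level (10..90)
    ss_donor: float
    ss_clone: float
    ss_within: float
    pct_donor: float
    pct_clone: float
    pct_within: float
    n_obs: int
    all_equal: bool = False    # total SS == 0; percentages reported as 0
    incomplete: bool = False   # some donor contributed no defined IC

    @property
    def ss_total(self) -> float:
        return self.ss_donor + self.ss_clone + self.ss_within

    @property
    def largest(self) -> str:
        parts = {"donor": self.pct_donor, "clone": self.pct_clone, "days": self.pct_within}
        return max(parts, key=parts.get)


def percentages_from_ss(ss_donor: float, ss_clone: float, ss_within: float):
    """Percent shares of the three components; zeros (flag) when total is 0."""
    total = ss_donor + ss_clone + ss_within
    if total <= 0:
        return 0.0, 0.0, 0.0, True
    return (100.0 * ss_donor / total, 100.0 * ss_clone / total,
            100.0 * ss_within / total, False)


def nested_ss(obs: pd.DataFrame, chemical: str = "", level: int = 0,
              value_col: str = "ic_value") -> VarPartRow:
    """Sequential nested sum-of-squares decomposition of one observation set.

    ``obs`` needs columns donor_id, clone_id and ``value_col`` (one row per
    day-level IC). Requires ≥ 2 donors; each clone must map to a single
    donor. Unbalanced group sizes are handled by the group-mean formulas.
    """
    obs = obs.dropna(subset=[value_col])
    empty = obs.groupby("clone_id")[value_col].count()
    if (empty == 0).any():
        warnings.warn("clones with zero observations dropped")
    clone_donor = obs.groupby("clone_id")["donor_id"].nunique()
    if (clone_donor > 1).any():
        raise ValueError("a clone maps to more than one donor")
    if obs["donor_id"].nunique() < 2:
        raise ValueError("nested decomposition needs at least 2 donors")

    y = obs[value_col].to_numpy(float)
    grand = y.mean()
    d_stats = obs.groupby("donor_id")[value_col].agg(["mean", "count"])
    ss_donor = float((d_stats["count"] * (d_stats["mean"] - grand) ** 2).sum())
    c_stats = obs.groupby(["donor_id", "clone_id"])[value_col].agg(["mean", "count"])
    donor_mean = d_stats["mean"].reindex(c_stats.index.get_level_values(0)).to_numpy()
    ss_clone = float((c_stats["count"].to_numpy()
                      * (c_stats["mean"].to_numpy() - donor_mean) ** 2).sum())
    clone_mean = obs.groupby("clone_id")[value_col].transform("mean").to_numpy()
    ss_within = float(((y - clone_mean) ** 2).sum())

    pd_, pc_, pw_, flag = percentages_from_ss(ss_donor, ss_clone, ss_within)
    return VarPartRow(chemical=chemical, level=level, ss_donor=ss_donor,
                      ss_clone=ss_clone, ss_within=ss_within,
                      pct_donor=pd_, pct_clone=pc_, pct_within=pw_,
                      n_obs=len(y), all_equal=flag)


def build_table(ic_long: pd.DataFrame, chemicals=None,
                levels=tuple(range(10, 100, 10)), on_um_scale: bool = True) -> pd.DataFrame:
    """Variance-partition table: one row per chemical × IC level.

    ``ic_long`` is the long IC table (donor_id, clone_id, chemical, day,
    level, ic_um [, t_hat], defined). Undefined ICs are excluded listwise;
    rows where some donor contributes no defined IC are flagged
    ``incomplete``. ``on_um_scale=False`` partitions on the t = log2(1+μM)
    scale instead of μM.
    """
    if chemicals is None:
        chemicals = [c for c in ic_long["chemical"].unique()]
    value_col = "ic_um" if on_um_scale else "t_hat"
    all_donors = set(ic_long["donor_id"].unique())
    rows = []
    for chem in chemicals:
        for lv in levels:
            sub = ic_long[(ic_long["chemical"] == chem) & (ic_long["level"] == lv)
                          & ic_long["defined"]]
            if sub["donor_id"].nunique() < 2:
                log.warning("%s IC%d: fewer than 2 donors with defined ICs, row skipped",
                            chem, lv)
                continue
            row = nested_ss(sub.rename(columns={value_col: "ic_value"}),
                            chemical=chem, level=lv)
            incomplete = set(sub["donor_id"].unique()) != all_donors
            rows.append({**row.__dict__, "incomplete": incomplete,
                         "largest": row.largest})
    return pd.DataFrame(rows)
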