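"""Plate normalization: raw well fluorescence → viability profiles.

Each treated well is expressed as percent of the untreated-control mean for
its clone/day plate. Control wells are screened for outliers with an
iterative Grubbs test before their mean is taken; duplicate treated wells at
the same titer are averaged before normalization. One normalized profile is
produced per clone × chemical × day, on both the μM and t = log2(1+μM)
concentration scales.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import t_from_um

__all__ = ["NormalizedProfile", "flag_control_outliers", "normalize"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizedProfile:
    """Viability (% of control) of one clone/chemical/day vs concentration."""

    clone_id: str
    chemical: str
    day: int
    conc_um: np.ndarray      # strictly increasing, μM
    t: np.ndarray            # log2(1 + μM)
    viability: np.ndarray    # percent of control; may exceed 100 (noise)
    n_controls_used: int
    n_controls_flagged: int
    donor_id: str = ""

    def __post_init__(self):
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.viability)) or np.any(self.viability < 0):
            raise ValueError("viability must be finite and >= 0")

    @property
    def max_t(self) -> float:
        return float(self.t[-1])


def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size n at level alpha."""
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def flag_control_outliers(values, alpha: float = 0.05, max_fraction: float = 0.10):
    """Partition control fluorescences into (retained, flagged) by iterative Grubbs.

    At each step the single most extreme value is tested against the
    two-sided Grubbs critical value at ``alpha``; flagging stops when the
    test no longer rejects or when ``max_fraction`` of the original wells
    have been removed. With fewer than 4 values no flagging is attempted
    (a warning is emitted). Deterministic.
    """
    values = np.asarray(values, dtype=float)
    n0 = len(values)
    if n0 < 4:
        warnings.warn("fewer than 4 control wells: outlier flagging skipped")
        return values.copy(), np.empty(0)
    cap = int(np.floor(max_fraction * n0))
    retained = values.copy()
    flagged = []
    while len(flagged) < cap and len(retained) >= 3:
        mean, sd = retained.mean(), retained.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(retained - mean)
        i = int(np.argmax(dev))
        if dev[i] / sd > _grubbs_critical(len(retained), alpha):
            flagged.append(retained[i])
            retained = np.delete(retained, i)
        else:
            break
    return retained, np.asarray(flagged)


def normalize(raw: pd.DataFrame, alpha: float = 0.05, per_chemical_controls: bool = False,
              max_outlier_fraction: float = 0.10) -> list[NormalizedProfile]:
    """Normalize a raw well table into per-clone/chemical/day viability profiles.

    For each (clone, chemical, day, titer), replicate wells are averaged and
    divided by the mean of the retained control wells of that clone/day,
    times 100. By default all of a clone/day's controls are pooled into one
    denominator; ``per_chemical_controls=True`` restricts the denominator to
    the control wells recorded for that chemical's flanking pairs, when the
    table carries a ``control_for`` column (the drift-sensitive mode).

    Units with missing or all-flagged controls are skipped with a logged
    reason; a zero control mean raises.
    """
    required = {"donor_id", "clone_id", "day", "chemical", "conc_um",
                "is_control", "replicate", "fluorescence"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw well table missing columns: {sorted(missing)}")

    profiles: list[NormalizedProfile] = []
    for (clone, day), unit in raw.groupby(["clone_id", "day"], sort=True):
        controls = unit.loc[unit["is_control"], "fluorescence"].to_numpy(float)
        if len(controls) == 0:
            log.warning("clone %s day %s skipped: no control wells", clone, day)
            continue
        retained, flagged_vals = flag_control_outliers(
            controls, alpha=alpha, max_fraction=max_outlier_fraction)
        treated = unit.loc[~unit["is_control"]]
        for chem, sub in treated.groupby("chemical", sort=True):
            if per_chemical_controls and "control_for" in unit.columns:
                cc = unit.loc[unit["is_control"] & (unit["control_for"] == chem),
                              "fluorescence"].to_numpy(float)
                if len(cc) > 0:
                    retained_c, flagged_c = flag_control_outliers(
                        cc, alpha=alpha, max_fraction=max_outlier_fraction)
                else:
                    retained_c, flagged_c = retained, flagged_vals
            else:
                retained_c, flagged_c = retained, flagged_vals
            denom = retained_c.mean()
            if denom == 0:
                raise ValueError(f"zero control mean for clone {clone} day {day}")
            per_titer = (sub.groupby("conc_um")["fluorescence"].mean().sort_index())
            conc = per_titer.index.to_numpy(float)
            viab = per_titer.to_numpy(float) / denom * 100.0
            profiles.append(NormalizedProfile(
                clone_id=str(clone), chemical=str(chem), day=int(day),
                conc_um=conc, t=t_from_um(conc), viability=viab,
                n_controls_used=len(retained_c), n_controls_flagged=len(flagged_c),
                donor_id=str(sub["donor_id"].iloc[0]),
            ))
    return profiles


def profiles_to_frame(profiles: list[NormalizedProfile]) -> pd.DataFrame:
    """Long-format CSV-ready view of a list of profiles."""
    recs = []
    for p in profiles:
        for c, t, v in zip(p.conc_um, p.t, p.viability):
            recs.append((p.donor_id, p.clone_id, p.chemical, p.day, c, t, v))
    return pd.DataFrame(
        recs, columns=["donor_id", "clone_id", "chemical", "day", "conc_um", "t", "viability"])
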