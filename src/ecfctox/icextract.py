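"""Inhibitory-concentration extraction from fitted curves.

The fitted curve is evaluated at 300 equally spaced points on [0, T], where
T slightly exceeds the largest observed concentration (t-scale), and ICxx —
the concentration at which viability falls to (100 − xx)% of control — is
found by locating the bracketing grid interval and linear interpolation,
then back-transformed: IC = 2^t̂ − 1 μM. A threshold the curve never reaches
on the grid yields an undefined estimate (typical for nontoxic chemicals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curvefit import FittedCurve, evaluate_curve

__all__ = ["CurveGrid", "ICEstimate", "make_grid", "extract_ic", "ic_long_table",
           "summarize_ic", "GRID_POINTS", "T_MULTIPLIER"]

log = logging.getLogger(__name__)

GRID_POINTS = 300
T_MULTIPLIER = 1.02   # "slightly higher" extension of the observed range
_MONO_TOL = 1e-6      # permitted non-monotonicity from quadrature round-off


@dataclass(frozen=True)
class CurveGrid:
    """ŷ(t) sampled at 300 equally spaced t values, 0 = t_1 < … < t_300 = T."""

    t_values: np.ndarray
    y_values: np.ndarray

    def __post_init__(self):
        if len(self.t_values) != len(self.y_values):
            raise ValueError("grid t and y lengths differ")
        if np.any(np.diff(self.y_values) > _MONO_TOL):
            raise ValueError("curve grid is not nonincreasing")


@dataclass(frozen=True)
class ICEstimate:
    """ICxx at one effect level; ``defined`` is False when never reached."""

    level: int            # xx in ICxx: percent viability loss (10..90)
    t_hat: float
    ic_um: float
    defined: bool

    @property
    def viability_threshold(self) -> float:
        return 100.0 - self.level


def make_grid(curve: FittedCurve, observed_max_t: float | None = None,
              n: int = GRID_POINTS, multiplier: float = T_MULTIPLIER) -> CurveGrid:
    """Sample a fitted curve on the IC-extraction grid.

    T = multiplier × observed_max_t (default 1.02, keeping extrapolation
    beyond the data negligible); both endpoints are included.
    """
    if observed_max_t is None:
        observed_max_t = curve.domain_T
    if observed_max_t <= 0:
        raise ValueError("observed_max_t must be > 0")
    t = np.linspace(0.0, multiplier * observed_max_t, n)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # flat extrapolation over the 2% extension
        y = evaluate_curve(curve, t)
    return CurveGrid(t_values=t, y_values=y)


def extract_ic(grid: CurveGrid, viability_threshold: float) -> ICEstimate:
    """Invert the sampled curve at a viability threshold v (percent).

    Finds i with ŷ(t_i) > v > ŷ(t_{i+1}) and interpolates
    t̂ = t_i − (ŷ(t_i) − v)/(ŷ(t_i) − ŷ(t_{i+1})) × (t_i − t_{i+1}),
    so the linear interpolant passes through v at t̂; the concentration is
    2^t̂ − 1 μM. Returns ``defined=False`` when no grid interval brackets v.
    """
    v = float(viability_threshold)
    if not 0.0 < v < 100.0:
        raise ValueError("viability threshold must be strictly between 0 and 100")
    t, y = grid.t_values, grid.y_values
    level = int(round(100.0 - v))
    above = y > v
    below = y < v
    bracket = np.nonzero(above[:-1] & ~above[1:])[0]
    if len(bracket) == 0:
        # exact hit on a grid node
        hit = np.nonzero(np.isclose(y, v, atol=1e-12))[0]
        if len(hit):
            i = int(hit[0])
            return ICEstimate(level, float(t[i]), float(np.exp2(t[i]) - 1.0), True)
        if not (np.any(above) and np.any(below)):
            return ICEstimate(level, float("nan"), float("nan"), False)
        return ICEstimate(level, float("nan"), float("nan"), False)
    i = int(bracket[0])
    t_hat = t[i] - (y[i] - v) / (y[i] - y[i + 1]) * (t[i] - t[i + 1])
    return ICEstimate(level, float(t_hat), float(np.exp2(t_hat) - 1.0), True)


def ic_long_table(fits: dict, levels=tuple(range(10, 100, 10))) -> pd.DataFrame:
    """Extract ICs at several levels for a dict of fitted curves.

    ``fits`` maps (donor_id, clone_id, chemical, day) → FittedCurve. Returns
    a long DataFrame (donor_id, clone_id, chemical, day, level, t_hat,
    ic_um, defined).
    """
    recs = []
    for (donor, clone, chem, day), curve in fits.items():
        grid = make_grid(curve)
        for lv in levels:
            est = extract_ic(grid, 100.0 - lv)
            recs.append((donor, clone, chem, day, lv, est.t_hat, est.ic_um, est.defined))
    return pd.DataFrame(recs, columns=["donor_id", "clone_id", "chemical", "day",
                                       "level", "t_hat", "ic_um", "defined"])


def summarize_ic(ic_values_by_clone: dict, min_n: int = 1):
    """Per-clone mean ± SD and the cross-clone summary for one chemical/level.

    ``ic_values_by_clone`` maps clone_id → iterable of defined IC values (μM),
    one per available day. Returns ``(per_clone, across)`` where ``per_clone``
    is a DataFrame (clone_id, n, mean, sd, single_obs) and ``across`` is a
    dict with the unweighted mean and sample SD of the per-clone means —
    the chemical-ranking summary. SD with a single observation is reported
    as 0 and flagged.
    """
    rows = []
    for clone, values in ic_values_by_clone.items():
        vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
        if len(vals) < min_n or len(vals) == 0:
            log.warning("clone %s: no defined IC values, row omitted", clone)
            continue
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append((clone, len(vals), float(vals.mean()), sd, len(vals) == 1))
    per_clone = pd.DataFrame(rows, columns=["clone_id", "n", "mean", "sd", "single_obs"])
    if len(per_clone) == 0:
        raise ValueError("no clone has a defined IC estimate")
    means = per_clone["mean"].to_numpy()
    across = {
        "mean": float(means.mean()),
        "sd": float(np.std(means, ddof=1)) if len(means) > 1 else 0.0,
        "n_clones": int(len(means)),
    }
    return per_clone, across
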