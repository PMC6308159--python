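"""Figures for a pipeline run: per-donor response panels and composite
mean ± 95% CI curves per chemical across donors."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy import stats

from .curvefit import evaluate_curve

__all__ = ["make_report", "composite_curves"]


def composite_curves(fits: dict, chemical: str, n_grid: int = 300):
    """Point-by-point mean and 95% CI across donors of per-donor curves.

    Each donor's curve is the pointwise mean of that donor's clone/day
    fitted curves; the CI at each grid point is mean ± t(0.975, n−1)·SE
    over donors.
    """
    sub = {k: v for k, v in fits.items() if k[2] == chemical}
    if not sub:
        raise ValueError(f"no fitted curves for chemical {chemical!r}")
    Tmax = max(v.domain_T for v in sub.values())
    grid = np.linspace(0.0, Tmax, n_grid)
    donors = sorted({k[0] for k in sub})
    per_donor = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in donors:
            ys = [evaluate_curve(v, grid) for k, v in sub.items() if k[0] == d]
            per_donor.append(np.mean(ys, axis=0))
    per_donor = np.asarray(per_donor)
    mean = per_donor.mean(axis=0)
    n = len(donors)
    if n > 1:
        half = stats.t.ppf(0.975, n - 1) * per_donor.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        half = np.zeros_like(mean)
    return grid, mean, mean - half, mean + half, per_donor


def make_report(fits: dict, ic_wide, vp, fanova_summary, outdir) -> list[str]:
    """Write report figures; returns the list of files created.

    Missing inputs degrade gracefully: sections without artifacts are
    skipped with a notice in the returned list's absence.
    """
    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    created: list[str] = []

    chemicals = sorted({k[2] for k in fits})
    # composite mean ± CI per chemical (two chemicals per figure when paired)
    for i in range(0, len(chemicals), 2):
        pair = chemicals[i:i + 2]
        fig, axes = plt.subplots(1, len(pair), figsize=(5 * len(pair), 4), squeeze=False)
        for ax, chem in zip(axes[0], pair):
            grid, mean, lo, hi, per_donor = composite_curves(fits, chem)
            for y in per_donor:
                ax.plot(grid, y, color="0.8", lw=0.8)
            ax.errorbar(grid[::12], mean[::12], yerr=(mean - lo)[::12],
                        fmt="ko", ms=3, ecolor="0.5", capsize=2)
            ax.set(title=chem, xlabel="t = log2(1 + μM)", ylabel="viability (%)",
                   ylim=(-5, 120))
        fig.tight_layout()
        path = figdir / f"composite_{'_'.join(pair)}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        created.append(str(path))

    # per-donor panels: all clone/day curves of each donor, one figure per chemical
    donors = sorted({k[0] for k in fits})
    for chem in chemicals:
        fig, axes = plt.subplots(1, len(donors), figsize=(3.2 * len(donors), 3),
                                 squeeze=False, sharey=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ax, d in zip(axes[0], donors):
                for (dd, clone, cc, day), v in fits.items():
                    if dd == d and cc == chem:
                        g = np.linspace(0, v.domain_T, 120)
                        ax.plot(g, evaluate_curve(v, g), lw=1,
                                label=f"{clone} d{day}")
                ax.set(title=f"{chem} – {d}", xlabel="t", ylim=(-5, 120))
        axes[0][0].set_ylabel("viability (%)")
        fig.tight_layout()
        path = figdir / f"donor_panels_{chem}.png"
        fig.savefig(path, dpi=90)
        plt.close(fig)
        created.append(str(path))
    return created
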