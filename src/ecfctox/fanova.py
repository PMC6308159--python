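"""Functional ANOVA of concentration-effect curves with a permutation test.

Day-to-day reproducibility is assessed by the additive model

    Y_ij(t) = μ(t) + α_i(t) + β_j(t) + ε_ij(t),   α_1(t) = β_1(t) = 0,

where Y_ij is the fitted curve for toxicant i on day j, μ the reference
curve (first toxicant, first day), α_i toxicant effects and β_j day
effects. The model is fit by ordinary least squares independently at each
grid point; a global day-effect statistic is the maximum over t > 0 of
|β̂_j(t)| / SE(t), calibrated by permuting day labels within each toxicant
(exact under day-exchangeability). Pointwise 95% envelopes come from the
2.5/97.5 percentiles of the permuted coefficient functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CurveCollection", "FanovaFit", "PermutationResult",
           "fit_fanova", "permutation_test", "DEFAULT_B"]

DEFAULT_B = 1000

# |β̂| and SE below this (viability-% units) are round-off from exactly tied
# curves; the ratio is defined as 0 there rather than an artefact of 0/0
_DEGENERATE_TOL = 1e-8


@dataclass(frozen=True)
class CurveCollection:
    """Curves Y_ij(t) on a shared grid, labelled by toxicant i and day j."""

    grid: np.ndarray                  # (G,) t values
    curves: np.ndarray                # (I, J, G) viability values
    toxicant_labels: tuple
    day_labels: tuple

    def __post_init__(self):
        I, J, G = self.curves.shape
        if I != len(self.toxicant_labels) or J != len(self.day_labels):
            raise ValueError("curve array shape does not match labels")
        if G != len(self.grid):
            raise ValueError("curve array grid length mismatch")
        missing = [(self.toxicant_labels[i], self.day_labels[j])
                   for i in range(I) for j in range(J)
                   if not np.all(np.isfinite(self.curves[i, j]))]
        if missing:
            raise ValueError(f"incomplete crossing, missing/non-finite cells: {missing}")


@dataclass
class FanovaFit:
    """Coefficient functions of the additive model on the collection's grid."""

    grid: np.ndarray
    mu: np.ndarray                    # (G,)
    alpha: np.ndarray                 # (I-1, G), toxicants 2..I
    beta: np.ndarray                  # (J-1, G), days 2..J
    residuals: np.ndarray             # (I, J, G)
    se_beta: np.ndarray               # (J-1, G) pointwise SEs
    toxicant_labels: tuple = ()
    day_labels: tuple = ()


@dataclass
class PermutationResult:
    """Global day-effect permutation test output, one entry per day contrast."""

    observed_stat: np.ndarray         # (J-1,)
    null_stats: np.ndarray            # (B, J-1)
    p_value: np.ndarray               # (J-1,)
    pointwise_lower: np.ndarray       # (J-1, G) 2.5% envelope of permuted β̂
    pointwise_upper: np.ndarray       # (J-1, G)
    B: int = 0
    day_labels: tuple = ()


def _design(I: int, J: int) -> np.ndarray:
    """Reference-coded design matrix for the I×J crossed layout, rows in
    (i, j) lexicographic order: intercept, toxicants 2..I, days 2..J."""
    X = np.zeros((I * J, 1 + (I - 1) + (J - 1)))
    X[:, 0] = 1.0
    for i in range(I):
        for j in range(J):
            r = i * J + j
            if i > 0:
                X[r, i] = 1.0
            if j > 0:
                X[r, I + j - 1] = 1.0
    return X


def _ols(X, XtXinv, Y):
    """Pointwise OLS of Y (IJ, G) on X; returns (coef, residual, s2)."""
    coef = XtXinv @ (X.T @ Y)
    resid = Y - X @ coef
    return coef, resid


def fit_fanova(collection: CurveCollection) -> FanovaFit:
    """Fit the additive toxicant + day model pointwise by least squares.

    Requires a complete crossing with at least 2 toxicants and 2 days.
    SE(β̂_j)(t) uses the residual variance with (I−1)(J−1) degrees of
    freedom. The decomposition is exact: fitted + residual reproduces every
    curve at every grid point.
    """
    I, J, G = collection.curves.shape
    if I < 2 or J < 2:
        raise ValueError("need at least 2 toxicants and 2 days")
    X = _design(I, J)
    XtXinv = np.linalg.inv(X.T @ X)
    Y = collection.curves.reshape(I * J, G)
    coef, resid = _ols(X, XtXinv, Y)
    df = (I - 1) * (J - 1)
    s2 = (resid ** 2).sum(axis=0) / df if df > 0 else np.zeros(G)
    se_beta = np.sqrt(np.maximum(s2[None, :], 0.0)
                      * np.diag(XtXinv)[I:, None])
    return FanovaFit(
        grid=collection.grid, mu=coef[0], alpha=coef[1:I], beta=coef[I:],
        residuals=resid.reshape(I, J, G), se_beta=se_beta,
        toxicant_labels=collection.toxicant_labels, day_labels=collection.day_labels)


def _ratio(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """|β|/SE elementwise; degenerate (tied) points give 0, a genuinely
    nonzero β with zero SE gives +inf (flagged saturated point)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(beta) / se
    degenerate = se < _DEGENERATE_TOL
    ratio = np.where(degenerate,
                     np.where(np.abs(beta) < _DEGENERATE_TOL, 0.0, np.inf), ratio)
    return ratio


def _max_ratio(beta: np.ndarray, se: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Max over masked grid points of |β|/SE per contrast."""
    return _ratio(beta, se)[:, mask].max(axis=1)


def permutation_test(collection: CurveCollection, B: int = DEFAULT_B,
                     seed: int = 0) -> PermutationResult:
    """Permutation test of the global day effect.

    Each of the B repeats independently permutes the day labels within each
    toxicant, refits the model, and records each day contrast's maximum of
    |β̂_j(t)|/SE(t) over grid points with t > 0 (at t = 0 all curves equal
    100 and the SE degenerates). p = (1 + #{null ≥ observed}) / (1 + B),
    so p ∈ [1/(B+1), 1]. Pointwise envelopes are the 2.5/97.5 percentiles
    of the permuted β̂_j at each grid point.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    I, J, G = collection.curves.shape
    X = _design(I, J)
    XtXinv = np.linalg.inv(X.T @ X)
    dbeta = np.diag(XtXinv)[I:]
    df = (I - 1) * (J - 1)
    mask = collection.grid > 0
    rng = np.random.default_rng(seed)

    fit = fit_fanova(collection)
    observed = _max_ratio(fit.beta, fit.se_beta, mask)

    # batch of permuted row orders: within each toxicant block, shuffle days
    perms = np.empty((B, I * J), dtype=np.intp)
    base = np.arange(I * J).reshape(I, J)
    for b in range(B):
        cols = np.stack([rng.permutation(J) for _ in range(I)])
        perms[b] = np.take_along_axis(base, cols, axis=1).reshape(-1)

    Y = collection.curves.reshape(I * J, G)
    P = XtXinv @ X.T                                   # (p, IJ)
    Yp = Y[perms]                                      # (B, IJ, G)
    coef = np.einsum("pr,brg->bpg", P, Yp)             # (B, p, G)
    resid = Yp - np.einsum("rp,bpg->brg", X, coef)
    s2 = (resid ** 2).sum(axis=1) / df                 # (B, G)
    beta_p = coef[:, I:, :]                            # (B, J-1, G)
    se_p = np.sqrt(np.maximum(s2[:, None, :], 0.0) * dbeta[None, :, None])
    null_stats = _ratio(beta_p, se_p)[:, :, mask].max(axis=2)   # (B, J-1)

    p = (1.0 + (null_stats >= observed[None, :]).sum(axis=0)) / (1.0 + B)
    lower = np.percentile(beta_p, 2.5, axis=0)
    upper = np.percentile(beta_p, 97.5, axis=0)
    return PermutationResult(observed_stat=observed, null_stats=null_stats,
                             p_value=p, pointwise_lower=lower, pointwise_upper=upper,
                             B=B, day_labels=collection.day_labels)
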