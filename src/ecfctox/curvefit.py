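"""Monotone penalized B-spline fit of concentration-effect curves.

A viability curve is modelled, on the transformed concentration scale
t = log2(1 + μM), as

    y(t) = 100 / (1 + ∫_0^t exp(w(s)) ds),      w(s) = Σ_k c_k b_k(s)

where b_1..b_K are B-spline basis functions. Since the integrand exp(w) is
positive, y decreases strictly from 100 at t = 0 toward 0 — monotonicity is
structural, not a constraint. The coefficients minimize the penalized sum of
squared errors

    PENSSE(c) = Σ_j (x_j − y(t_j))² + λ ∫ (w''(t))² dt

by Newton-Raphson with backtracking line search (quasi-Newton fallback on
failure). The roughness penalty acts on w, the log-derivative structure of
1/y, so λ → ∞ drives the fitted curve toward the two-parameter family with
affine w.

Defaults: K = 20 cubic B-splines on [0, T] with equally spaced interior
knots, λ = 0.01. All curve integrals use cumulative composite Simpson on a
fixed 501-point grid over the fitting domain, with linear interpolation of
the cumulative integral at off-grid points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .normalize import NormalizedProfile

__all__ = ["BasisSpec", "FittedCurve", "build_basis", "penalty_matrix",
           "evaluate_curve", "fit_curve", "DEFAULT_LAMBDA", "DEFAULT_K"]

DEFAULT_LAMBDA = 0.01
DEFAULT_K = 20
N_QUAD = 501          # fixed quadrature grid size over the fitting domain
_EXP_CLIP = 60.0      # cap on w(s) before exponentiation


@dataclass(frozen=True)
class BasisSpec:
    """B-spline basis: K functions of a given order on [0, T]."""

    K: int
    order: int
    domain: tuple
    knots: np.ndarray = field(repr=False)

    @property
    def degree(self) -> int:
        return self.order - 1

    def _bspline(self, deriv: int = 0) -> BSpline:
        b = BSpline(self.knots, np.eye(self.K), self.degree, extrapolate=False)
        return b.derivative(deriv) if deriv else b

    def design_matrix(self, s) -> np.ndarray:
        """Basis values b_k(s): shape (len(s), K)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = self._bspline()(s)
        return np.nan_to_num(out, nan=0.0)

    def second_deriv_matrix(self, s) -> np.ndarray:
        """Second derivatives b_k''(s): shape (len(s), K)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if self.degree < 2:
            return np.zeros((len(s), self.K))
        out = self._bspline(2)(s)
        return np.nan_to_num(out, nan=0.0)


def build_basis(K: int = DEFAULT_K, order: int = 4, domain: tuple = (0.0, 1.0)) -> BasisSpec:
    """Construct a B-spline basis with equally spaced interior knots.

    ``K`` must be at least ``order``. The knot vector clamps the boundary
    (order-fold repeats of both endpoints) and places K − order interior
    knots uniformly, so the basis sums to 1 everywhere on the domain.
    """
    if K < order:
        raise ValueError(f"K ({K}) must be >= order ({order})")
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise ValueError("domain length must be > 0")
    interior = np.linspace(lo, hi, K - order + 2)[1:-1]
    knots = np.concatenate([np.full(order, lo), interior, np.full(order, hi)])
    return BasisSpec(K=K, order=order, domain=(lo, hi), knots=knots)


def penalty_matrix(basis: BasisSpec) -> np.ndarray:
    """Gram matrix R of second derivatives: R_kl = ∫ b_k''(t) b_l''(t) dt.

    Assembled exactly by Gauss-Legendre quadrature per knot span (the
    integrand is piecewise polynomial of degree 2·(order−3), so ``order``
    nodes per span suffice). PEN(c) = cᵀ R c is zero iff Σ c_k b_k is
    affine on the domain.
    """
    if basis.degree < 2:
        return np.zeros((basis.K, basis.K))
    spans = np.unique(basis.knots)
    nodes, weights = np.polynomial.legendre.leggauss(max(basis.order, 2))
    R = np.zeros((basis.K, basis.K))
    for a, b in zip(spans[:-1], spans[1:]):
        half = 0.5 * (b - a)
        x = 0.5 * (a + b) + half * nodes
        D = basis.second_deriv_matrix(x)                 # (n, K)
        R += (D * (weights * half)[:, None]).T @ D
    return R


@dataclass
class FittedCurve:
    """A fitted monotone concentration-effect curve and its diagnostics."""

    basis: BasisSpec
    c: np.ndarray
    lam: float
    sse: float
    pen: float
    pensse: float
    converged: bool
    n_points: int
    n_iter: int = 0
    degenerate: bool = False

    @property
    def domain_T(self) -> float:
        return self.basis.domain[1]

    def __call__(self, t):
        return evaluate_curve(self, t)

    def to_json(self) -> str:
        return json.dumps({
            "K": self.basis.K, "order": self.basis.order,
            "domain": list(self.basis.domain), "c": self.c.tolist(),
            "lambda": self.lam, "sse": self.sse, "pen": self.pen,
            "pensse": self.pensse, "converged": self.converged,
            "n_points": self.n_points, "n_iter": self.n_iter,
            "degenerate": self.degenerate,
        })

    @classmethod
    def from_json(cls, text: str) -> "FittedCurve":
        d = json.loads(text)
        basis = build_basis(d["K"], d["order"], tuple(d["domain"]))
        return cls(basis=basis, c=np.asarray(d["c"], dtype=float), lam=d["lambda"],
                   sse=d["sse"], pen=d["pen"], pensse=d["pensse"],
                   converged=d["converged"], n_points=d["n_points"],
                   n_iter=d.get("n_iter", 0), degenerate=d.get("degenerate", False))


class _Quadrature:
    """Fixed-grid cumulative-Simpson machinery shared by evaluation and fitting."""

    def __init__(self, basis: BasisSpec, n: int = N_QUAD):
        lo, hi = basis.domain
        self.s = np.linspace(lo, hi, n)
        self.h = self.s[1] - self.s[0]
        self.B = basis.design_matrix(self.s)             # (n, K)
        # nonzero basis-product pairs (B-splines overlap only within the order)
        K = basis.K
        ku, lu = np.meshgrid(np.arange(K), np.arange(K), indexing="ij")
        keep = np.abs(ku - lu) < basis.order
        self.pair_k, self.pair_l = ku[keep], lu[keep]
        self.BB = self.B[:, self.pair_k] * self.B[:, self.pair_l]   # (n, P)

    def integrand(self, c: np.ndarray) -> np.ndarray:
        w = np.clip(self.B @ c, -_EXP_CLIP, _EXP_CLIP)
        return np.exp(w)

    def cumulative(self, values: np.ndarray) -> np.ndarray:
        """Cumulative Simpson along axis 0, zero at the left endpoint."""
        return cumulative_simpson(values, dx=self.h, axis=0, initial=0.0)

    def interp(self, cum: np.ndarray, t: np.ndarray):
        """Linear interpolation of cumulative integrals (any trailing shape) at t."""
        idx = np.clip(np.searchsorted(self.s, t, side="right") - 1, 0, len(self.s) - 2)
        frac = (t - self.s[idx]) / self.h
        shape = (-1,) + (1,) * (cum.ndim - 1)
        return cum[idx] + frac.reshape(shape) * (cum[idx + 1] - cum[idx])


def evaluate_curve(curve: FittedCurve, t):
    """Evaluate the fitted viability curve at t (log2(1+μM) units).

    y(0) = 100 exactly. Beyond the fitting domain's upper end the integrand
    is extended flat at its boundary value (a warning is emitted); negative
    t is rejected.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    q = _Quadrature(curve.basis)
    E = q.integrand(curve.c)
    CI = q.cumulative(E)
    T = curve.domain_T
    inside = np.minimum(t_arr, T)
    I = q.interp(CI, inside)
    over = t_arr > T + 1e-12
    if np.any(over):
        warnings.warn("evaluating curve beyond fitted domain: flat integrand extrapolation")
        I = I + np.where(over, (t_arr - T) * E[-1], 0.0)
    y = 100.0 / (1.0 + I)
    y[t_arr == 0.0] = 100.0
    return float(y[0]) if np.isscalar(t) else y


def _objective(c, q, R, t_j, x_j, lam):
    """PENSSE and the intermediates needed by the derivative assembly."""
    E = q.integrand(c)                                   # (G,)
    CI = q.cumulative(E)
    I_j = q.interp(CI, t_j)                              # (J,)
    y_j = 100.0 / (1.0 + I_j)
    r = x_j - y_j
    pen = float(c @ R @ c)
    sse = float(r @ r)
    return sse + lam * pen, sse, pen, E, I_j, r


def _grad_hess(c, q, R, t_j, x_j, lam, E, I_j, r):
    """Gradient and Hessian of PENSSE at c, given the objective intermediates."""
    K = len(c)
    # dI_j/dc: cumulative integrals of b_k(s) e^{w(s)}
    CIk = q.cumulative(q.B * E[:, None])                 # (G, K)
    dI = q.interp(CIk, t_j)                              # (J, K)
    dydI = -100.0 / (1.0 + I_j) ** 2                     # (J,)
    dy = dydI[:, None] * dI                              # (J, K)
    g = -2.0 * (r @ dy) + 2.0 * lam * (R @ c)

    # d²I_j/dc²: cumulative integrals of b_k b_l e^w (banded: b_k b_l ≡ 0
    # unless the splines overlap)
    CIp = q.cumulative(q.BB * E[:, None])                # (G, P)
    d2I_p = q.interp(CIp, t_j)                           # (J, P)
    wj = -2.0 * r * dydI                                 # weight of d2I per point
    Hp = wj @ d2I_p                                      # (P,)
    H = np.zeros((K, K))
    np.add.at(H, (q.pair_k, q.pair_l), Hp)
    d2ydI2 = 200.0 / (1.0 + I_j) ** 3
    H += 2.0 * (dy.T @ dy)
    H -= 2.0 * np.einsum("j,jk,jl->kl", r * d2ydI2, dI, dI)
    H += 2.0 * lam * R
    return g, H


def _pensse_fg(c, q, R, t_j, x_j, lam):
    """Objective and gradient only (for the quasi-Newton fallback)."""
    E = q.integrand(c)
    CI = q.cumulative(E)
    I_j = q.interp(CI, t_j)
    y_j = 100.0 / (1.0 + I_j)
    r = x_j - y_j
    f = float(r @ r) + lam * float(c @ R @ c)
    CIk = q.cumulative(q.B * E[:, None])
    dI = q.interp(CIk, t_j)
    dy = (-100.0 / (1.0 + I_j) ** 2)[:, None] * dI
    g = -2.0 * (r @ dy) + 2.0 * lam * (R @ c)
    return f, g


def _initial_coefficients(t_j, x_j, K: int) -> np.ndarray:
    """Start at a constant log-integrand w ≡ log w0 placing y near the data.

    If the observed viabilities cross 50%, w0 = 1/t_mid puts the constant-w
    curve's midpoint at the empirical mid-decline titer; otherwise w0 is set
    so the curve meets the last observed viability at the last titer.
    """
    if np.any(x_j <= 50.0):
        k = int(np.argmax(x_j <= 50.0))
        if k == 0:
            t_mid = t_j[0]
        else:
            x0, x1 = x_j[k - 1], x_j[k]
            t_mid = t_j[k - 1] + (x0 - 50.0) / max(x0 - x1, 1e-9) * (t_j[k] - t_j[k - 1])
        w0 = 1.0 / max(t_mid, 1e-6)
    else:
        v_end = float(np.clip(x_j[-1], 1.0, 99.5))
        w0 = (100.0 / v_end - 1.0) / t_j[-1]
    return np.full(K, np.log(max(w0, 1e-12)))


def fit_curve(profile: NormalizedProfile, lam: float = DEFAULT_LAMBDA,
              K: int = DEFAULT_K, order: int = 4, tol: float = 1e-8,
              max_iter: int = 200) -> FittedCurve:
    """Fit the monotone curve to one normalized profile by minimizing PENSSE.

    Newton-Raphson on the coefficients with Levenberg-style ridge escalation
    when the Hessian is indefinite and Armijo backtracking on the step;
    if Newton stalls, an L-BFGS-B polish from the best iterate is used and
    the better objective kept. Refitting the same profile is deterministic.
    The fitting domain is [0, max observed t].
    """
    t_j = np.asarray(profile.t, dtype=float)
    x_j = np.asarray(profile.viability, dtype=float)
    if len(np.unique(t_j)) < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    degenerate = bool(np.ptp(x_j) < 1e-9)
    if degenerate:
        warnings.warn(f"{profile.clone_id}/{profile.chemical}/d{profile.day}: "
                      "all viabilities identical; degenerate fit flagged")

    basis = build_basis(K=K, order=order, domain=(0.0, float(t_j.max())))
    R = penalty_matrix(basis)
    q = _Quadrature(basis)
    c = _initial_coefficients(t_j, x_j, K)

    f, sse, pen, E, I_j, r = _objective(c, q, R, t_j, x_j, lam)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g, H = _grad_hess(c, q, R, t_j, x_j, lam, E, I_j, r)
        # Newton direction, with ridge escalation on indefinite Hessian
        step = None
        ridge = 0.0
        for _ in range(12):
            try:
                L = np.linalg.cholesky(H + ridge * np.eye(len(c)))
                step = np.linalg.solve(L.T, np.linalg.solve(L, -g))
                break
            except np.linalg.LinAlgError:
                ridge = 1e-8 * max(1.0, np.trace(H) / len(c)) if ridge == 0 else ridge * 10.0
        if step is None or not np.all(np.isfinite(step)):
            step = -g  # steepest descent as last resort

        # Armijo backtracking on the objective alone
        alpha, accepted = 1.0, False
        gTs = float(g @ step)
        for _ in range(40):
            c_new = c + alpha * step
            f_new, sse_new, pen_new, E_new, I_new, r_new = _objective(
                c_new, q, R, t_j, x_j, lam)
            if np.isfinite(f_new) and f_new <= f + 1e-4 * alpha * gTs:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        rel = abs(f - f_new) / max(1.0, abs(f))
        c, f, sse, pen = c_new, f_new, sse_new, pen_new
        E, I_j, r = E_new, I_new, r_new
        if rel < tol:
            converged = True
            break

    if not converged:
        res = minimize(_pensse_fg, c, args=(q, R, t_j, x_j, lam), jac=True,
                       method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-12})
        if np.isfinite(res.fun) and res.fun <= f:
            c = res.x
            f, sse, pen, E, I_j, r = _objective(c, q, R, t_j, x_j, lam)
            converged = bool(res.success)
        if not converged:
            warnings.warn(f"{profile.clone_id}/{profile.chemical}/d{profile.day}: "
                          f"PENSSE fit did not converge after {it} Newton iterations")

    return FittedCurve(basis=basis, c=c, lam=lam, sse=sse, pen=pen,
                       pensse=sse + lam * pen, converged=converged,
                       n_points=len(t_j), n_iter=it, degenerate=degenerate)
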