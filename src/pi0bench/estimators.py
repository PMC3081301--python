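"""Five p-value-based estimators of the proportion of true null hypotheses.

All five consume nothing but a vector of p-values from M simultaneous tests
and return an estimate of pi0 = M0/M, the fraction of tests whose null
hypothesis is true.  They exploit, in different ways, the fact that null
p-values are Uniform(0,1) while p-values from false nulls pile up near 0:

PM03  — maximum-likelihood fit of a beta-uniform mixture (BUM) density
        f(p) = w + (1-w) * a * p^(a-1); the density at p = 1,
        w + (1-w)*a, upper-bounds pi0.
PC04  — LOESS smoothing of the reciprocal p-value spacings (a raw density
        estimate); pi0 is the minimum of the smoothed density.
Ch04  — monotone cubic B-spline fit to the empirical CDF of p-values with
        knots concentrated near 0; pi0 is the minimum of the fitted CDF's
        derivative.
ST03  — the lambda-tail estimate pi0(lambda) = #{p > lambda} / (M(1-lambda))
        extrapolated to lambda -> 1 by a natural cubic smoothing spline with
        3 effective degrees of freedom.
ZG04  — median slope of the chords joining upper-tail points of the
        empirical CDF to the corner (1, 1).

Every estimator clips its result to [0, 1] and records method-specific
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import interpolate, optimize
from statsmodels.nonparametric.smoothers_lowess import lowess

from .synthetic import PValueSet

__all__ = [
    "METHODS",
    "Pi0Estimate",
    "estimate_pi0_zg04",
    "estimate_pi0_st03",
    "estimate_pi0_pm03",
    "estimate_pi0_pc04",
    "estimate_pi0_ch04",
    "estimate_all",
    "bum_loglik",
    "smoothing_spline_fit",
]

#: canonical method order used throughout the benchmark
METHODS = ("PM03", "PC04", "Ch04", "ST03", "ZG04")


@dataclass
class Pi0Estimate:
    """A pi0 estimate with provenance and fit diagnostics."""

    method: str
    pi0_hat: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0_hat <= 1.0):
            raise ValueError("pi0_hat must lie in [0, 1]")


def _as_array(p: PValueSet | np.ndarray) -> np.ndarray:
    arr = p.p if isinstance(p, PValueSet) else np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a one-dimensional vector of at least 2 p-values")
    return arr


def _clip(value: float) -> tuple[float, bool]:
    clipped = float(min(1.0, max(0.0, value)))
    return clipped, clipped != value


# ---------------------------------------------------------------------------
# ZG04 — median chord slope of the upper-tail empirical CDF
# ---------------------------------------------------------------------------

def estimate_pi0_zg04(p: PValueSet | np.ndarray, t1: float = 0.5,
                      t2: float = 1.0) -> Pi0Estimate:
    """Median slope of chords from upper-tail ECDF points to (1, 1).

    With p-values sorted ascending, the point (p_(i), i/M) lies on the
    empirical CDF; the chord to (1, 1) has slope
    s_i = (1 - i/M) / (1 - p_(i)).  For null-dominated upper tails the ECDF
    is locally linear with slope pi0, so the median of the s_i over
    t1 <= p_(i) <= t2 estimates pi0.  The index i = M (slope identically 0)
    and any p_(i) = 1 (undefined slope) are excluded.
    """
    arr = _as_array(p)
    if not (0.0 < t1 < t2 <= 1.0):
        raise ValueError("need 0 < t1 < t2 <= 1")
    M = arr.size
    ps = np.sort(arr)
    i = np.arange(1, M + 1)
    keep = (ps >= t1) & (ps <= t2) & (ps < 1.0) & (i < M)
    if not np.any(keep):
        raise ValueError(
            f"no sorted p-value falls in [{t1}, {t2}] with p < 1 and i < M; "
            "widen the (t1, t2) range"
        )
    slopes = (1.0 - i[keep] / M) / (1.0 - ps[keep])
    raw = float(np.median(slopes))
    pi0_hat, was_clipped = _clip(raw)
    return Pi0Estimate("ZG04", pi0_hat, {
        "n_slopes": int(keep.sum()), "raw": raw, "clipped": was_clipped,
        "t1": t1, "t2": t2,
    })


# ---------------------------------------------------------------------------
# ST03 — lambda-tail estimates extrapolated by a smoothing spline
# ---------------------------------------------------------------------------

def _natural_spline_matrices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Reinsch form of the natural cubic smoothing spline: roughness matrix
    # K = D' W^{-1} D built from the second-difference operator D and the
    # tridiagonal Gram matrix W of the second-derivative basis.
    n = x.size
    h = np.diff(x)
    D = np.zeros((n - 2, n))
    W = np.zeros((n - 2, n - 2))
    for j in range(n - 2):
        D[j, j] = 1.0 / h[j]
        D[j, j + 1] = -1.0 / h[j] - 1.0 / h[j + 1]
        D[j, j + 2] = 1.0 / h[j + 1]
        W[j, j] = (h[j] + h[j + 1]) / 3.0
        if j + 1 < n - 2:
            W[j, j + 1] = W[j + 1, j] = h[j + 1] / 6.0
    K = D.T @ np.linalg.solve(W, D)
    return K, h


def smoothing_spline_fit(x: np.ndarray, y: np.ndarray,
                         df: float = 3.0) -> np.ndarray:
    """Natural cubic smoothing spline with the given effective df.

    Returns the fitted values at the data points.  The penalty is chosen by
    bisection so that the trace of the smoother matrix (I + alpha*K)^{-1}
    equals ``df``; df must lie strictly between 2 (the linear limit) and the
    number of distinct points (interpolation).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 4:
        raise ValueError("smoothing spline needs at least 4 points")
    if not (2.0 < df < n):
        raise ValueError(f"effective df must be in (2, {n})")
    K, _ = _natural_spline_matrices(x)
    eye = np.eye(n)

    def trace_df(log_alpha: float) -> float:
        return float(np.trace(np.linalg.solve(eye + np.exp(log_alpha) * K, eye)))

    lo, hi = -25.0, 25.0
    while trace_df(lo) < df:
        lo -= 10.0
    while trace_df(hi) > df:
        hi += 10.0
    # trace is decreasing in alpha
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if trace_df(mid) > df:
            lo = mid
        else:
            hi = mid
    alpha = np.exp(0.5 * (lo + hi))
    return np.linalg.solve(eye + alpha * K, y)


def estimate_pi0_st03(p: PValueSet | np.ndarray,
                      lambda_grid: np.ndarray | None = None,
                      spline_df: float = 3.0) -> Pi0Estimate:
    """Tail-fraction estimates over a lambda grid, smoothed and read at the end.

    pi0(lambda) = #{p_i > lambda} / (M (1 - lambda)) is unbiased for pi0 as
    lambda -> 1 but increasingly variable; a natural cubic smoothing spline
    with 3 effective degrees of freedom is fitted to the grid of estimates
    and evaluated at the largest lambda.  Default grid: 0, 0.01, ..., 0.95.
    """
    arr = _as_array(p)
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 0.9501, 0.01)
    lam = np.asarray(lambda_grid, float)
    if lam.size < 4:
        raise ValueError("need at least 4 lambda grid points for the spline")
    if np.any(np.diff(lam) <= 0) or lam[0] < 0 or lam[-1] >= 1:
        raise ValueError("lambda_grid must be strictly increasing in [0, 1)")
    M = arr.size
    pi0_lambda = np.array([(arr > l).sum() / (M * (1.0 - l)) for l in lam])
    fitted = smoothing_spline_fit(lam, pi0_lambda, df=spline_df)
    raw = float(fitted[-1])
    pi0_hat, was_clipped = _clip(raw)
    return Pi0Estimate("ST03", pi0_hat, {
        "lambda_grid": lam, "pi0_lambda": pi0_lambda, "fitted": fitted,
        "raw": raw, "clipped": was_clipped,
    })


# ---------------------------------------------------------------------------
# PM03 — beta-uniform mixture MLE, density at p = 1 as the upper bound
# ---------------------------------------------------------------------------

_P_FLOOR = 1e-10


def bum_loglik(a: float, w: float, p: np.ndarray) -> float:
    """Log-likelihood of the BUM density w + (1-w) * a * p^(a-1)."""
    dens = w + (1.0 - w) * a * np.power(p, a - 1.0)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def estimate_pi0_pm03(p: PValueSet | np.ndarray) -> Pi0Estimate:
    """BUM maximum likelihood; pi0 upper bound is the fitted density at p = 1.

    The likelihood is maximised over 0 < a <= 1, 0 <= w <= 1 by bounded
    quasi-Newton iterations from a 3 x 3 grid of starting points (the
    surface can be flat in w when a is near 1).  p-values are clipped to
    [1e-10, 1] so that p^(a-1) stays finite.
    """
    arr = np.clip(_as_array(p), _P_FLOOR, 1.0)

    def nll(theta: np.ndarray) -> float:
        return -bum_loglik(theta[0], theta[1], arr)

    best = None
    for a0 in (0.1, 0.5, 0.9):
        for w0 in (0.1, 0.5, 0.9):
            res = optimize.minimize(
                nll, x0=np.array([a0, w0]), method="L-BFGS-B",
                bounds=[(1e-4, 1.0), (0.0, 1.0)],
                options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
            )
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("BUM likelihood optimisation failed to converge")
    a_hat, w_hat = float(best.x[0]), float(best.x[1])
    raw = w_hat + (1.0 - w_hat) * a_hat
    pi0_hat, was_clipped = _clip(raw)
    return Pi0Estimate("PM03", pi0_hat, {
        "a_hat": a_hat, "w_hat": w_hat, "loglik": -float(best.fun),
        "raw": raw, "clipped": was_clipped,
    })


# ---------------------------------------------------------------------------
# PC04 — LOESS-smoothed spacing density, minimum as pi0
# ---------------------------------------------------------------------------

def estimate_pi0_pc04(p: PValueSet | np.ndarray, span: float = 0.3,
                      window: int = 21) -> Pi0Estimate:
    """Smooth the reciprocal spacings of sorted p-values; pi0 = density minimum.

    Between consecutive distinct sorted p-values the empirical density is
    1/(M * spacing) at the interval midpoint; tied values are merged, each
    contributing its average (multiplicity-divided) spacing.  A single
    exponential gap has a reciprocal with infinite mean, so each raw
    ordinate uses the running mean of ``window`` neighbouring spacings —
    still exactly 1 on an equally spaced grid, but with light tails under
    sampling noise.  The ordinates are then smoothed against the midpoints
    with locally weighted regression at the given span, anchored at 0 and 1,
    and the minimum of the smoothed density — clipped to [0, 1] — is pi0.
    """
    arr = _as_array(p)
    M = arr.size
    if M < 3:
        raise ValueError("PC04 needs at least 3 p-values")
    u, counts = np.unique(arr, return_counts=True)
    if u.size < 2:
        raise ValueError("all p-values identical; spacing density undefined")
    d = np.diff(u)
    mids = 0.5 * (u[:-1] + u[1:])
    mass = 0.5 * (counts[:-1] + counts[1:])
    spacing = d / mass  # spacing per unit of probability mass
    w = max(1, min(window, spacing.size))
    kern = np.ones(w)
    dbar = (np.convolve(spacing, kern, mode="same")
            / np.convolve(np.ones_like(spacing), kern, mode="same"))
    y = 1.0 / (M * dbar)
    # anchor the curve at the interval ends so the minimum is taken on [0, 1]
    x_all = np.concatenate([[0.0], mids, [1.0]])
    y_all = np.concatenate([[y[0]], y, [y[-1]]])
    smoothed = lowess(y_all, x_all, frac=span, it=0, delta=0.005,
                      return_sorted=True)
    fitted = smoothed[:, 1]
    raw = float(fitted.min())
    pi0_hat, was_clipped = _clip(raw)
    return Pi0Estimate("PC04", pi0_hat, {
        "span": span, "window": w, "raw": raw, "clipped": was_clipped,
        "argmin": float(smoothed[int(np.argmin(fitted)), 0]),
    })


# ---------------------------------------------------------------------------
# Ch04 — monotone B-spline CDF, minimum derivative as pi0
# ---------------------------------------------------------------------------

def _ch04_knots(n_knots: int) -> np.ndarray:
    """Interior knots: geometric progression near 0, uniform over the tail.

    The p-value CDF bends sharply near 0 (where alternative p-values pile
    up) and is nearly linear in the tail, so knot resolution is concentrated
    where curvature lives.
    """
    n_geo = max(2, int(round(0.6 * n_knots)))
    n_uni = n_knots - n_geo
    geo = 0.005 * (0.3 / 0.005) ** (np.arange(n_geo) / (n_geo - 1))
    uni = np.linspace(0.3, 1.0, n_uni + 2)[1:-1] if n_uni else np.array([])
    return np.concatenate([geo, uni])


def estimate_pi0_ch04(p: PValueSet | np.ndarray, n_knots: int = 10,
                      concave: bool = True) -> Pi0Estimate:
    """Shape-constrained cubic B-spline fit to the p-value ECDF; pi0 = min derivative.

    The CDF is represented as a cubic B-spline on [0, 1] constrained to
    F(0) = 0, F(1) = 1 with nondecreasing coefficients (which makes the
    spline itself nondecreasing).  By default the fit is also concave —
    under the uniform-plus-alternatives mixture the p-value density is
    nonincreasing, and without this constraint the spline's derivative
    develops spurious dips just past the steep rise of the CDF near 0.  The
    coefficient increments are found by constrained least squares against
    the empirical CDF; the estimate is the minimum of the fitted CDF's
    first derivative over [0, 1].
    """
    arr = _as_array(p)
    M = arr.size
    if M < n_knots + 4:
        raise ValueError(f"Ch04 needs at least n_knots + 4 = {n_knots + 4} p-values")
    interior = _ch04_knots(n_knots)
    t = np.concatenate([[0.0] * 4, interior, [1.0] * 4])
    n_coef = n_knots + 4

    xs = np.sort(np.clip(arr, 0.0, 1.0))
    ys = (np.arange(1, M + 1) - 0.5) / M
    if M > 2000:  # thin the ECDF; the fit has only n_coef parameters
        idx = np.linspace(0, M - 1, 2000).astype(int)
        xs, ys = xs[idx], ys[idx]

    design = interpolate.BSpline.design_matrix(xs, t, 3).toarray()
    # c = cumsum(u) with c_0 = 0; sum(u) = 1 pins F(1) = 1, u >= 0 pins monotonicity
    C = np.tril(np.ones((n_coef - 1, n_coef - 1)))
    A = design[:, 1:] @ C

    greville = np.array([t[i + 1:i + 4].mean() for i in range(n_coef)])
    u0 = np.diff(greville)  # increments of the identity CDF
    u0 = np.maximum(u0, 1e-8)
    u0 /= u0.sum()

    def obj(u: np.ndarray) -> float:
        r = A @ u - ys
        return float(r @ r)

    def grad(u: np.ndarray) -> np.ndarray:
        return 2.0 * A.T @ (A @ u - ys)

    constraints = [{"type": "eq", "fun": lambda u: u.sum() - 1.0,
                    "jac": lambda u: np.ones_like(u)}]
    if concave:
        # derivative-spline coefficients 3*u_i/(t[i+4]-t[i+1]) nonincreasing
        scale = 3.0 / (t[4:4 + n_coef - 1] - t[1:n_coef])
        G = np.zeros((n_coef - 2, n_coef - 1))
        idx = np.arange(n_coef - 2)
        G[idx, idx] = scale[:-1]
        G[idx, idx + 1] = -scale[1:]
        constraints.append({"type": "ineq", "fun": lambda u: G @ u,
                            "jac": lambda u: G})
        # the identity-CDF start (constant unit density) is strictly feasible

    res = optimize.minimize(
        obj, u0, jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * (n_coef - 1),
        constraints=constraints,
        options={"maxiter": 300, "ftol": 1e-12},
    )
    if not res.success and obj(res.x) > obj(u0):
        raise RuntimeError(f"monotone spline fit infeasible: {res.message}")
    coef = np.concatenate([[0.0], C @ res.x])
    spline = interpolate.BSpline(t, coef, 3)
    grid = np.linspace(0.0, 1.0, 1001)
    dens = spline.derivative()(grid)
    raw = float(dens.min())
    pi0_hat, was_clipped = _clip(raw)
    return Pi0Estimate("Ch04", pi0_hat, {
        "n_knots": n_knots, "coef": coef, "knots": t, "raw": raw,
        "clipped": was_clipped, "argmin": float(grid[int(np.argmin(dens))]),
    })


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_DISPATCH: dict[str, Callable[..., Pi0Estimate]] = {
    "PM03": estimate_pi0_pm03,
    "PC04": estimate_pi0_pc04,
    "Ch04": estimate_pi0_ch04,
    "ST03": estimate_pi0_st03,
    "ZG04": estimate_pi0_zg04,
}


def estimate_all(p: PValueSet | np.ndarray,
                 methods: tuple[str, ...] = METHODS) -> dict[str, Pi0Estimate]:
    """Run the requested estimators (default: all five) on one p-value set."""
    out: dict[str, Pi0Estimate] = {}
    for name in methods:
        try:
            fn = _DISPATCH[name]
        except KeyError:
            raise ValueError(f"unknown method {name!r}; choose from {METHODS}")
        out[name] = fn(p)
    return out
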