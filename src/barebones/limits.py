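"""Scaling limit of the density map along the unstable direction.

The central object is

    H(x) = lim_n f^n(x_re + x / rho^n),   x in R x R_+,

the limit of n-fold map iterates started an O(rho^-n) perturbation away
from the resident equilibrium.  H maps the early-growth randomness of the
mutant lineage (the martingale limit W of the linearised branching process)
to a macroscopic population state, and solves the Abel functional equation
H(x) = f(H(x/rho)) with H(0) = x_re.

The one-dimensional machinery behind the convergence proof is also exposed:
the quadratic comparison recursion x_{m,n} = rho*x_{m-1,n}*(1 + C*x_{m-1,n})
and the Schroeder function phi of the inverse parabola
f(x) = sqrt(1/4 + s*x) - 1/2, s = 1/rho, satisfying phi(f(x)) = s*phi(x),
phi'(0+) = 1.  The conjugacy p^n(x/rho^n) -> phi_inverse(x) bounds the
recursion and is used as an independent oracle in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, DerivedModel, derive_constants, f_map

__all__ = [
    "LimitEvaluation",
    "iterate_map",
    "compute_H",
    "h_convergence_differences",
    "abel_residual",
    "h_grid",
    "auxiliary_recursion",
    "SchroederFunction",
    "schroeder_phi",
]

_MAX_ITER = 700  # rho^n handled by repeated division, so no overflow below this


@dataclass(frozen=True)
class LimitEvaluation:
    """Value of H at a point with convergence diagnostics."""

    input: tuple[float, float]
    value: tuple[float, float]
    iterations: int
    last_increment: float
    converged: bool


def iterate_map(x0, n: int, params: ModelParams) -> np.ndarray:
    """Deterministic trajectory x0, f(x0), ..., f^n(x0), shape (n+1, 2)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    out = np.empty((n + 1, 2))
    x1, x2 = float(x0[0]), float(x0[1])
    if x1 < 0 or x2 < 0:
        raise ValueError("start must lie in the nonnegative quadrant")
    out[0] = (x1, x2)
    for k in range(1, n + 1):
        x1, x2 = f_map((x1, x2), params)
        out[k] = (x1, x2)
    return out


def _admissible_start_n(x1: float, x2: float, d: DerivedModel) -> int:
    """Smallest n such that x_re + x/rho^n lies in the forward-invariant set.

    In absolute coordinates the set is [x_co1, inf) x [0, x_co2]: the first
    coordinate of the start is a1 + x1/rho^n and the second x2/rho^n.
    """
    a1 = d.params.a1
    rho = d.rho
    y1, y2 = x1, x2
    for n in range(_MAX_ITER):
        if a1 + y1 >= d.x_co[0] and y2 <= d.x_co[1]:
            return n
        y1 /= rho
        y2 /= rho
    raise ValueError(f"no admissible start x_re + x/rho^n found for x={(x1, x2)}")


def _orbit_from(x1: float, x2: float, n: int, params: ModelParams) -> tuple[float, float]:
    """f^n applied to (x1, x2) with plain-float arithmetic (hot loop)."""
    a1, a2, g = params.a1, params.a2, params.gamma
    for _ in range(n):
        x1, x2 = (
            2.0 * x1 * a1 / (a1 + x1 + g * x2),
            2.0 * x2 * a2 / (a2 + g * x1 + x2),
        )
    return x1, x2


def compute_H(
    x,
    params: ModelParams,
    tol: float = 1e-10,
    max_iter: int = _MAX_ITER,
    return_differences: bool = False,
):
    """Evaluate H(x) = lim_n f^n(x_re + x/rho^n).

    The perturbation x/rho^n is computed by repeated division (rho^n is
    never formed).  Iteration stops when the sup-norm of successive values
    drops below ``tol``; the proof's geometric decay at rate 1/rho makes the
    successive difference a tail bound up to a constant.  H(0) = x_re
    exactly.  If ``x1 < 0`` the start may initially leave the quadrant;
    iteration begins at the smallest n placing the start in the
    forward-invariant set.

    Returns a :class:`LimitEvaluation`, plus the successive-difference array
    if ``return_differences``.
    """
    x1, x2 = float(x[0]), float(x[1])
    if x2 < 0:
        raise ValueError("H is defined on R x R_+; second coordinate must be >= 0")
    d = derive_constants(params)
    if not d.coexistence:
        raise ValueError("H evaluation requires the coexistence condition")
    a1, rho = params.a1, d.rho

    if x1 == 0.0 and x2 == 0.0:
        ev = LimitEvaluation((x1, x2), (a1, 0.0), 0, 0.0, True)
        return (ev, np.array([])) if return_differences else ev

    n0 = _admissible_start_n(x1, x2, d)
    y1, y2 = x1, x2
    for _ in range(n0):
        y1 /= rho
        y2 /= rho

    prev = _orbit_from(a1 + y1, y2, n0, params)
    diffs = []
    converged = False
    last = math.inf
    n = n0
    while n < max_iter:
        n += 1
        y1 /= rho
        y2 /= rho
        cur = _orbit_from(a1 + y1, y2, n, params)
        last = max(abs(cur[0] - prev[0]), abs(cur[1] - prev[1]))
        diffs.append(last)
        prev = cur
        if last < tol:
            converged = True
            break

    ev = LimitEvaluation((x1, x2), prev, n, last, converged)
    return (ev, np.asarray(diffs)) if return_differences else ev


def h_convergence_differences(x, params: ModelParams, n_max: int = 80) -> np.ndarray:
    """Sup-norm successive differences of the H iterates, for rate studies.

    The proof bounds them by C*rho^-n, so a log-linear regression against n
    has slope approximately -log(rho).
    """
    _, diffs = compute_H(x, params, tol=0.0, max_iter=n_max, return_differences=True)
    return diffs


def abel_residual(x, params: ModelParams, tol: float = 1e-10) -> float:
    """Residual of the Abel equation, ||H(x) - f(H(x/rho))||_inf.

    Identically zero in exact arithmetic; computed at tolerance ``tol`` it
    serves as a self-consistency diagnostic of the H evaluation.
    """
    d = derive_constants(params)
    hx = compute_H(x, params, tol=tol).value
    hdamped = compute_H((x[0] / d.rho, x[1] / d.rho), params, tol=tol).value
    fh = f_map(hdamped, params)
    return max(abs(hx[0] - fh[0]), abs(hx[1] - fh[1]))


def h_grid(
    w_values,
    x1_values,
    params: ModelParams,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Tabulate H over a grid of mutant weights w >= 0 and resident offsets x1.

    One row per (x1, w) pair with columns x1, w, H1, H2, iterations,
    last_increment, converged.  Individual failed evaluations are flagged
    (converged=False, NaN values) rather than aborting the table.  Supports
    the numerical observation that H is flat in the resident offset x1.
    """
    rows = []
    for x1 in x1_values:
        for w in w_values:
            try:
                ev = compute_H((x1, w), params, tol=tol)
                rows.append(
                    dict(
                        x1=x1,
                        w=w,
                        H1=ev.value[0],
                        H2=ev.value[1],
                        iterations=ev.iterations,
                        last_increment=ev.last_increment,
                        converged=ev.converged,
                    )
                )
            except ValueError:
                rows.append(
                    dict(
                        x1=x1,
                        w=w,
                        H1=np.nan,
                        H2=np.nan,
                        iterations=0,
                        last_increment=np.nan,
                        converged=False,
                    )
                )
    return pd.DataFrame(rows)


def auxiliary_recursion(x: float, C: float, rho: float, n: int) -> np.ndarray:
    """Quadratic comparison recursion x_{m,n} = rho*x_{m-1,n}*(1 + C*x_{m-1,n}).

    Started from x_{0,n} = x/rho^n; returns the full sequence m = 0..n.
    With C = 0 it is the linear recursion x*rho^(m-n); for C > 0 it is
    bounded by phi_inverse(C*x)/C * rho^(m-n) via the Schroeder conjugacy.
    """
    if x < 0 or C < 0:
        raise ValueError("x and C must be nonnegative")
    if rho <= 1:
        raise ValueError("rho must exceed 1")
    out = np.empty(n + 1)
    v = x
    for _ in range(n):
        v /= rho
    out[0] = v
    for m in range(1, n + 1):
        v = rho * v * (1.0 + C * v)
        out[m] = v
    return out


class SchroederFunction:
    """Schroeder function of the inverse parabola f(x) = sqrt(1/4 + s*x) - 1/2.

    With s = 1/rho in (0, 1), phi(x) = lim_n f^n(x)/s^n exists, is strictly
    increasing with phi(0) = 0 and phi'(0+) = 1, and solves
    phi(f(x)) = s*phi(x).  Its inverse linearises the parabola
    p(y) = rho*y*(1+y): p(y) = phi_inverse(rho*phi(y)).

    The iteration uses the cancellation-free form
    f(t) = s*t / (sqrt(1/4 + s*t) + 1/2), which is exact near 0 where the
    textbook form loses all significant digits.  The inverse is computed by
    bisection on a geometrically grown bracket.  Evaluations are memoised
    on exact float inputs.
    """

    def __init__(self, rho: float, tol: float = 1e-14):
        if rho <= 1:
            raise ValueError("rho must exceed 1")
        self.rho = float(rho)
        self.s = 1.0 / self.rho
        self.tol = tol
        self._cache: dict[float, float] = {0.0: 0.0}

    def map(self, x: float) -> float:
        """The contraction f(x) = sqrt(1/4 + s*x) - 1/2 on [0, inf)."""
        return self.s * x / (math.sqrt(0.25 + self.s * x) + 0.5)

    def __call__(self, x: float) -> float:
        x = float(x)
        if x < 0:
            raise ValueError("phi is defined on [0, inf)")
        cached = self._cache.get(x)
        if cached is not None:
            return cached
        t, scale = x, 1.0
        val = x
        for _ in range(_MAX_ITER):
            t = self.map(t)
            scale *= self.rho
            new = t * scale
            if abs(new - val) <= self.tol * max(abs(new), 1e-300):
                val = new
                break
            val = new
        self._cache[x] = val
        return val

    def inverse(self, y: float, xtol: float = 1e-12) -> float:
        """phi^{-1}(y) by monotone bisection; bracket grown geometrically."""
        y = float(y)
        if y < 0:
            raise ValueError("phi inverse is defined on [0, inf)")
        if y == 0.0:
            return 0.0
        hi = max(y, 1.0)
        while self(hi) < y:
            hi *= 2.0
            if hi > 1e300:
                raise RuntimeError("phi inverse bracket growth failed")
        lo = 0.0
        while hi - lo > xtol * max(1.0, hi):
            mid = 0.5 * (lo + hi)
            if self(mid) < y:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


def schroeder_phi(x: float, rho: float, tol: float = 1e-14) -> tuple[float, SchroederFunction]:
    """Evaluate phi(x) and return the function object (with .inverse)."""
    fn = SchroederFunction(rho, tol=tol)
    return fn(x), fn
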