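"""Core of the two-type Bare Bones evolution model.

A resident (wild-type) and a mutant population of binary-splitting cells
compete in a habitat of carrying capacity ``K``.  Given the current counts
``(Z1, Z2)`` each resident splits into two with probability
``a1*K / (a1*K + Z1 + gamma*Z2)`` and each mutant with probability
``a2*K / (a2*K + gamma*Z1 + Z2)``, independently; otherwise it leaves no
offspring.  On the density scale ``x = Z/K`` the conditional one-step mean
defines the deterministic map

    f(x) = (x1 * m1(x), x2 * m2(x)),   m_i(x) = 2 * p_i(x),

whose fixed points organise the global dynamics: total extinction ``(0,0)``,
the monomorphic equilibria ``(a1,0)`` and ``(0,a2)``, and the coexistence
point ``x_co = ((a1-g*a2)/(1-g^2), (a2-g*a1)/(1-g^2))``.  The mutant is
initially supercritical with mean ``rho = 2*a2/(a2 + gamma*a1) > 1`` and the
establishment time scale is ``b*log(K)`` with ``b = 1/log(rho)``.

This module holds the parameter containers, per-capita laws, the map ``f``,
its translation ``g`` centred at the resident equilibrium, Jacobians and
fixed-point classification.  All other modules build on it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize

__all__ = [
    "ModelParams",
    "DerivedModel",
    "derive_constants",
    "splitting_probabilities",
    "count_splitting_probabilities",
    "offspring_means",
    "f_map",
    "g_map",
    "iterate_f",
    "jacobian_f",
    "classify_fixed_points",
]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters.

    a1, a2 : carrying-capacity coefficients of resident and mutant (>0).
    gamma  : cross-type interaction coefficient, strictly in (0, 1) — a cell
             encroaches less on the reproduction of the other type than on
             its own.
    K      : carrying capacity (positive integer); optional for purely
             deterministic computations.
    """

    a1: float
    a2: float
    gamma: float
    K: int | None = None

    def __post_init__(self) -> None:
        if not self.a1 > 0:
            raise ValueError(f"a1 must be > 0, got {self.a1}")
        if not self.a2 > 0:
            raise ValueError(f"a2 must be > 0, got {self.a2}")
        if not 0 < self.gamma < 1:
            raise ValueError(f"gamma must lie strictly in (0, 1), got {self.gamma}")
        if self.K is not None:
            if int(self.K) != self.K or self.K < 1:
                raise ValueError(f"K must be a positive integer, got {self.K}")
            object.__setattr__(self, "K", int(self.K))

    @property
    def coexistence(self) -> bool:
        """Condition C: both coordinates of x_co positive."""
        return (self.a1 - self.gamma * self.a2 > 0) and (
            self.a2 - self.gamma * self.a1 > 0
        )

    @property
    def supercritical(self) -> bool:
        """Whether the invading mutant is supercritical at the resident equilibrium."""
        return self.a2 > self.gamma * self.a1

    def require_K(self) -> int:
        if self.K is None:
            raise ValueError("this operation requires the carrying capacity K")
        return self.K

    def with_K(self, K: int) -> "ModelParams":
        return ModelParams(self.a1, self.a2, self.gamma, K)


@dataclass(frozen=True)
class DerivedModel:
    """Constants derived from :class:`ModelParams`.

    rho        : mutant offspring mean at the resident equilibrium, > 1 under
                 supercriticality.
    b          : establishment time constant 1/log(rho).
    x_ex, x_re, x_mu, x_co : the four fixed points of the density map.
    coexistence: condition C flag.
    rho_tilde  : numerically estimated supremum of the row-sum (l-infinity
                 operator) norm of the Jacobian of f over the quadrant;
                 lies in (rho, 2].
    """

    params: ModelParams
    rho: float
    b: float
    x_ex: tuple[float, float]
    x_re: tuple[float, float]
    x_mu: tuple[float, float]
    x_co: tuple[float, float]
    coexistence: bool
    rho_tilde: float

    @property
    def fixed_points(self) -> dict[str, tuple[float, float]]:
        return {
            "x_ex": self.x_ex,
            "x_re": self.x_re,
            "x_mu": self.x_mu,
            "x_co": self.x_co,
        }

    def to_dict(self) -> dict:
        p = self.params
        return {
            "a1": p.a1,
            "a2": p.a2,
            "gamma": p.gamma,
            "K": p.K,
            "rho": self.rho,
            "b": self.b,
            "x_ex": list(self.x_ex),
            "x_re": list(self.x_re),
            "x_mu": list(self.x_mu),
            "x_co": list(self.x_co),
            "coexistence": self.coexistence,
            "rho_tilde": self.rho_tilde,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _check_state(x) -> tuple[float, float]:
    x1, x2 = float(x[0]), float(x[1])
    if x1 < 0 or x2 < 0:
        raise ValueError(f"density state must be in the nonnegative quadrant, got {(x1, x2)}")
    return x1, x2


def splitting_probabilities(x, params: ModelParams) -> tuple[float, float]:
    """Per-capita splitting probabilities at density state ``x = (x1, x2)``.

    p1 = a1/(a1 + x1 + gamma*x2),  p2 = a2/(a2 + gamma*x1 + x2); both in (0, 1].
    """
    x1, x2 = _check_state(x)
    p = params
    p1 = p.a1 / (p.a1 + x1 + p.gamma * x2)
    p2 = p.a2 / (p.a2 + p.gamma * x1 + x2)
    return p1, p2


def count_splitting_probabilities(z, params: ModelParams) -> tuple[float, float]:
    """Splitting probabilities on the count scale ``z = (Z1, Z2)``.

    p1 = a1*K/(a1*K + Z1 + gamma*Z2), p2 = a2*K/(a2*K + gamma*Z1 + Z2).
    At ``Z = (a1*K, 0)`` the resident probability is exactly 1/2.
    """
    K = params.require_K()
    z1, z2 = float(z[0]), float(z[1])
    if z1 < 0 or z2 < 0:
        raise ValueError("population counts must be nonnegative")
    g = params.gamma
    p1 = params.a1 * K / (params.a1 * K + z1 + g * z2)
    p2 = params.a2 * K / (params.a2 * K + g * z1 + z2)
    return p1, p2


def offspring_means(x, params: ModelParams) -> tuple[float, float]:
    """Conditional offspring means m_i(x) = 2*p_i(x); both equal 1 at x_co."""
    p1, p2 = splitting_probabilities(x, params)
    return 2.0 * p1, 2.0 * p2


def f_map(x, params: ModelParams) -> tuple[float, float]:
    """One step of the deterministic density dynamics, f(x) = x * m(x)."""
    x1, x2 = _check_state(x)
    p = params
    return (
        2.0 * x1 * p.a1 / (p.a1 + x1 + p.gamma * x2),
        2.0 * x2 * p.a2 / (p.a2 + p.gamma * x1 + x2),
    )


def iterate_f(x, n: int, params: ModelParams) -> tuple[float, float]:
    """n-fold composition f^n(x) (n >= 0)."""
    if n < 0:
        raise ValueError("n must be >= 0; f is not invertible")
    y = _check_state(x)
    for _ in range(n):
        y = f_map(y, params)
    return y


def g_map(x, params: ModelParams) -> tuple[float, float]:
    """Translation of f centred at the resident equilibrium.

    g(x) = f(x_re + x) - x_re with x_re = (a1, 0); g(0) = 0 and the Jacobian
    of g at the origin is the matrix A = [[1/2, -gamma/2], [0, rho]].
    """
    x1, x2 = float(x[0]), float(x[1])
    s1, s2 = params.a1 + x1, x2
    if s1 < 0 or s2 < 0:
        raise ValueError(
            f"g domain requires x_re + x in the nonnegative quadrant, got {(s1, s2)}"
        )
    f1, f2 = f_map((s1, s2), params)
    return f1 - params.a1, f2


def jacobian_f(x, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of f at x (2x2 array).

    At x_re = (a1, 0) it equals [[1/2, -gamma/2], [0, rho]].
    """
    x1, x2 = _check_state(x)
    a1, a2, g = params.a1, params.a2, params.gamma
    d1 = a1 + x1 + g * x2
    d2 = a2 + g * x1 + x2
    return np.array(
        [
            [2 * a1 * (a1 + g * x2) / d1**2, -2 * a1 * g * x1 / d1**2],
            [-2 * a2 * g * x2 / d2**2, 2 * a2 * (a2 + g * x1) / d2**2],
        ]
    )


def _jacobian_row_sum_max(x1, x2, params: ModelParams):
    """Row-sum (l-infinity operator) norm of the Jacobian, vectorised."""
    a1, a2, g = params.a1, params.a2, params.gamma
    d1 = a1 + x1 + g * x2
    d2 = a2 + g * x1 + x2
    r1 = 2 * a1 * (a1 + g * (x1 + x2)) / d1**2
    r2 = 2 * a2 * (a2 + g * (x1 + x2)) / d2**2
    return np.maximum(r1, r2)


def _rho_tilde(params: ModelParams, grid: int = 121) -> float:
    """Numerical sup of ||Df(x)||_inf over the quadrant.

    The row sums are maximal near the axes and decay like 1/x away from the
    origin, so a grid over [0, 4*a1] x [0, 4*a2] followed by local refinement
    brackets the supremum to ~1e-6.
    """
    u = np.linspace(0.0, 4 * params.a1, grid)
    v = np.linspace(0.0, 4 * params.a2, grid)
    X1, X2 = np.meshgrid(u, v, indexing="ij")
    vals = _jacobian_row_sum_max(X1, X2, params)
    i, j = np.unravel_index(np.argmax(vals), vals.shape)
    best = float(vals[i, j])

    res = optimize.minimize(
        lambda p: -_jacobian_row_sum_max(p[0], p[1], params),
        x0=[X1[i, j], X2[i, j]],
        method="Powell",
        bounds=[(0.0, 4 * params.a1), (0.0, 4 * params.a2)],
        options={"xtol": 1e-10, "ftol": 1e-12},
    )
    return max(best, float(-res.fun))


@lru_cache(maxsize=256)
def derive_constants(params: ModelParams) -> DerivedModel:
    """Derive rho, b, the four fixed points, coexistence flag and rho_tilde.

    Requires supercriticality a2 > gamma*a1 (else rho <= 1 and b is
    undefined).  The coexistence flag may still be False; callers that need
    condition C must check it.
    """
    if not params.supercritical:
        raise ValueError(
            "supercriticality a2 > gamma*a1 is required for establishment analysis"
        )
    a1, a2, g = params.a1, params.a2, params.gamma
    rho = 2 * a2 / (a2 + g * a1)
    b = 1.0 / math.log(rho)
    denom = 1.0 - g * g
    x_co = ((a1 - g * a2) / denom, (a2 - g * a1) / denom)
    return DerivedModel(
        params=params,
        rho=rho,
        b=b,
        x_ex=(0.0, 0.0),
        x_re=(a1, 0.0),
        x_mu=(0.0, a2),
        x_co=x_co,
        coexistence=params.coexistence,
        rho_tilde=_rho_tilde(params),
    )


def classify_fixed_points(derived: DerivedModel) -> dict[str, str | None]:
    """Stability labels from Jacobian eigenvalue moduli at each fixed point.

    'stable' if the spectral radius is < 1, 'unstable' if all eigenvalue
    moduli are > 1, 'saddle' otherwise.  Under coexistence: x_co stable,
    x_ex unstable, x_re and x_mu saddles.  Without coexistence the x_co
    classification is suppressed (None) since the point leaves the quadrant.
    """
    labels: dict[str, str | None] = {}
    for name, pt in derived.fixed_points.items():
        if name == "x_co" and not derived.coexistence:
            labels[name] = None
            continue
        eig = np.linalg.eigvals(jacobian_f(pt, derived.params))
        moduli = np.abs(eig)
        if np.all(moduli < 1):
            labels[name] = "stable"
        elif np.all(moduli > 1):
            labels[name] = "unstable"
        else:
            labels[name] = "saddle"
    return labels
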