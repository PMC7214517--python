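"""Exact stochastic simulation of the two-type splitting process.

Four processes can be driven by one seeded uniform stream:

* ``Z``  — the true density-dependent process: individual j of type i in
  generation n splits iff its uniform variate falls below the state
  dependent threshold (a_i*K over the weighted total).
* ``Y``  — the linearised Galton-Watson pair frozen at the resident
  equilibrium: resident threshold 1/2 (critical), mutant threshold rho/2
  (supercritical), starts ([a1*K], 1).
* ``L``, ``U`` — bounding Galton-Watson processes with constant rates
  r-_K < 1 < r+_K and rho-_K < rho < rho+_K chosen so that, while Z stays
  inside a polynomial tube around the resident equilibrium (up to the exit
  time tau), the shared uniforms force L <= Z <= U pathwise, and
  L2 <= Y2 <= U2 always.

Uniform variates are generated in a fixed order keyed by (type, generation,
individual index); every process consumes the prefix of length equal to its
current population, which realises the common-variate coupling without
storing the stream.

A distributionally equivalent binomial-draw mode (``simulate_fast``)
serves Monte-Carlo ensembles where the coupling is not needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, derive_constants, f_map, splitting_probabilities

__all__ = [
    "PopulationState",
    "Alphas",
    "alpha_preset",
    "bounding_rates",
    "CoupledTrajectories",
    "ExitTimes",
    "PopulationCapExceeded",
    "step_populations",
    "simulate_coupled",
    "simulate_fast",
    "martingale_limit_sample",
    "exit_times",
    "noise_decomposition",
    "noise_one_step_ensemble",
]

DEFAULT_CAP = 10**8


class PopulationCapExceeded(RuntimeError):
    """Raised when a supercritical run blows past the population cap.

    Carries the partial trajectory computed so far in ``partial``.
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class PopulationState:
    """Integer population counts at one generation."""

    Z1: int
    Z2: int
    generation: int = 0

    def __post_init__(self):
        if self.Z1 < 0 or self.Z2 < 0 or self.generation < 0:
            raise ValueError("counts and generation index must be nonnegative")


@dataclass(frozen=True)
class Alphas:
    """Tube exponents (alpha_1l, alpha_1u, alpha_2), each in (c, 1).

    alpha_1l / alpha_1u size the lower / upper resident tube half-widths
    a1*K^alpha, alpha_2 the mutant ceiling K^alpha_2.
    """

    alpha_1l: float
    alpha_1u: float
    alpha_2: float

    def __post_init__(self):
        for name in ("alpha_1l", "alpha_1u", "alpha_2"):
            v = getattr(self, name)
            if not 0.5 < v < 1:
                raise ValueError(f"{name} must lie in (1/2, 1), got {v}")

    def validate_against(self, c: float) -> None:
        for name in ("alpha_1l", "alpha_1u", "alpha_2"):
            v = getattr(self, name)
            if not c < v < 1:
                raise ValueError(f"{name}={v} must lie in (c, 1) with c={c}")


def alpha_preset(kind: str, c: float = 0.9) -> Alphas:
    """Exponent presets matching the three exit-time arguments.

    'equal'          — all three equal (mutant-ceiling exit bound),
    'resident_lower' — alpha_1u = alpha_2 < alpha_1l (lower resident exit),
    'resident_upper' — alpha_2 = alpha_1l < alpha_1u (upper resident exit).
    """
    lo = c + (1 - c) / 3
    mid = c + (1 - c) / 2
    hi = c + 2 * (1 - c) / 3
    if kind == "equal":
        return Alphas(mid, mid, mid)
    if kind == "resident_lower":
        return Alphas(hi, lo, lo)
    if kind == "resident_upper":
        return Alphas(lo, hi, lo)
    raise ValueError(f"unknown preset {kind!r}")


def bounding_rates(params: ModelParams, alphas: Alphas) -> dict[str, float]:
    """Constant offspring means of the bounding processes L and U.

    r-_K  = 2*a1 / (a1 + a1*(1 + K^(a1u-1)) + gamma*K^(a2-1))  < 1
    r+_K  = 2*a1 / (a1 + a1*(1 - K^(a1l-1)))                   > 1
    rho-_K = 2*a2 / (a2 + gamma*a1*(1 + K^(a1u-1)) + K^(a2-1)) < rho
    rho+_K = 2*a2 / (a2 + gamma*a1*(1 - K^(a1l-1)))            > rho

    The lower resident rate feels the mutant ceiling through the
    gamma*K^(alpha_2-1) term; the upper one does not (the mutant only
    depresses resident reproduction), mirroring the asymmetry of the
    construction.
    """
    K = params.require_K()
    a1, a2, g = params.a1, params.a2, params.gamma
    e1l = K ** (alphas.alpha_1l - 1)
    e1u = K ** (alphas.alpha_1u - 1)
    e2 = K ** (alphas.alpha_2 - 1)
    return {
        "r_minus": 2 * a1 / (a1 + a1 * (1 + e1u) + g * e2),
        "r_plus": 2 * a1 / (a1 + a1 * (1 - e1l)),
        "rho_minus": 2 * a2 / (a2 + g * a1 * (1 + e1u) + e2),
        "rho_plus": 2 * a2 / (a2 + g * a1 * (1 - e1l)),
    }


@dataclass
class CoupledTrajectories:
    """Aligned integer population paths driven by shared uniform variates.

    Arrays have shape (horizon+1, 2); ``L``/``U`` are None when the run was
    made without the bounding processes.  ``seed`` plus the deterministic
    (type, generation, individual-index) stream order regenerate every
    variate.
    """

    Z: np.ndarray
    Y: np.ndarray
    L: np.ndarray | None
    U: np.ndarray | None
    params: ModelParams
    seed: int
    c: float
    alphas: Alphas | None
    horizon: int

    def to_frame(self) -> pd.DataFrame:
        data = {"generation": np.arange(self.Z.shape[0])}
        for name, arr in (("Z", self.Z), ("Y", self.Y), ("L", self.L), ("U", self.U)):
            if arr is not None:
                data[f"{name}1"] = arr[:, 0]
                data[f"{name}2"] = arr[:, 1]
        return pd.DataFrame(data)

    def metadata(self) -> dict:
        p = self.params
        return {
            "seed": int(self.seed),
            "a1": p.a1,
            "a2": p.a2,
            "gamma": p.gamma,
            "K": p.K,
            "mode": "coupled" if self.L is not None else "coupled_zy",
            "horizon": self.horizon,
            "c": self.c,
            "alphas": None
            if self.alphas is None
            else [self.alphas.alpha_1l, self.alphas.alpha_1u, self.alphas.alpha_2],
        }


@dataclass(frozen=True)
class ExitTimes:
    """First-passage generations out of the tube around the resident equilibrium.

    tau_1l — first n with Z1(n) <= a1*(K - K^alpha_1l)
    tau_1u — first n with Z1(n) >= a1*(K + K^alpha_1u)
    tau_2  — first n with Z2(n) >= K^alpha_2

    ``None`` means not reached within the horizon; ``tau`` is the minimum
    under None-as-infinity ordering.
    """

    tau_1l: int | None
    tau_1u: int | None
    tau_2: int | None
    horizon: int

    @property
    def tau(self) -> int | None:
        reached = [t for t in (self.tau_1l, self.tau_1u, self.tau_2) if t is not None]
        return min(reached) if reached else None


def step_populations(
    state: PopulationState, params: ModelParams, u1: np.ndarray, u2: np.ndarray
) -> PopulationState:
    """One exact generation of Z given per-individual uniforms.

    Resident j splits iff u1[j] <= a1*K/(a1*K + Z1 + gamma*Z2); mutant j iff
    u2[j] <= a2*K/(a2*K + gamma*Z1 + Z2).  Requires one uniform per
    individual — fewer is an error, to keep couplings from silently breaking.
    """
    K = params.require_K()
    u1 = np.asarray(u1)
    u2 = np.asarray(u2)
    if u1.shape[0] < state.Z1 or u2.shape[0] < state.Z2:
        raise ValueError(
            f"need >= ({state.Z1}, {state.Z2}) uniforms, got ({u1.shape[0]}, {u2.shape[0]})"
        )
    g = params.gamma
    thr1 = params.a1 * K / (params.a1 * K + state.Z1 + g * state.Z2)
    thr2 = params.a2 * K / (params.a2 * K + g * state.Z1 + state.Z2)
    n1 = 2 * int(np.count_nonzero(u1[: state.Z1] <= thr1))
    n2 = 2 * int(np.count_nonzero(u2[: state.Z2] <= thr2))
    return PopulationState(n1, n2, state.generation + 1)


def simulate_coupled(
    params: ModelParams,
    horizon: int,
    seed: int,
    alphas: Alphas | None = None,
    c: float = 0.9,
    with_bounds: bool = True,
    cap: int = DEFAULT_CAP,
) -> CoupledTrajectories:
    """Simulate Z, Y (and optionally L, U) on shared uniform variates.

    All processes start at ([a1*K], 1) and consume the same U(n, j), V(n, j)
    for the same (generation, individual index).  Threshold monotonicity
    rho-_K < rho < rho+_K then yields L2 <= Y2 <= U2 surely and the
    componentwise bound L <= Z <= U on generations before the exit time.

    Raises :class:`PopulationCapExceeded` (with the partial trajectory) if
    any process outgrows ``cap``.
    """
    K = params.require_K()
    d = derive_constants(params)
    if not d.coexistence:
        raise ValueError("coupled simulation requires the coexistence condition")
    if not 0.5 < c < 1:
        raise ValueError(f"c must lie in (1/2, 1), got {c}")
    if with_bounds:
        if alphas is None:
            alphas = alpha_preset("equal", c)
        alphas.validate_against(c)

    a1, a2, g = params.a1, params.a2, params.gamma
    rho = d.rho
    rng = np.random.default_rng(seed)

    z0 = np.array([int(a1 * K), 1], dtype=np.int64)
    Z = np.empty((horizon + 1, 2), dtype=np.int64)
    Y = np.empty_like(Z)
    Z[0] = z0
    Y[0] = z0
    if with_bounds:
        rates = bounding_rates(params, alphas)
        L = np.empty_like(Z)
        U = np.empty_like(Z)
        L[0] = z0
        U[0] = z0
        thr_L = (rates["r_minus"] / 2, rates["rho_minus"] / 2)
        thr_U = (rates["r_plus"] / 2, rates["rho_plus"] / 2)
    else:
        L = U = None

    def _partial(n):
        return CoupledTrajectories(
            Z[: n + 1],
            Y[: n + 1],
            None if L is None else L[: n + 1],
            None if U is None else U[: n + 1],
            params,
            seed,
            c,
            alphas,
            n,
        )

    for n in range(horizon):
        pops1 = [Z[n, 0], Y[n, 0]] + ([L[n, 0], U[n, 0]] if with_bounds else [])
        pops2 = [Z[n, 1], Y[n, 1]] + ([L[n, 1], U[n, 1]] if with_bounds else [])
        if max(max(pops1), max(pops2)) > cap:
            raise PopulationCapExceeded(
                f"population exceeded cap {cap} at generation {n}", partial=_partial(n)
            )
        u = rng.random(int(max(pops1)))
        v = rng.random(int(max(pops2)))

        thr_z1 = a1 * K / (a1 * K + Z[n, 0] + g * Z[n, 1])
        thr_z2 = a2 * K / (a2 * K + g * Z[n, 0] + Z[n, 1])
        Z[n + 1, 0] = 2 * np.count_nonzero(u[: Z[n, 0]] <= thr_z1)
        Z[n + 1, 1] = 2 * np.count_nonzero(v[: Z[n, 1]] <= thr_z2)
        Y[n + 1, 0] = 2 * np.count_nonzero(u[: Y[n, 0]] <= 0.5)
        Y[n + 1, 1] = 2 * np.count_nonzero(v[: Y[n, 1]] <= rho / 2)
        if with_bounds:
            L[n + 1, 0] = 2 * np.count_nonzero(u[: L[n, 0]] <= thr_L[0])
            L[n + 1, 1] = 2 * np.count_nonzero(v[: L[n, 1]] <= thr_L[1])
            U[n + 1, 0] = 2 * np.count_nonzero(u[: U[n, 0]] <= thr_U[0])
            U[n + 1, 1] = 2 * np.count_nonzero(v[: U[n, 1]] <= thr_U[1])

    return CoupledTrajectories(Z, Y, L, U, params, seed, c, alphas, horizon)


def simulate_fast(
    params: ModelParams,
    horizon: int,
    reps: int,
    seed: int,
    start: tuple[int, int] | None = None,
    cap: int = DEFAULT_CAP,
) -> np.ndarray:
    """Binomial-draw ensemble of Z trajectories, shape (horizon+1, reps, 2).

    Per generation the number of splitters is binomial with the state
    dependent probability, so each trajectory's law coincides with the
    per-individual construction; the coupling across processes is not
    represented.
    """
    K = params.require_K()
    a1, a2, g = params.a1, params.a2, params.gamma
    rng = np.random.default_rng(seed)
    if start is None:
        start = (int(a1 * K), 1)
    out = np.empty((horizon + 1, reps, 2), dtype=np.int64)
    out[0, :, 0] = start[0]
    out[0, :, 1] = start[1]
    z1 = out[0, :, 0].copy()
    z2 = out[0, :, 1].copy()
    for n in range(horizon):
        p1 = a1 * K / (a1 * K + z1 + g * z2)
        p2 = a2 * K / (a2 * K + g * z1 + z2)
        z1 = 2 * rng.binomial(z1, p1)
        z2 = 2 * rng.binomial(z2, p2)
        if z1.max() > cap or z2.max() > cap:
            raise PopulationCapExceeded(
                f"population exceeded cap {cap} at generation {n + 1}",
                partial=out[: n + 1],
            )
        out[n + 1, :, 0] = z1
        out[n + 1, :, 1] = z2
    return out


def martingale_limit_sample(
    params: ModelParams,
    n_gens: int,
    reps: int,
    seed: int,
    min_damping: float = 0.01,
) -> np.ndarray:
    """Sample of W approximants rho^(-n) * Y2(n) from single-ancestor runs.

    Y2 is the supercritical Galton-Watson process with splitting probability
    rho/2; rho^(-n)*Y2(n) is a unit-mean martingale whose a.s. limit W has
    an atom at 0 of mass 2/rho - 1 (the lineage's extinction probability).
    ``n_gens`` must be large enough that rho^(-n_gens) < ``min_damping``.
    """
    d = derive_constants(params)
    rho = d.rho
    if rho ** (-n_gens) >= min_damping:
        raise ValueError(
            f"n_gens={n_gens} too small: rho^-n = {rho ** (-n_gens):.3g} >= {min_damping}"
        )
    rng = np.random.default_rng(seed)
    y = np.ones(reps, dtype=np.int64)
    for _ in range(n_gens):
        y = 2 * rng.binomial(y, rho / 2)
    return y * rho ** (-float(n_gens))


def exit_times(traj: np.ndarray, params: ModelParams, alphas: Alphas) -> ExitTimes:
    """First-passage generations of a Z trajectory out of the K^alpha tube.

    ``traj`` has shape (n+1, 2) (counts).  Crossings are searched from
    generation 1 onward; ``None`` marks thresholds not reached within the
    trajectory.
    """
    traj = np.asarray(traj)
    if traj.ndim != 2 or traj.shape[0] < 1:
        raise ValueError("trajectory must be a nonempty (n+1, 2) array")
    K = params.require_K()
    a1 = params.a1
    lo1 = a1 * (K - K**alphas.alpha_1l)
    hi1 = a1 * (K + K**alphas.alpha_1u)
    hi2 = K**alphas.alpha_2

    def first(mask: np.ndarray) -> int | None:
        idx = np.flatnonzero(mask[1:])
        return int(idx[0]) + 1 if idx.size else None

    return ExitTimes(
        tau_1l=first(traj[:, 0] <= lo1),
        tau_1u=first(traj[:, 0] >= hi1),
        tau_2=first(traj[:, 1] >= hi2),
        horizon=traj.shape[0] - 1,
    )


def noise_decomposition(traj: np.ndarray, params: ModelParams) -> pd.DataFrame:
    """Per-generation noise record eta(n+1) = sqrt(K) * (X(n+1) - f(X(n))).

    The decomposition X(n+1) = f(X(n)) + eta(n+1)/sqrt(K) is an identity;
    conditionally on X(n) the noise has zero mean and per-coordinate
    variance 4*x_i*p_i(x)*(1 - p_i(x)).
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2 or traj.shape[0] < 2:
        raise ValueError("trajectory must contain at least two generations")
    K = params.require_K()
    X = traj / K
    rows = []
    sqrtK = math.sqrt(K)
    for n in range(traj.shape[0] - 1):
        fx = f_map(X[n], params)
        eta1 = sqrtK * (X[n + 1, 0] - fx[0])
        eta2 = sqrtK * (X[n + 1, 1] - fx[1])
        rows.append(dict(generation=n + 1, eta1=eta1, eta2=eta2))
    return pd.DataFrame(rows)


def noise_one_step_ensemble(
    params: ModelParams, state, reps: int, seed: int
) -> dict[str, np.ndarray | float]:
    """One-step noise ensemble at a fixed density state.

    Rounds K*state to integer counts, draws ``reps`` one-step transitions and
    returns the eta samples together with the theoretical variances
    4*x_i*p_i*(1-p_i) evaluated at the realised density x = Z/K.
    """
    K = params.require_K()
    z = np.rint(np.asarray(state, dtype=float) * K).astype(np.int64)
    x = z / K
    p1, p2 = splitting_probabilities(x, params)
    fx = f_map(x, params)
    rng = np.random.default_rng(seed)
    s1 = 2 * rng.binomial(z[0], p1, size=reps) / K
    s2 = 2 * rng.binomial(z[1], p2, size=reps) / K
    sqrtK = math.sqrt(K)
    eta = np.column_stack([sqrtK * (s1 - fx[0]), sqrtK * (s2 - fx[1])])
    return {
        "eta": eta,
        "var_theory": (4 * x[0] * p1 * (1 - p1), 4 * x[1] * p2 * (1 - p2)),
        "state": (x[0], x[1]),
    }
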