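"""Mutant establishment: time scale, glued approximation, random initial condition.

The mutant lineage needs about n1 = [log_rho K] generations to reach size of
order K.  Around that time the density process X(n1 + n) is asymptotically
the deterministic flow f^n started at the *random* point

    chi(K) = H( rho^(-{log_rho K}) * (0, W) ),

where W is the martingale limit of the linearised mutant branching process
and {.} is the fractional part.  On {W = 0} the mutant fails and
chi(K) = x_re; establishment happens with probability 2*(1 - 1/rho).

This module computes the time indices, the glued trajectory (linearised
branching up to n_c = [log_rho K^c], deterministic flow after), chi(K),
Monte-Carlo and analytic establishment probabilities, and the paired
discrepancy between X(n1 + n) and f^n(chi(K)) across carrying capacities —
the finite-K face of the limit theory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelParams, derive_constants, iterate_f
from .limits import compute_H
from .simulate import simulate_coupled, simulate_fast

__all__ = [
    "TimeIndices",
    "time_indices",
    "glued_trajectory",
    "chi_K",
    "EstablishmentProbability",
    "establishment_probability",
    "EstablishmentResult",
    "establishment_experiment",
    "DiscrepancyReport",
    "limit_discrepancy",
]


@dataclass(frozen=True)
class TimeIndices:
    """n1 = [log_rho K], n_c = [log_rho K^c], and the fractional part {log_rho K}."""

    n1: int
    n_c: int
    frac: float


def time_indices(params: ModelParams, K: int | None = None, c: float = 0.9) -> TimeIndices:
    """Establishment time indices for capacity K (defaults to params.K)."""
    if K is None:
        K = params.require_K()
    if K < 2:
        raise ValueError("K must be >= 2")
    if not 0.5 < c < 1:
        raise ValueError(f"c must lie in (1/2, 1), got {c}")
    d = derive_constants(params)
    log_rho_K = math.log(K) / math.log(d.rho)
    n1 = math.floor(log_rho_K)
    n_c = math.floor(c * log_rho_K)
    return TimeIndices(n1=n1, n_c=n_c, frac=log_rho_K - n1)


def glued_trajectory(coupled, params: ModelParams, c: float = 0.9) -> np.ndarray:
    """Glued density approximation Z-tilde of the true density process.

    Z_tilde(n) = Y(n)/K for n <= n_c, and f^(n - n_c)(Y(n_c)/K) afterwards:
    the linearised branching carries the randomness through the early phase,
    the deterministic flow takes over once the mutant is of size K^c.
    Returns an array of shape (horizon+1, 2); the trajectory must reach n1.
    """
    K = params.require_K()
    ti = time_indices(params, K, c)
    Y = coupled.Y
    if Y.shape[0] - 1 < ti.n1:
        raise ValueError(
            f"coupled horizon {Y.shape[0] - 1} too short to reach n1={ti.n1}"
        )
    out = np.empty((Y.shape[0], 2))
    out[: ti.n_c + 1] = Y[: ti.n_c + 1] / K
    x = (Y[ti.n_c, 0] / K, Y[ti.n_c, 1] / K)
    for n in range(ti.n_c + 1, Y.shape[0]):
        x = iterate_f(x, 1, params)
        out[n] = x
    return out


def chi_K(w: float, params: ModelParams, K: int | None = None, tol: float = 1e-10) -> tuple[float, float]:
    """Random initial condition chi(K) = H(rho^(-{log_rho K}) * (0, w)).

    For w = 0 this is the resident equilibrium x_re; for w > 0 the mutant
    coordinate is positive.  When K is an exact power of rho the damping
    factor is 1 and chi = H((0, w)).
    """
    if w < 0:
        raise ValueError("w must be >= 0")
    ti = time_indices(params, K)
    d = derive_constants(params)
    damp = d.rho ** (-ti.frac)
    return compute_H((0.0, damp * w), params, tol=tol).value


@dataclass(frozen=True)
class EstablishmentProbability:
    estimate: float
    se: float
    mode: str
    reps: int | None
    warnings: tuple[str, ...] = ()


def establishment_probability(
    params: ModelParams,
    reps: int = 2000,
    seed: int | None = None,
    mode: str = "analytic",
    threshold_exponent: float = 0.5,
    c: float = 0.9,
) -> EstablishmentProbability:
    """Probability that the mutant establishes alongside the resident.

    Analytic mode returns the asymptotic survival probability
    2*(1 - 1/rho) of the linearised mutant lineage.  Monte-Carlo mode
    simulates ``reps`` trajectories to n1 = [log_rho K] and reports the
    fraction with Z2(n1) >= K^threshold_exponent (default sqrt(K), which
    separates the O(1)-extinct cluster from the Theta(K) cluster), with
    binomial standard error.
    """
    d = derive_constants(params)
    if not d.coexistence:
        raise ValueError("establishment analysis requires the coexistence condition")
    if mode == "analytic":
        return EstablishmentProbability(2 * (1 - 1 / d.rho), 0.0, "analytic", None)
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")
    K = params.require_K()
    if seed is None:
        raise ValueError("monte_carlo mode requires a seed")
    warnings = ()
    if reps < 100:
        warnings = (f"reps={reps} < 100: standard error will be large",)
    if not 0 < threshold_exponent < 1:
        raise ValueError("threshold_exponent must lie in (0, 1)")
    ti = time_indices(params, K, c)
    ens = simulate_fast(params, horizon=ti.n1, reps=reps, seed=seed)
    established = ens[ti.n1, :, 1] >= K**threshold_exponent
    p_hat = float(established.mean())
    se = math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / reps)
    return EstablishmentProbability(p_hat, se, "monte_carlo", reps, warnings)


@dataclass
class EstablishmentResult:
    """Per-replicate records of one coupled establishment experiment.

    ``records`` columns: rep, W_hat (= rho^-n_c * Y2(n_c)), established,
    chi1, chi2, X1_n1, X2_n1, and one ``diff[n]`` column per offset with the
    paired sup-norm difference |X(n1+n) - f^n(chi)|.
    """

    K: int
    n1: int
    n_c: int
    frac: float
    offsets: tuple[int, ...]
    records: pd.DataFrame
    summary: dict


def establishment_experiment(
    params: ModelParams,
    K: int,
    reps: int,
    seed: int,
    offsets=(0,),
    c: float = 0.9,
    tol: float = 1e-8,
    threshold_exponent: float = 0.5,
) -> EstablishmentResult:
    """Coupled replicates comparing X(n1 + n) with f^n(chi(K)) pairwise.

    Each replicate runs Z and Y on shared uniforms, takes its own W
    approximant rho^(-n_c) * Y2(n_c), forms chi from it, and records the
    paired sup-norm differences at the requested offsets (negative offsets
    via the Abel equation: f^n(chi) = H(rho^(n - frac) * (0, W))).
    """
    pk = params.with_K(K)
    d = derive_constants(pk)
    ti = time_indices(pk, K, c)
    offsets = tuple(int(n) for n in offsets)
    if ti.n1 + min(offsets) < 0:
        raise ValueError(f"offset {min(offsets)} reaches below generation 0")
    horizon = ti.n1 + max(0, max(offsets))
    rho = d.rho
    damp = rho ** (-ti.frac)
    seeds = np.random.SeedSequence(seed).generate_state(reps)

    rows = []
    for r in range(reps):
        traj = simulate_coupled(pk, horizon, seed=int(seeds[r]), c=c, with_bounds=False)
        w_hat = traj.Y[ti.n_c, 1] * rho ** (-float(ti.n_c))
        chi = compute_H((0.0, damp * w_hat), pk, tol=tol).value
        row = dict(
            rep=r,
            W_hat=w_hat,
            established=bool(traj.Z[ti.n1, 1] >= K**threshold_exponent),
            chi1=chi[0],
            chi2=chi[1],
            X1_n1=traj.Z[ti.n1, 0] / K,
            X2_n1=traj.Z[ti.n1, 1] / K,
        )
        for n in offsets:
            if n >= 0:
                pred = iterate_f(chi, n, pk)
            else:
                pred = compute_H((0.0, damp * rho**n * w_hat), pk, tol=tol).value
            x = traj.Z[ti.n1 + n] / K
            row[f"diff[{n}]"] = max(abs(x[0] - pred[0]), abs(x[1] - pred[1]))
        rows.append(row)

    records = pd.DataFrame(rows)
    ks = stats.ks_2samp(records["X2_n1"], records["chi2"])
    summary = {
        "K": K,
        "n1": ti.n1,
        "n_c": ti.n_c,
        "frac": ti.frac,
        "established_fraction": float(records["established"].mean()),
        "nonzero_W_fraction": float((records["W_hat"] > 0).mean()),
        "ks_stat_X2_vs_chi2": float(ks.statistic),
        "mean_diff": {n: float(records[f"diff[{n}]"].mean()) for n in offsets},
    }
    return EstablishmentResult(K, ti.n1, ti.n_c, ti.frac, offsets, records, summary)


@dataclass
class DiscrepancyReport:
    """Distances between the density process and the limit prediction, per K.

    per_offset: DataFrame with columns K, offset, mean_sup_diff.
    ks:         DataFrame with columns K, ks_stat (mutant coordinate at n1).
    """

    per_offset: pd.DataFrame
    ks: pd.DataFrame
    experiments: list[EstablishmentResult]


def limit_discrepancy(
    params: ModelParams,
    K_list,
    reps: int,
    offsets,
    seed: int,
    c: float = 0.9,
    tol: float = 1e-8,
) -> DiscrepancyReport:
    """Paired discrepancy X(n1+n) vs f^n(chi(K)) across carrying capacities.

    As K grows the mean paired sup-norm difference shrinks at every offset
    and the Kolmogorov-Smirnov distance between {X2(n1)} and {chi2(K)}
    decreases — the finite-K signature of convergence in probability.
    """
    child = np.random.SeedSequence(seed).generate_state(len(list(K_list)))
    experiments = []
    rows = []
    ks_rows = []
    for K, s in zip(K_list, child):
        exp = establishment_experiment(
            params, int(K), reps, int(s), offsets=offsets, c=c, tol=tol
        )
        experiments.append(exp)
        for n in exp.offsets:
            rows.append(dict(K=int(K), offset=n, mean_sup_diff=exp.summary["mean_diff"][n]))
        ks_rows.append(dict(K=int(K), ks_stat=exp.summary["ks_stat_X2_vs_chi2"]))
    return DiscrepancyReport(pd.DataFrame(rows), pd.DataFrame(ks_rows), experiments)
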