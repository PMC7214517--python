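"""Self-check battery behind the ``barebones validate`` subcommand.

Runs quick structural checks of the model at the given parameters: the
closed-form fixed points, the Jacobian at the resident equilibrium, the
Abel equation satisfied by the scaling limit H, the Schroeder functional
equation, and (when K is given) the pathwise coupling order of the
simulated processes.  Each check returns a pass flag and a measured value;
failures are collected rather than raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParams, derive_constants, f_map, jacobian_f, classify_fixed_points
from .limits import abel_residual, SchroederFunction
from .simulate import simulate_coupled, alpha_preset


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    value: float
    detail: str = ""


def run_checks(params: ModelParams, seed: int = 0, coupled_runs: int = 5) -> list[CheckResult]:
    d = derive_constants(params)
    out: list[CheckResult] = []

    resid = max(
        max(abs(np.array(f_map(pt, params)) - np.array(pt)))
        for pt in d.fixed_points.values()
    )
    out.append(CheckResult("fixed_point_residual", resid < 1e-12, float(resid)))

    A = jacobian_f(d.x_re, params)
    expected = np.array([[0.5, -params.gamma / 2], [0.0, d.rho]])
    jerr = float(np.max(np.abs(A - expected)))
    out.append(CheckResult("jacobian_at_x_re", jerr < 1e-12, jerr))

    labels = classify_fixed_points(d)
    ok = labels["x_ex"] == "unstable" and labels["x_re"] == "saddle" and labels["x_mu"] == "saddle"
    if d.coexistence:
        ok = ok and labels["x_co"] == "stable"
    out.append(CheckResult("fixed_point_classification", ok, float(ok), str(labels)))

    if d.coexistence:
        res = max(abel_residual(x, params, tol=1e-10) for x in [(0.0, 0.5), (0.0, 2.0), (0.3, 1.0)])
        out.append(CheckResult("abel_residual", res < 1e-8, float(res)))

    phi = SchroederFunction(d.rho)
    x = 1.0
    s_res = abs(phi(phi.map(x)) - phi(x) / d.rho)
    out.append(CheckResult("schroeder_residual", s_res < 1e-10, float(s_res)))

    if params.K is not None and d.coexistence:
        violations = 0
        rng_seeds = np.random.SeedSequence(seed).generate_state(coupled_runs)
        alphas = alpha_preset("equal", 0.9)
        from .simulate import exit_times

        for s in rng_seeds:
            tr = simulate_coupled(params, horizon=15, seed=int(s), alphas=alphas, c=0.9)
            if not (np.all(tr.L[:, 1] <= tr.Y[:, 1]) and np.all(tr.Y[:, 1] <= tr.U[:, 1])):
                violations += 1
                continue
            tau = exit_times(tr.Z, params, alphas).tau
            upto = tr.Z.shape[0] if tau is None else tau + 1
            if not (np.all(tr.L[:upto] <= tr.Z[:upto]) and np.all(tr.Z[:upto] <= tr.U[:upto])):
                violations += 1
        out.append(CheckResult("coupling_order", violations == 0, float(violations)))

    return out


def all_passed(results: list[CheckResult]) -> bool:
    return all(r.passed for r in results)
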