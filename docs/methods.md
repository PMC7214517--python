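# Methods

## Model and assumptions

The model is a discrete-time, density-dependent two-type branching process.
Each cell leaves 0 or 2 offspring, independently given the current counts;
the splitting probabilities `p1 = a1K/(a1K + Z1 + γZ2)` and
`p2 = a2K/(a2K + γZ1 + Z2)` decrease with crowding, with the cross-type
pressure discounted by `γ ∈ (0,1)`.  The process starts from a resident
population at its quasi-equilibrium `[a1K]` plus a single mutant, so the
resident branch is critical and the mutant branch is supercritical with
mean `ρ = 2a2/(a2+γa1)` — the whole analysis assumes `a2 > γa1` and, for
coexistence, condition C: `a1 − γa2 > 0` and `a2 − γa1 > 0`.

On the density scale the process is a small random perturbation of the map
`f`: `X(n+1) = f(X(n)) + η(n+1)/√K`, where the noise has conditional mean 0
and per-coordinate variance `4 x_i p_i (1−p_i)`.  Classical bounded-horizon
theory says `X` tracks the orbit of `f` as `K → ∞`, but from the start
`(a1, 0)` that orbit is constant, so the interesting transition happens on
the `log K` time scale and retains randomness through the mutant's early
Galton–Watson phase.

## Parameters

| name | meaning | default / typical |
|------|---------|-------------------|
| `a1`, `a2` | carrying-capacity coefficients (population `a_i K` at the single-type equilibria); dimensionless | 1.0 |
| `gamma` | cross-type interaction in (0,1), symmetric between types | 1/3 (gives ρ = 3/2) |
| `K` | carrying capacity (habitat size); populations are O(K) | 10³–10⁶ |
| `c` | fraction of the establishment time for which the linearisation is trusted, `n_c = [log_ρ K^c]`; must be in (1/2, 1) | 0.9 |
| `alpha_1l, alpha_1u, alpha_2` | tube exponents in (c, 1): resident tube `a1(K ± K^α)`, mutant ceiling `K^α2` | presets spaced inside (c,1) |
| `tol` | stopping tolerance for the H iteration (sup-norm of successive values) | 1e-10 |

Validation is strict-reject for `γ ∉ (0,1)` and non-positive `a_i`;
violated coexistence is a flag rather than an error so the monomorphic and
saddle regimes remain explorable.  `[·]` is the floor function throughout
(`[a1K]`, `[log_ρ K]`, `[log_ρ K^c]`), and `{y} = y − [y]`.

## Numerical computation of H

`H(x) = lim_n f^n(x_re + x/ρ^n)` is evaluated by direct iteration.  The
perturbation `x/ρ^n` is obtained by repeated division (never forming
`ρ^n`, which would overflow long before the 700-iteration cap).  The
successive differences decay geometrically at rate `1/ρ`, so stopping when
they drop below `tol` bounds the remaining tail up to a constant factor;
the evaluation returns the iteration count, last increment and a
convergence flag.  If `x1 < 0` the start can leave the quadrant for small
`n`; iteration begins at the smallest `n` placing the start inside the
forward-invariant set `[x_co1, ∞) × [0, x_co2]` (in absolute coordinates),
on which the dynamics is well behaved.  `H(0) = x_re` is returned exactly.

Two numerical observations are tested as observations, not theorems: `H`
is flat in the resident offset `x1` (spread < 1e-3 on the default grid,
measured ~1e-10), and `H((x1, 0)) = x_re` — both consistent with the
contraction of the stable direction of the saddle at `x_re`.

The one-dimensional comparison machinery uses the Schröder function of the
inverse parabola `f(x) = √(1/4 + sx) − 1/2`, `s = 1/ρ`, computed as
`φ(x) = lim f^n(x)/s^n`.  The iteration uses the algebraically equivalent
form `f(t) = st/(√(1/4+st)+1/2)`, which avoids the catastrophic
cancellation of the textbook form near 0 and is what lets `φ'(0+) = 1` be
verified at `x = 1e-8` to 1e-5.  `φ⁻¹` is computed by bisection on a
geometrically grown bracket (relative accuracy ~1e-12); values are
memoised on exact float inputs.  Note `φ` grows extremely slowly (below
any power of `log x`), so `φ⁻¹` is super-exponentially large:
`φ⁻¹(10) ≈ 7.5·10⁹⁶`.  At that magnitude float64 spacing is ~1e80, so the
conjugacy `p^n(x/ρ^n) → φ⁻¹(x)` is checked with an absolute 1e-6 band for
`x ∈ {0.1, 1}` and a relative 1e-6 band at `x = 10` (measured ~2e-7 at
n = 60).

`ρ̃ = sup ‖Df‖_∞` over the quadrant is computed by a grid over
`[0,4a1]×[0,4a2]` plus Powell refinement.  The row sums equal
`2a_i(a_i+γ(x1+x2))/D_i²`, maximal at the origin where they equal 2, so
the computed value is 2 for every parameter set and the asserted bracket
`(ρ, 2]` holds.

## Simulation design

The coupled simulator draws, per generation and type, one uniform array of
length equal to the largest current population among the coupled
processes; every process consumes the prefix of its own length.  This
realises the common-variate construction exactly: ordered thresholds plus
shared uniforms give `L2 ≤ Y2 ≤ U2` surely and `L ≤ Z ≤ U` componentwise
on generations before the exit time `τ` (the first crossing of the tube
boundaries), which the tests verify over 500+ seeded runs with zero
violations.  Streams are seeded with `numpy.random.default_rng`; identical
seeds give identical trajectories.  A population cap (default 10⁸ per
type) turns supercritical runaway into an explicit error carrying the
partial trajectory.  Even counts (binary splitting) are asserted only for
generations ≥ 1, since the starts `[a1K]` and 1 may be odd.

The `fast` mode replaces per-individual indicators with binomial draws of
the number of splitters — the same one-step law, without the cross-process
coupling — and is used for Monte-Carlo ensembles (establishment fractions,
martingale samples, noise ensembles).  A two-sample Kolmogorov–Smirnov
test confirms the two modes agree in distribution.

The tube exponents matter in opposite directions: asymptotically any
`α ∈ (c,1)` works, but at moderate `K` the bounding rates contain
`K^{α−1}`, which approaches 1 as `α → 1`.  Coupling demonstrations
therefore use `c = 0.55` with the `equal` preset (α ≈ 0.78), keeping the
bounding processes' drift mild at `K = 10⁴`; establishment analyses use
the default `c = 0.9`, where the exponents only enter through `n_c`.  The
exposed range for `c` is (1/2, 1) (the closed right end appears only in
intermediate statements of the theory and `c = 1` would make `n_c = n1`).

## Establishment analyses

Establishment is an asymptotic notion (`liminf X2 > 0`); at finite K a
replicate counts as established iff `Z2(n1) ≥ √K` with `n1 = [log_ρ K]`.
The √K threshold sits between the O(1) extinct cluster and the Θ(K)
established cluster; the exponent is configurable in (0,1).  The per-
replicate `W` approximant is `ρ^{-n_c} Y2(n_c)` from the same coupled run,
preserving the pairing between the density path and its predicted limit;
`χ(K)` is then `H(ρ^{-{log_ρ K}} (0, W))`.  For negative offsets `n`,
`f^n(χ)` is computed through the Abel equation as
`H(ρ^{n−{log_ρ K}} (0, W))`, since `f` is not invertible — the same extra
damping used by the theory itself.  Exact powers of ρ are realised as
`K = round(ρ^j)` (e.g. 7482 ≈ 1.5²², fractional part 6e-5), since the
model needs integer K.  Distributional comparisons use the two-sample
Kolmogorov–Smirnov statistic on the mutant coordinate — a reporting
convention, not a claim of the theory.

## Problem sizes

The shipped checks use: 100 random parameter sets for the fixed-point
suite; 3 parameter sets × 50 random points for the Abel residual
(tol 1e-10, residual < 1e-8); 10⁵ replicates × 40 generations for the
martingale sample; 2000 replicates at K = 10⁴ for the establishment
probability; 500 coupled runs at K = 10⁴ for the coupling order; and
300 replicates at K ∈ {10³, 10⁴, 10⁵} with offsets −2…3 for the
random-initial-condition comparison.  These sizes give 3σ-level
statistical resolution for every asserted quantity while keeping the whole
suite at desk scale on one CPU.

## What the simulator does and does not emulate

The simulator *is* the model — there is no finer-grained reality behind
it — so the only idealisations are those of the model itself: discrete
non-overlapping generations, binary splitting, symmetric interaction via a
single γ, and a constant habitat K.  Passing tests show the implementation
matches the model's exact laws and its large-K theory at the sizes above;
they say nothing about biological systems with age structure, mutation
after invasion, or fluctuating environments, which are outside the model.

## Known limitations

* `H` is evaluated pointwise by iteration; no closed form or series is
  attempted, and off the admissible half-plane (`x2 < 0`) it is undefined.
* Establishment-probability convergence in K is slow (the finite-K
  allowance in the tests is 0.05); no Edgeworth-type correction is made.
* The coexistence-duration question (exponential in K) and diffusion-scale
  corrections are out of scope.
* At moderate K the L/U bounding tube is loose for α near 1 (see above);
  the bounds are a proof device, not sharp envelopes.
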