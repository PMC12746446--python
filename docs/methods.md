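# Methods

This note records the model, the numerical and design choices behind each
component, what the synthetic systems do and do not emulate, and the known
limitations. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Model systems and units

All systems are analytic toys in reduced units: energies in kT, β
configurable with default β = 1. They are deliberate surrogates for
molecular systems — one oracle per component claim — not approximations of
any force field.

- **Harmonic oscillator** `harmonic(k0, k1, dimension)`:
  U = ½k(λ)|x|², k(λ) = (1−λ)k0 + λk1. Gaussian partition function gives
  βG(λ) = (d/2) ln k(λ), so ΔG(0→1) = d/(2β)·ln(k1/k0); the conditional
  mean and variance of ∂U/∂λ are also closed-form, which is what lets the
  bias and the TI quadrature be checked to floating-point-level tolerances.
  Defaults k0 = 1, k1 = 4 give ΔG = ln 2.
- **Charging toy** `charging(k0, k1, c)`: U = ½k(λ)x² + λcx. Completing
  the square gives βG(λ) = ½ ln k(λ) − βλ²c²/(2k(λ)). Both the spring
  interpolation and the linear field are needed: with a λ-independent
  spring, Var(∂U/∂λ) = c²/β is constant and the variance-adaptive
  component would have nothing to adapt to. With the defaults
  (k0 = 1, k1 = 4, c = 2) the conditional variance varies by more than 5×
  across λ.
- **Torsion chain** `torsion(torsions, scaled, k0, k1)`: angles θ_j with
  AMBER-style terms (V_j/2)(1 + cos(n_jθ_j − δ_j)), each multiplied by γ
  if its index is in `scaled` (one index emulates single-torsion
  enhancement, several emulate multi-torsion enhancement), plus a
  λ-coupled harmonic well ½k(λ)s² on the collective coordinate
  s = Σcos θ_j. Angles wrap to (−π, π]. With (V, n, δ) = (10, 2, π) the
  single-angle chain is a symmetric double well — minima at 0 and π,
  10 kT barrier at ±π/2 — the kinetic-trap testbed. The 1-D chain has a
  deterministic quadrature oracle for ΔG; chains with d > 1 report the
  oracle as unavailable because the collective coupling is not separable.

∂U/∂λ is defined at fixed γ (the two-Hamiltonian-state scheme, the
default). Under the direct mapping γ(λ) = λ the scaled torsional energy
rides λ and its derivative is added; that mode disables γ-flip exchanges.

## Samplers

The default propagator is random-walk Metropolis with isotropic Gaussian
proposals (default scale 0.5 in reduced length units, 1.0 in most tests):
its stationary distribution is *exactly* exp(−βU), so every downstream
acceptance check is free of integrator bias. A BAOAB-discretized Langevin
integrator (unit mass, default dt = 0.05, friction 1.0) is provided for
dynamical realism; it carries O(dt²) stationary bias and is validated only
for moment agreement with Metropolis, not used in the oracle path.

One RNG stream per replica, spawned from the master seed via
`SeedSequence`; every jump and exchange draws from the stream of the
replica performing the attempt. Runs are therefore bit-reproducible.

Samples (∂U/∂λ and U) are recorded every step by default: the dense
recording is what the autocorrelation analysis is designed for, and
thinning is an analysis-time choice.

## Serial tempering

The λ grid is uniform with 101 windows (Δλ = 0.01) by default. The bias is
the negative running Simpson integral of the per-window mean ∂U/∂λ:
F_0 = 0 (gauge), F_1 by one trapezoid panel (the lowest-order consistent
closure of the two-point recursion start; its O(Δλ³) one-panel error is
negligible at Δλ = 0.01), and F_i = F_{i−2} − (Δλ/3)(y_{i−2} + 4y_{i−1} +
y_i) thereafter. On the harmonic model's analytic means the even-window
bias matches −½ ln(k(λ)/k0) to 1.3e−8.

Jumps use the normalized heat-bath distribution over *all* windows k ≠ i
with logP(λ_j) = −β[U(r, λ_j) − U(r, λ_i) + F_j − F_i], computed with
max-subtraction; probabilities below 1e−300 are treated as zero, and if
every candidate vanishes the jump is declined. Excluding the current
window makes this a forced-move scheme, which violates detailed balance by
a term second-order in the spread of the conditional window probabilities;
with a converged bias that spread is small, and the flat-histogram χ² test
(10⁵ jump events over 101 windows, α = 0.01) bounds the residual bias
empirically. A neighbors-only candidate restriction is available for
diffusion studies. Jumps are attempted every 100 propagation steps; the
bias is rebuilt from the running means every 10⁴ steps per replica
(adaptation interval), with scan and post-scan data weighted equally —
the bias derives from the accumulated thermodynamics, not from a
visitation penalty.

Phase 1 is one sequential pass over all windows (default 100 steps per
window), which both seeds the bias and guarantees every window enters the
running statistics before any burn-in or jump dynamics.

## Variance adaptation

Per-window count/mean/variance are maintained by Welford updates (chunk
merges use the parallel-merge formula); the variance is the population
form, matching the defining second-moment expression — the n vs n−1
distinction is irrelevant at the sample counts involved. Windows with
fewer than 10 samples have untrusted variances and inherit the mean
variance of trusted windows (the target formula is undefined on empty
counts and nothing principled distinguishes a noisy small-count variance
from zero information).

Targets: P_i ∝ Var_i, then P_i ← max(P_i, 0.1·max_j P_j), then
renormalize. The floor keeps every window reachable and guarantees the
ratio weighting below is well defined. The jump re-weighting
P′(i→j) ∝ P(i→j)·P_target(j)/P_target(i) is renormalized over candidates
(without renormalization the numbers are not probabilities); it is applied
to the heat-bath vector rather than to a pairwise acceptance.

Budget allocation: the propagated TI variance is Σ (Δλ_i/N_i)σ_i² (first
power of the spacing, as the component's objective; a squared-spacing
switch is provided). Two allocation rules are implemented because two
distinct optimality notions exist:

- `neyman` (default): N_i ∝ √(Δλ_i)·σ_i, the true minimizer of the
  objective by Cauchy–Schwarz. It is never worse than uniform allocation
  and strictly better whenever the Δλ_iσ_i² are heterogeneous.
- `variance`: N_i ∝ Δλ_i·σ_i², which equalizes the per-window
  contribution Δλ_iσ_i²/N_i. Under the first-power objective this rule
  yields exactly the same total variance as uniform allocation (an
  algebraic identity), so it should be read as an effort-equalization
  heuristic, not an optimum.

The two rules coincide only for homogeneous variances; both are tested
for the property each actually has.

## Exchange moves

Replica exchange swaps the entire walker state between fixed adjacent
pairs (0,1), (2,3), … every 100 steps, accepted with min(1, e^(−βΔU)) on
true potential energies only — bias terms never enter, so the exchange
preserves the product ensemble. An alternating pairing scheme is available.
The fixed-λ reference ladder uses configuration-only swaps (each window
slot keeps its λ) with alternating neighbor pairing.

γ-flip (physical ↔ dummy) attempts share the 100-step cadence. When both
are due in the same round, γ-flips run first, then replica swaps — the
ordering is a convention (either order preserves the stationary
distribution since each move does individually) and both events are
counted separately. Dummy-state samples are flagged and excluded from all
TI estimates; only the physical alchemical coordinate is integrated.

## Estimation and diagnostics

- TI uses composite Simpson on the uniform grid (odd window counts; an
  even count falls back to trapezoid on the last panel, logged). 101
  windows integrate the harmonic model's analytic means to within the
  composite-Simpson error bound (≈1.3e−8 here).
- Autocorrelation uses the biased (population) covariance with the overall
  series mean. The statistical-inefficiency sum truncates at the first lag
  with ρ_k ≤ 0 — the "decayed to zero" prescription; a windowed-sum
  alternative is noted but not implemented as default. g is floored at 1.
- Burn-in: the leading 10% of each replica's record stream is discarded
  before all estimation (configurable). Note this usually consumes the
  sequential-scan data; windows a replica never revisits are filled from
  the pooled means for that replica's estimate only (logged), leaving the
  pooled estimate unaffected.
- Per-replicate standard errors propagate through the quadrature as
  Var(ΔG) = Σ w_i²σ_i²/N_eff,i with w_i the composite quadrature weights
  and N_eff,i = N_i/g_i — the delta-method form. The first-power spacing
  form is *not* used here: as an SE of the quadrature estimate it is off
  by a factor ≈ 1/Δλ, which would make the concordance diagnostic
  unattainable by construction. Per-window g estimation thins series
  beyond 5000 points by striding and rescales (g is approximately
  divided by the stride), bounding the lag-scan cost.
- The quality ratio is σ_Â/⟨SE⟩ with σ_Â the (n−1)-normalized standard
  deviation of the per-replicate ΔG estimates and ⟨SE⟩ the mean propagated
  SE; flags: ok ≤ 2 < warning ≤ 5 < severe.

## Driver conventions

Replicas are logically concurrent but executed serially; exchange attempts
synchronize pairs at the configured interval. The per-replica budgets
partition the total step budget exactly (remainder steps go to the
lowest-indexed replicas), and the sequential scan counts toward the
budget. Replicas launch at evenly spread starting windows,
round(r·(N−1)/(N_rep−1)). The benchmark matrix (ST, ST+VAR, ST+RE,
ST+VAR+RE, 21W, 21W+RE, ± single/multi-torsion enhancement) is reachable
from toggles alone. Outputs: sample tables as headered CSV (replica, step,
lam_index, gamma_state, dudl, u), reports as JSON, configs as YAML —
plain tables keep the diagnostics usable on third-party data.

## Problem sizes used in the checks

The end-to-end checks run each benchmark configuration with 8 replicas and
10⁶ total steps (the harmonic ΔG is then recovered well within 3× the
replicate spread, which is itself below 0.012 kT); visitation checks use
10⁵ jump events; the barrier-escape check uses a 150,000-step budget with
proposal scale 0.1, calibrated once by a pilot so that the unenhanced
walker reliably stays trapped while γ-flip exchange mixes the wells; the
concordance check uses 150 experiments of 8 replicate runs × 1500 steps.

## What the toys do and do not show

Passing tests establish that every component is implemented correctly
against its defining property on systems where the truth is known exactly:
bias construction, flattening, variance targeting, allocation optimality,
exchange acceptance, barrier escape, and the diagnostics algebra. They do
not demonstrate performance on molecular systems: the toys have smooth
unimodal (or deliberately bimodal) one-dimensional landscapes, no solvent,
no soft-core singularities, and no separation between fast and slow
degrees of freedom beyond the constructed torsional trap. Claims about
relative efficiency of the method variants on real transformations are
outside what this package can support.

## Known limitations

- The forced-move heat-bath jump is followed as specified; its small
  detailed-balance violation is bounded empirically, not corrected
  analytically (a Metropolized acceptance factor would restore exactness).
- The Langevin path is for comparison only; its discretization bias is
  unquantified beyond moment agreement at small dt.
- Temperature-based tempering, nonuniform λ grids, BAR/MBAR-style
  estimators, multi-transformation allocation, and any automatic torsion
  selection are out of scope.
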