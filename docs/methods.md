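# Methods

This note records the models implemented in `chemoscale`, the assumptions
behind them, the numerical choices, and the places where the design was
genuinely open and a decision had to be made.

## Excitation–adaptation model (`cartoon`)

The minimal adapting circuit has a fast excitation variable u₁ (the
response) and a slow adaptation variable u₂:

    du₁/dt = (f(S(t)) − u₁ − u₂)/τₑ
    du₂/dt = (f(S(t)) − u₂)/τₐ,       τₑ ≪ τₐ,  f(0) = 0.

Both right-hand sides divide the whole bracket by the time constant.  This
bracket placement is the only reading under which the steady state of u₁ is
exactly zero for any constant stimulus — the defining property of perfect
adaptation — so it is the one implemented.  The step response from rest is

    u₁(t) = f(S₀) · τₐ/(τₐ − τₑ) · (e^{−t/τₐ} − e^{−t/τₑ})
    u₂(t) = f(S₀) · (1 − e^{−t/τₐ}).

A version of this solution with denominator (τₐ + τₑ) circulates in the
literature; differentiating shows it is inconsistent with the initial slope
f(S₀)/τₑ implied by the ODE, so we ship the (τₐ − τₑ) form and verify it
against the integrator to 1e−10 relative.  In the τₑ ≪ τₐ regime used
everywhere here the two differ by O(τₑ/τₐ) and all qualitative statements
(peak ≈ f(S₀), pulse peak ≈ (1 − 1/e)·S₁ ≈ 2S₁/3) are unaffected.

Numerics: the system is linear, so piecewise-constant stimuli are integrated
*exactly* by a cached matrix-exponential update per segment (steps are split
at segment boundaries; the only error is round-off).  Ramp segments fall
back to fixed-step RK4, with stimulus stages evaluated through the active
segment so that the half-open segment convention cannot leak a wrong value
into the last RK4 stage.  The confluent case τₐ = τₑ is rejected by the
closed form (the integrator itself handles it, via the matrix exponential).

Defaults: τₑ = 0.1 s, τₐ = 10 s, f = identity.  Saturating transduction
functions can be plugged in; f(0) = 0 is enforced.

## Receptor-cluster equilibria (`mwc_cluster`)

The core signalling unit is the trimer of receptor homodimers, treated as a
two-state (active/inactive) allosteric unit with three sequential ligand
binding steps per state.  At fixed methylation label m the eight levels are
E_on (plus binding terms) and E_off (plus binding terms), with the binding
polynomial P(L) = 1 + 3L/K₁ + 3L²/K₁K₂ + L³/K₁K₂K₃ carrying the 3,3,1
degeneracies.  Boltzmann statistics give

    p_on = 1/(1 + e^{Δf}),   Δf = E_on − E_off + log[P_off(L)/P_on(L)],

and cluster-energy additivity gives p_on = 1/(1 + e^{nΔf}) for n coupled
trimers; mixed clusters add n_a·Δf_a + n_s·Δf_s with the non-target
receptor type contributing its ligand-free Δf as a constant offset.  One
printed form of the active-state binding polynomial carries an L² where the
cubic term belongs; the L³ form (required by the binding-polynomial
derivation and used in every other instance) is implemented throughout.

Conventions and defaults:

- Attractants bind the inactive state more tightly (attractant binding
  inhibits the kinase), so default parameter sets have Kd_off,i < Kd_on,i
  and decreasing dose–response curves.  Reversing the inequality yields
  repellent-like increasing curves; both monotonicities are property-tested.
- The exact parameter values behind the published mutant dose–response
  families are not public; the shipped defaults (Tar: Kd_off = 0.02,
  Kd_on = 0.5; Tsr: 0.1/5.0; methylation offsets EEEE +1, QEQE −1,
  QQQQ −3 k_BT) are documented order-of-magnitude choices that reproduce
  the qualitative structure (baseline activity ordering
  EEEE < QEQE < QQQQ, amplitude growth with expression level).  No claim of
  numerical identity with any published dataset is made.
- Receptor-expression multipliers map to trimer counts as
  n = max(1, round(mult × base)), base configurable (1 for the pure-type
  families, 6 for the "native Tsr" background in mixed clusters).
- Only pure-type trimers occur inside mixed clusters, and single-ligand
  protocols only; E_off carries no methylation dependence.
- All energy arithmetic is in log space with `logsumexp`; Δf is finite for
  any L up to overflow of log(L) itself (tested at L = 1e300).
- At L = 0 the ligand-bound levels have zero Boltzmann weight; they are
  reported as unoccupied (NaN energy + flag) rather than +∞.

The identity between the logistic form and the brute-force eight-level
partition sum is enforced to 1e−12 over random parameter draws — the two
routes stay independent in the tests.

## Hill fits (`hill`)

A(L) = A_inf + (A₀ − A_inf)/(1 + (L/K)^{n_H}), fitted by least squares in
log-L space with free plateaus.  Free plateaus matter: a single-site
two-state unit produces a Möbius function of L, which is *exactly* a Hill
curve with n_H = 1 only when the plateaus are free.  Initialisation is
deterministic (K at the grid point nearest half-range, n_H from the local
log-log slope, restarts from half and double that slope; best of three), so
fits carry no seed dependence.  Cooperativity classes partition the fitted
coefficient at 1.5 and 3 — "~1" / "~2–3" / "≫3"; both boundaries are
arguments, not constants.  Flat curves (range < 1e−6) are rejected rather
than fitted.

## Run-and-tumble agents (`agents`)

Velocity-jump process: each cell swims at fixed speed s₀ and tumbles at
rate λ(y₁) = λ₀(1 − y₁/(γ₀ + |y₁|)), bounded in (0, 2λ₀); the internal
pair (y₁, y₂) follows the excitation–adaptation dynamics with the local
signal G(S(x, t)) as drive.  Tumbles are instantaneous (the ~0.1 s real
tumble duration is not modelled) and the post-turn velocity is uniform on
the speed sphere — in 1-D, ±s₀ with probability ½, so a "turn" may
re-select the incoming direction; run statistics are therefore *turn-based*,
and direction-reversal intervals are longer than run intervals by a factor
of 2 in 1-D.  The measured gamma-distributed turning-angle distribution of
real cells is deliberately not used; the uniform kernel is the modelling
assumption this package propagates consistently into its continuum limit.

Numerics:

- Time-driven stepping with fixed dt, refused unless dt ≤ tₑ/5 (resolve
  excitation) and 2λ₀·dt ≤ 0.2 (keep per-step turn probabilities small).
- Internal variables advance by the exact matrix-exponential update with
  the signal frozen over the step (first-order splitting against motion).
- A turn fires in a step with probability 1 − e^{−λdt}; *given* a turn, the
  event time within the step is drawn from the matching truncated
  exponential.  Recorded run durations are therefore exact inter-event
  times of the underlying Poisson process (up to the one-event-per-step
  thinning, O((λdt)²)), rather than dt-lattice values; at the default
  dt = 0.005 s the residual bias on the mean run interval is ≈ 0.25%,
  against a censoring bias of ≈ −1% from discarding each cell's final
  (incomplete) run on a 100 s window.
- One seeded generator draws fixed-shape arrays per step (turn decision,
  event fraction, new direction for *every* cell, used or not), so the
  stream consumed never depends on how many cells turned and results are
  independent of any notional iteration order; identical seed + config is
  bit-reproducible.
- Diffusion is estimated from the time-averaged MSD (origins every 2/λ₀)
  with a linear fit over lags in (10/λ₀, t_end/3), past the
  ballistic-to-diffusive crossover; for the uniform kernel the target is
  D = s₀²/(Nλ₀).
- Domains: unbounded (for MSD work), periodic, or reflecting boxes.

γ₀ (the turning-rate saturation scale, units of y₁) has no published value;
the default is 1, and the continuum-comparison fixtures use γ₀ = 0.25 so
that b = λ₀/γ₀ = 4 matches the canonical comparison parameter set.  G
defaults to the identity.

## Chemical fields (`fields`)

Attractant S and optional nutrient F on a 1-D/2-D lattice:

    ∂S/∂t = D_s ΔS + γ Σᵢ δ(x − xᵢ) − µS
    ∂F/∂t = D_f ΔF − k Σᵢ δ(x − xᵢ)

The attractant loss term is implemented as first-order decay −µS; a bare
constant labelled a "degradation rate" appears in one printed source and is
treated as a typo (a constant source/sink is neither degradation nor
bounded).  The consumed-signal variant replaces secretion with a constant
per-cell sink (−γ Σ δ(x − xᵢ), S(x,0) = 1): total mass then falls by
exactly γ·n_cells·dt per step until local depletion, where concentrations
are clamped at zero with a warning.

Numerics: delta sources spread by cloud-in-cell (bilinear) weights — mass
deposition is exact to round-off and deposit/interpolate form a transpose
pair (checked by an inner-product identity).  Diffusion is implicit backward
Euler, alternating-direction in 2-D, one prefactorised tridiagonal/sparse
solve per axis; because each 1-D Laplacian has zero column sums under both
periodic and no-flux closures, every solve conserves mass to round-off.
Reactions are applied pointwise after diffusion (exact exponential update
for decay+source, linear for the consumption terms).  Cells and fields
advance on a shared dt by first-order splitting; the field is sampled at
cell positions with the same bilinear weights.

Pattern scenarios and what they do (and do not) show: the shipped scenarios
run at deliberately reduced scale (50–60 node grids, 3000–4000 cells,
300–400 s) so the full suite stays in minutes.  The published
pattern-formation experiments involve ~10⁶–10⁸ cells over hours to days;
scenario parameters here are order-of-magnitude choices, and only
*qualitative* claims are tested: secretion-driven growth of binned-density
variance with a γ = 0 control that stays at shot noise, and constant-speed
front advance (R² > 0.99) for the consumed-signal band.  The secretion rate
of the liquid-aggregation scenario (γ = 5) is placed inside the chemotactic
instability region computed from the linearised dispersion relation
σ(k) = k²(χn₀γ/(D_s k² + µ) − Dₙ) with ≈ 18 s e-folding at the
domain-scale mode — the scenario is *designed* to be unstable, since the
claim under test is the bifurcation (aggregation with secretion, none
without), not a particular pattern geometry.  Cell growth/death,
nutrient-dependent motility, hydrodynamics and agar mechanics are out of
scope; the nutrient field only tracks depletion for the swarm-ring
visualisation.

## Continuum limit (`pks`)

Linearising the internal dynamics about the adapted state
(z = y − (0, G(S))) and closing the moment hierarchy of the velocity-jump
transport equation at first order gives

    ∂n/∂t = ∂ₓ(Dₙ ∂ₓn − χ n ∂ₓS),
    Dₙ = s₀²/(Nλ₀),
    χ  = b s₀² tₐ / (Nλ₀ (1 + λ₀tₐ)(1 + λ₀tₑ)),   b = |∂λ/∂y₁|₀ = λ₀/γ₀.

One printed form of this equation omits the density factor n in the
chemotactic flux; a flux independent of n would allow negative densities
and contradicts the standard chemotaxis-equation family, so the n·∂ₓS form
is implemented.  Signs are fixed by the physics: for an attractant the
turning rate falls with y₁, χ is reported positive, and the drift is
up-gradient — verified against the closed-form drift speed χ·∂ₓS in a
linear signal and against the zero-flux stationary profile
n ∝ exp(χS/Dₙ), an exact solution used as a 1% pointwise oracle.

Solver: conservative finite volume, central diffusion + first-order upwind
advection, explicit stepping with the joint positivity limit
dt ≤ 0.8·dx/(2Dₙ/dx + |u|_max).  Upwinding adds numerical diffusion
|u|dx/2, so the 1% stationary-profile check is run at dx = 10 µm where that
artefact is ≈ 3 µm²/s against Dₙ = 400 µm²/s.

Validity diagnostic: the derivation assumes the signal change seen over one
run is small against 1/tₐ; the comparison reports ε = s₀·|∂ₓG(S)|·tₐ and
flags ε ≥ 1.  In the canonical comparison (s₀ = 20 µm/s, λ₀ = 1/s, b = 4,
piecewise-linear signal peaked mid-domain, ε = 0.05) the L1 distance between
the 10⁴-cell histogram and the PDE stays ≈ 0.05 with 40 bins — the
Monte-Carlo floor; in a 40× steeper signal (ε = 2) the discrepancy grows
and the flag trips, which is the expected failure mode, not a defect.

## Scenario sizes and runtime

All scenarios are sized for a single CPU: the full test suite runs in
~1.5 minutes and the acceptance script in seconds.  The stochastic checks
pin their seeds; their tolerances (2% on the mean run interval, 5% on
diffusivity, 0.1 on L1) were sized from the estimator noise at the chosen
population sizes (e.g. the endpoint-difference drift estimator has ≈ 2.7%
standard error at 8000 cells × 400 s).

## Known limitations

- No methylation kinetics: methylation enters only as a label selecting
  parameter sets (the adaptation-deficient mutant setting); the full
  signal-transduction network and CheYp dynamics are out of scope.
- The single-trimer Hill coefficient and the cluster ultrasensitivity are
  equilibrium statements; no kinetic receptor model is included.
- 1-D continuum solver only; steep-gradient regimes need higher-order
  moment closures that are not implemented (the diagnostic flags them).
- Agent–field coupling is first-order in dt; patterns at reduced scale are
  qualitative, not quantitative reproductions of plate-scale experiments.
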