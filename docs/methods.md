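# Methods

## The model family

All models are two-variable ODE systems for the internal nutrient
concentration `S_int` and the plasma-membrane transporter concentration `T`,
driven by an external nutrient concentration `S_ext` treated as a fixed
environmental input:

```
dS_int/dt = T·u(S_ext) − γS(S_int)
dT/dt     = αT(S_int) − kγT(S_ext, S_int, T)·T
```

`u` is the uptake rate per transporter (Michaelian,
`u = kcat·S_ext/(S_ext+Kext)`, the standard assumption for transporter
kinetics), `γS = kgS·S_int` is first-order usage, `αT` the synthesis flux and
`kγT` the per-transporter downregulation rate.  Downregulation flux is
assumed linear in `T` except for the internal-flux-sensor variant, where a
sensor reading the total flux `T·u` makes the downregulation flux
`ksens·u·T²`.  The registry covers: no regulation; activity-dependent
downregulation (`kγT = kgTc + kgTa·x` with occupancy `x = S_ext/(S_ext+Kext)`);
Hill repression of synthesis by `S_int`; Hill activation of downregulation by
`S_int`; the combination of activity-dependent downregulation with synthesis
repression; an external-nutrient sensor (`kγT = kgTc + ksens·S_ext/(S_ext+Ksensor)`);
the unnormalized internal flux sensor; and a linear-in-`S_ext`
downregulation variant kept for qualitative comparisons (its functional form
is an interpretation — no saturating sensor — and it is exposed as
`external_linear` outside the canonical seven).

A custom construction path accepts arbitrary sympy flux expressions in the
general uptake form (`u(S_ext, S_int)`, `γS(S_ext, S_int)`,
`αT(S_ext, S_int, T)`, `kγT(S_ext, S_int)`); nonnegativity is checked by
sampling, not proved.

### Parameters, units, defaults

Concentrations are conventionally reported in units of `Kext`; rate constants
in inverse time.  All defaults are 1 except as noted.  Two derived scales
matter:

- `S0 = kcat·aT/(kgS·kgTc)` — the saturated steady-state `S_int` of the
  unregulated system, the natural unit for internal-feedback saturation
  constants.  `Ksyn` and `Kdeg` default to `S0` itself.  Note that a
  feedback half-point at `S0` only engages near transporter saturation: with
  this default, synthesis repression *alone* cannot exceed r ≈ 0.65 at
  `S_ext = Kext` no matter how large the Hill coefficient, because the
  repression is nearly inert for `S_int` below `S0`.  Pass `Ksyn ≪ S0` (for
  example `0.1·S0`) to study feedback that shapes the whole operating range.
- `ρ = kgTa/kgTc` — the ratio of activity-dependent to basal
  downregulation, the primary knob of the robustness–efficiency trade-off.

The Hill coefficient `n` must be finite; the perfect-homeostasis-by-synthesis
limit `n → ∞` is a documented limit, never a parameter value.

## Steady states

The transporter equation fixes `T_ss = αT(S_int)/kγT(S_ext, S_int)` (for
`T`-nonlinear downregulation, a closed form or inner 1-D root solve), which
reduces the fixed-point problem to one scalar equation
`G(S_int) = u·αT − γS·kγT = 0`.  For constant synthesis and
`S_int`-independent downregulation this is linear (closed form); Hill
variants use Brent root-finding on the bracket `[0, 10·S0]` — `u ≤ kcat`
bounds every synthesis-repressed variant by the unregulated saturated level —
with one 100× expansion before failing loudly.  `G` is strictly monotone for
every registry variant at valid parameters, so roots are unique; an optional
root-counting scan (257 subdivisions) reports multiplicity for custom models.

Every reported state is verified against the right-hand side
(residual < 1e−9 × state scale, asserted on return) and classified by the
2×2 Jacobian eigenvalues (non-hyperbolic when a real part is within 1e−9 of
zero, e.g. the degenerate `kgS = 0` system).  Systems whose downregulation
vanishes while synthesis persists (`kγT = 0`, e.g. pure activity-dependent
downregulation at `S_ext = 0`) have no finite steady state; this is reported
as a dedicated `NoSteadyStateError`, never as a convergence failure.
Relaxation by adaptive LSODA integration (`rtol 1e−10`, `atol 1e−12`,
default `t_max = 1e4`, convergence when the derivative norm falls below
1e−10 × state scale) serves as the independent numerical oracle; the default
initial state `(0, 1)` is immaterial because the steady states are unique
and globally attracting at valid parameters.

## Deciding global perfect homeostasis

Global perfect homeostasis means `∂S_int_ss/∂S_ext = 0` at every `S_ext`.
Three routes are implemented and must agree:

1. **Reduced symbolic criterion.** For the reduced family the necessary and
   sufficient condition is that `kγT/αT` factor as `u(S_ext)·func(S_int)`;
   operationally, `∂/∂S_ext [kγT/(αT·u)]` must vanish identically on the
   positive orthant.  Zero testing simplifies first and falls back to exact
   rational evaluation at 50 seeded random points — exact arithmetic rules
   out both roundoff false zeros and simplification false negatives.  When
   the instance fails, candidate constraints (`kgTc = 0`; `Ksensor = Kext`;
   both) are scanned on the parameter-symbolic form; a constraint that
   rescues the criterion without degenerating the model (e.g. matched sensor
   and transporter affinities) is reported as the condition under which the
   verdict flips, and the verdict becomes `locally_perfect_only`.  A failure
   no constraint rescues is `not_homeostatic_structurally`.
2. **Structural rank condition.** With flux channels
   `σ = (T·u, γS, αT, kγT·T)`, the logarithmic sensitivity column
   `P_i = ∂log σ_i/∂log S_ext` must lie in the parameter-independent
   subspace `I` spanned by the normalized columns of `(M|K)`, where
   `M_i = ∂log σ_i/∂log T` and `K` pairs the steady-state fluxes to the two
   state variables (columns proportional to `(1,1,0,0)` and `(0,0,1,1)`
   after applying the steady-state flux balances).  "Parameter-independent"
   is operationalized as: no rate-constant symbols survive normalizing a
   column by its first nonzero entry; `I` is assembled greedily.
   `rank(P|I) = rank(I)` is decided over the rational-function field by
   exact rational sampling (30 seeded points), which realizes the generic
   rank with probability one.  For the reduced family this reduces exactly
   to `∂log kγT/∂log S_ext = ∂log u/∂log S_ext`, i.e. the factorization
   criterion — the two symbolic routes are independent implementations of
   one mathematical fact, which is what the agreement tests exercise.
3. **Numeric sensitivity.** The logarithmic derivative
   `d log S_int_ss / d log S_ext` by multiplicative central differences
   (half-width 1e−4 in log space; truncation ~1e−8, roundoff ~1e−8 given
   solver accuracy), on a default grid of 41 log-spaced points over
   `[1e−2, 1e2]·Kext`.  Perfection threshold: max |sensitivity| < 1e−6.
   Grid points without a steady state are marked missing, not dropped.

Downregulation nonlinear in `T` (internal flux sensor) is outside both
symbolic templates and is checked numerically only; its sensitivity is
strictly positive (`S_int_ss ∝ √u`), confirming that flux sensing needs
sensor-number normalization to be homeostatic.

## Robustness and efficiency

`r(S_ext) = S_int_ss(S_ext) / sup_{S_ext∈(0,∞)} S_int_ss` — so `r ∈ [0, 1]`
and `r ≡ 1` is global perfect homeostasis.  For the monotone families
(steady state depends on `S_ext` only through the occupancy `x` and is
nondecreasing in it) the supremum is the analytic saturation limit,
evaluated by solving at an effectively infinite `S_ext` (1e30, where the
occupancies round to 1.0 exactly in double precision); this avoids grid
truncation of the normalizer.  Sensor variants need not be monotone — a
lower-affinity external sensor puts the supremum at `S_ext → 0` — so their
supremum is scanned over `[1e−6, 1e6]·Kext` (481 points) plus the saturation
limit and flagged `grid_max`.  The sensor-mismatch analyses instead use
`S_int` normalized by the saturation limit itself (values may exceed 1),
with flatness = max/min across the grid.

`e = αS/γT = u/kγT` at steady state: the nutrient transported by one
transporter over its average lifetime, reported per transporter (not per
cell).  The trade-off: along `ρ`, `r = x(1+ρ)/(1+ρx)` is nondecreasing and
`e = kcat·x/(kgTc(1+ρx))` nonincreasing (these closed forms are test
oracles; the package always solves forward).  Trade-off tables also export
`e` normalized by its curve maximum, since the reference normalization of
the efficiency axis is not fixed by the analyses it reproduces.

## Iso-robustness contours

For a target `r*` at fixed normalized `S_ext`, the solver returns parameter
pairs achieving `r = r*`: for the combined architecture, `ρ` per Hill
coefficient `n` (bracketed Brent on `[0, hi]` with geometric expansion,
`xtol 1e−12`); for pure activity-dependent downregulation the single `(0, ρ)`
pair; for synthesis repression alone the Hill coefficient is the unknown
(pairs `(n, 0)`), since that architecture has no `ρ` knob.  Targets below
the `ρ = 0` minimal robustness or at/above 1 raise a range error citing the
bound.  Every solution is re-evaluated by an independent forward solve and
must land within 1e−6 of the target — a built-in check, not just a test.

## The transporter cycle

The mass-action cycle (bind `kon/koff`, conformational change `kc`, release
`kr`, modification `km`) grounds the activity-dependent term mechanistically:
uptake and downregulation exit from the same bound conformation, so their
flux ratio is `km/kr` identically in `S_ext`.  The quasi-steady-state
distribution over cycle intermediates is solved exactly (linear balance;
QSS is taken on the fast cycle relative to slow synthesis/degradation), and
the coarse-grained uptake law is exactly Michaelian with
`kcat_eff = kr·kc/(kc+kr+km)`, `Kext_eff = (koff+kc)(kr+km)/(kon·(kc+kr+km))`
and `kgTa_eff = kcat_eff·km/kr`; the closed form is still verified
numerically over 4 decades (tolerance 1%) with worst-point diagnostics.
Direct modification of the bound conformation is modeled; irreversible
indirect inactivation is equivalent at steady state.  Embedded in a whole
cell (synthesis into the free pool, first-order usage), modification is the
only transporter sink, so `S_int_ss = kr·aT/(km·kgS)` exactly — independent
of `S_ext` — and the coarse-grained model reproduces it.

## What the defaults do and do not represent

The package generates all of its own inputs; there is no measured data.
Unit rate constants with concentrations in units of `Kext` are the
dimensionless convention of the analyses being reproduced, not a fit to any
organism.  Passing tests therefore demonstrate the mathematical structure of
the regulatory architectures — which ones can and cannot be perfectly
homeostatic, and the shape of their trade-offs — not quantitative behavior
of a particular transporter system.  Real systems add transporter synthesis
delays, internal nutrient storage and recycling, stochastic copy-number
effects and multi-nutrient competition, all outside scope here; transient
behavior is only demonstrated qualitatively (the step-response test), not
characterized.

## Numerical choices and problem sizes

- Default `S_ext` grid 41 log-spaced points over `[1e−2, 1e2]·Kext`;
  `ρ` grids 41 log-spaced over `[1e−2, 1e4]`; Hill grid {0,1,2,3,4,6,8,10}.
- Random-sweep tests use a few hundred draws with rate constants log-uniform
  on `[0.1, 10]` rounded to 3 significant digits (keeping exact-rational
  symbolic checks fast) and integer Hill coefficients 1–4.
- Hill powers are evaluated in float64 so that overflow saturates to `inf`
  (and Hill fractions to their limits) instead of raising; the Hill
  coefficient bracket for contour solving is capped at 128.
- Seeded randomness: symbolic zero/rank sampling uses a fixed recorded seed;
  hypothesis profiles are derandomized.

## Known limitations

- The symbolic special-condition scan covers the constraints that arise in
  the canonical architectures (`kgTc = 0`, `Ksensor = Kext`, their
  conjunction); a custom model perfect only under some other parameter
  relation is reported as structurally non-homeostatic with its residual,
  without naming the relation.
- `rank(P|I) = rank(I)` is decided by exact sampling of the generic rank;
  rank drops on measure-zero parameter sets are deliberately ignored (they
  correspond to locally, not globally, fine-tuned perfection).
- The supremum scan for non-monotone (sensor) variants is a dense grid, not
  a proof; profiles with structure outside `[1e−6, 1e6]·Kext` would
  understate the normalizer.
- No bifurcation continuation or limit-cycle detection: all registry systems
  are monotone relaxing at valid parameters.
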