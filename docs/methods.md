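# Methods

`condpop` quantifies how ion-channel diversity shapes the *density*,
*stability* and *connectedness* of valid regions in the conductance
parameter space of a neuron model.  Because the original detailed
granule-cell mechanisms and the experimental spike-feature statistics are
not public, the package operates on a self-contained surrogate family of
conductance-based models plus a fully specified probabilistic toy model.
This note records the models, the numerical choices, and what the shipped
defaults do and do not emulate.

## Surrogate neuron family

### Structure

Three isopotential compartments form a tree rooted at the soma:

| compartment | area (cm²) | C_m (µF/cm²) | axial g to soma (µS) |
|---|---|---|---|
| soma | 2.5·10⁻⁵ | 1 | — |
| AIS | 2.5·10⁻⁶ | 1 | 0.05 |
| dendrite | 5·10⁻⁵ | 1 | 0.04 |

Each channel is a product of Hodgkin–Huxley-style gates.  Voltage gates use
a Boltzmann steady state `1/(1 + exp(−(V−V½)/k))` (signed slope `k`) and a
Gaussian-bell time constant `τ(V) = τ₀ + τ_a·exp(−((V−V_τ)/σ)²)`, floored
at 0.05 ms.  Calcium gates use a Hill steady state
`ca^h/(ca^h + K_d^h)` with a fixed τ.  One first-order calcium pool per
compartment integrates all Ca-channel currents (`influx 0.3 µM/(nA·ms)`,
removal τ 8 ms, rest 0.05 µM); Ca currents are ohmic with a fixed +120 mV
reversal (no GHK), which is simpler, monotone in the driving force, and
sufficient for a pool that only needs to track spike-driven influx.

The rosters mirror the granule-cell models: the 5-channel model is
{pas, Kir21, na8st, BK, Cav22}; the 9-channel model adds
{Kv21, Kv34, Kv42, Kv723}; the 15-channel model further adds
{Kv11, Kv14, SK, Cav12, Cav13, Cav32}.  Region-resolved expression gives
9 / 13 / 27 parameters (mS/cm²); `pas` and `Kir21` (one entry each,
expressed everywhere) are frozen in every protocol because they set the
passive properties.

**All kinetic constants are engineering surrogates, not published channel
fits.**  Two deliberate design features matter for the science:

1. *Within-class overlap.*  Channels of one functional class — the
   voltage-gated K class (Kv11…Kv723), the Ca-activated K pair (BK, SK),
   the high-threshold Ca class (Cav12/13/22/32) — share their steady-state
   parameters and differ only in time constants, exactly the construction
   used for artificial isoforms.  Degeneracy (mutual substitutability) is
   therefore built in at the class level, which is the property whose
   population-level consequences the experiments measure.
2. *Class-total conservation.*  Baseline densities split each class total
   roughly evenly across its members as the roster grows, so the three
   baselines produce similar firing (rest ≈ −83 mV, 3 spikes at 50 pA,
   5 at 90 pA) while differing in how many independent parameters carry
   each function.

The Kv activation midpoint (−30 mV) deliberately reaches into the
spike-downstroke voltage range so that the Kv class genuinely shares the
repolarisation/fAHP role with BK rather than acting only at the spike peak;
without that overlap the class split would add parameters without adding
compensation, and diversity would *reduce* robustness.

### Integration

Fixed-step integrator: exponential-Euler gate and calcium updates and an
implicit (backward-Euler) voltage step solved exactly on the compartment
tree, so the scheme is unconditionally stable and charge balance holds to
solver round-off at every step (asserted in the tests).  Gate steady states
and exponential-Euler factors are tabulated on a 0.05 mV voltage grid at
simulation start (the tables are built from the same public gate functions
and rebuilt when dt changes).  Default dt is 0.025 ms; population-scale
screening (population sampling, walks, sweeps, expansion, knockout refits
in the acceptance suite) runs at dt = 0.1 ms, the coarsest step the solver
accepts, with feature targets generated at the same dt.  The orderings
reported by the acceptance suite were checked to be unchanged at dt = 0.05
and 0.025; sup-norm trace differences decrease monotonically under dt
halving and the subthreshold trajectory agrees to < 0.05 mV.

Every simulation starts from a settle-in at zero current whose final state
defines V_rest.  The settle-in caps at 500 ms and exits early once
max |dV/dt| stays below 10⁻⁴ mV/ms for 20 ms; the exit changes nothing
about the dynamics, it only skips integration of an already-stationary
state.  The 50/90 pA protocols of one evaluation share a single settle-in.

### Features and fitness

Nine features are extracted per protocol (50 and 90 pA, 50 ms pre / 200 ms
step / 50 ms post): spike count, latency, threshold (V_m where dV/dt first
exceeds 15 mV/ms), mean amplitude, signed fAHP (threshold minus the minimum
within 5 ms after the peak), |fAHP|, width at half amplitude (linear
interpolation between samples), first ISI, adaptation index
`AI = 1 − ISI₁/ISI_end`.  After an onset no new onset is accepted until V_m
falls back below that spike's threshold (refractory rule against double
counting).  Features whose prerequisites are absent (no second spike → no
ISI) carry NaN and are skipped by the fitness maximum; the spike-count
deviation carries the penalty in those cases.

Fitness per feature is `F_i = |SF_i − mean_i| / SD_i`; the Pareto
efficiency `P = max F_i` over all defined (feature, protocol) pairs, and a
model is valid iff `P < 2` (strict).  A model with zero spikes at both
amplitudes receives the sentinel `P = 6`.  Both amplitudes contribute to
the maximum — the package computes every feature at both stimuli, a
documented convention.

Targets are generated from a reference simulation: means are the reference
features; SDs are `max(f·|mean|, floor)` with per-unit floors (0.5 spikes,
1 ms, 1 mV, 0.05 unitless).  The default SD fraction is `f = 0.15`, chosen
as a realistic coefficient of variation for repeated-cell
electrophysiology; with the floors it yields 0–2× population valid
fractions of ~5–30%, random-walk survivals of tens of steps, and ±20%
neighbourhood validity of ~60–90% — the qualitative scale of the original
population analyses.  Because targets are self-generated from each
baseline, cross-model comparisons measure the *geometry* of each model's
valid region around an exactly valid centre, not agreement with any real
dataset.

## Search

Powell-style successive line minimisations: slopes per dimension from two
sample points at ±5% of the parameter value; line minimisation by
expanding geometric steps plus golden-section refinement (≤ 20 evaluations
per line, parameters clipped at zero); after each sweep the direction of
largest gain is replaced by the sweep's aggregate displacement.  When both
probes of a line agree exactly with the centre (a flat plateau, typically
the non-spiking sentinel) the line is skipped; when a whole sweep fails to
improve, the probe step escalates in +5-percentage-point increments to
±50%, after which parameters are randomised in an increasing range (±10% →
±50% in ±10% steps), the direction set resets to the axes, and the
schedule restarts.  "Stalled" means two full escalation+randomisation
rounds without improving P by more than 10⁻⁶.  The search stops at P < 2
by default; baseline-construction uses that criterion, while the isoform
expansion refines to a lower threshold (0.1) so the refitted model sits
near the *centre* of its valid region rather than its edge — a baseline at
the edge would make the measured 0–2× valid fraction an artefact of the
stopping rule.

On random positive-definite quadratics in ≤ 5 dimensions the search
recovers the analytic minimum to ≤ 10⁻² (tested against the closed form).

## Population protocols

* **Sampling**: each non-frozen density independently uniform on
  [0, 2]× baseline (frozen pas/Kir21 fixed).  Valid fraction with Wilson
  95% CI.  The estimator is validated against the exact Irwin–Hall
  probability using the toy validity rule as evaluator.
* **Range sweeps**: uniform on [1−w, 1+w]× a valid reference.
* **Correlations**: Pearson r over valid rows, exact-t two-sided p-values,
  flags at p < 0.01, no multiple-testing correction.
* **Random walks**: every free parameter multiplied per step by an
  independent uniform factor in [0.95, 1.05]; a walk ends at the first
  invalid state.  Histograms use a 4-step bin width.
* **Isoform expansion**: k isoforms of BK and Cav22 added in alternation,
  gate time constants rescaled by uniform factors on [0, 2); the parent
  class total is split evenly across copies so the expanded default keeps
  the 5-channel class totals; conductances are then sampled in a two-fold
  range, the best three candidates refined by the search, and the best
  refined model becomes the new baseline.
* **Hyperplanes**: pairs are connected iff all nine convex interpolants
  (w = 0.1 … 0.9) are valid; triplets evaluate P on the
  (w₁, w₂) ∈ [−1.5, 2.5]² grid with step 0.04 (w₃ = 1 − w₁ − w₂),
  masking combinations with any negative parameter.  The uniform grid does
  not contain the unit-weight corners, so the three exact vertices are
  appended to the evaluated set (vertex identity is part of the contract).

## Toy model

Each parameter is uniform on [0, 2]; the output is the row mean; a sample
is valid iff |mean − 1| < 0.015 (strict).  The valid fraction for n
independent variables has the exact Irwin–Hall form evaluated through
`scipy.stats.irwinhall` (numerically stable splines; the sum of n U(0,1)
is IH(n), and the mean of n U(0,2) maps onto it linearly).  Note that the
frequently quoted normal approximation at n = 8 (0.0586) differs from the
exact value (0.05748); tests assert the exact oracle, which Monte Carlo
confirms.

For the monotonicity-in-n experiment the fractions for n = 1 … 20 are
computed from prefixes of one common sample matrix (common random
numbers), which cancels most Monte Carlo noise from the comparison without
changing any marginal estimate.

Correlated variants use a Gaussian copula with equicorrelation ρ
(feasible only for ρ ≥ −1/(n−1); the eigenvalue decomposition handles the
PSD boundary).  The uniform outputs then have Pearson correlation
(6/π)·arcsin(ρ/2), the classic closed form used as a test anchor.  The
"distributed" sampler places each new variable uniformly in the largest
gap between the ordered existing values (boundary gaps included, ties
broken at the lowest left endpoint).  Valid sets under the mean-constraint
show mean pairwise correlation ≈ −1/(n−1) — the compositional-constraint
value — which is why the observed output correlation depends on n but
barely on the input ρ.

Nonlinear interaction orders follow
`v₀ = S(u)`, `v₁ = S(M·S(u))`, `v₂ = S(M̂·S(M·S(u)))` with
`S(x) = −1 + 2/(1+e^(−x))` (= tanh(x/2)) and column-normalised random
matrices on [−1, 1] (near-zero column sums redrawn).  The validity rule for
these variants is unstated in the linear construction, so the package
keeps the distance-to-target semantics: the reference output is the
transform of the all-ones vector under the same matrices, and a sample is
valid iff |mean(v) − mean(v_ref)| < 0.015.

## What the synthetic defaults do not emulate

* No reconstructed morphology, no published channel kinetics (including
  the 8-state Markov Na scheme), no HCN channel, no temperature
  dependence: passing tests show that the *population-level phenomena*
  (LLN-driven growth of valid fractions, walk stability, knockout
  compensation, isoform gains) emerge from class-structured degeneracy in
  a conductance-based model family — not that the surrogate reproduces any
  real cell's numbers.
* Targets are self-generated; absolute valid fractions scale with the
  chosen SD fraction and floors and should be compared only across models
  evaluated under the same targets.
* The two-fold sampling range, ±5% walk steps, tolerance 0.015, weight
  grids and sentinel 6 are fixed protocol constants of the study design.

## Reproducibility

Every stochastic operation takes a seed; CLI commands and the acceptance
script split one global seed into per-component child seeds via
`numpy.random.SeedSequence`, so adding a consumer never shifts another's
stream.  Problem sizes in the acceptance suite (500-sample populations,
200 walks capped at 200 steps, 400-sample ±20% sweeps, 150-candidate
expansion screens, 10⁶-sample toy experiments) are the package's standard
screening sizes; all ordering results were additionally spot-checked at
larger sizes and finer dt during development.
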