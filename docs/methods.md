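# Methods

## The channel model

`hergfit` ships a single built-in model of the rapid delayed-rectifier
potassium current IKr, carried by channels encoded by hERG.  The channel
is described by a four-state continuous-time Markov scheme — open (O),
closed (C), inactivated-open (IO), inactivated-closed (IC) — with
conservation `[IC] = 1 − ([O] + [C] + [IO])` substituted structurally, so
only three occupancies are integrated and probability conservation holds
by construction rather than numerically.  The observed current is

```
IKr = GKr · [O] · (Vm − EK)
```

with `GKr` the maximal conductance (μS) and `EK` the K⁺ reversal
potential (mV).  Each of the four transition rates is a two-parameter
exponential function of voltage,

```
kO = kO1·exp(+kO2·Vm)     kC = kC1·exp(−kC2·Vm)
kI = kI1·exp(+kI2·Vm)     kA = kA1·exp(−kA2·Vm)
```

giving nine free parameters.  Internal units are fixed: ms, mV, ms⁻¹,
μS, nA.

This topology factorises exactly into two independent Hodgkin–Huxley
gates: activation `a = O + IO` with `da/dt = kO(1−a) − kC·a`, and
recovery-from-inactivation `r = O + C` with `dr/dt = kA(1−r) − kI·r`,
with `O = a·r` for any product-state initial condition.  At constant
voltage each gate relaxes as a single exponential with
`a∞ = kO/(kO+kC)`, `τa = 1/(kO+kC)` (and analogously for `r`), which
provides a closed-form solution used as an independent test oracle.

## Simulation

Two simulators are cross-checked against each other and against the
constant-voltage closed form:

* `simulate` — the reference route: scipy's stiff-capable LSODA on the
  (O, C, IO) system, restarted at every protocol-segment boundary so
  voltage discontinuities are never smoothed by the stepper.  Default
  tolerances rtol 1e-7 / atol 1e-9 give comfortable margin against the
  1e-6 oracle-agreement requirement.
* `simulate_fast` — the inference route: exact exponential propagation of
  the two gates.  On constant-voltage segments the update over any step
  is exact; on ramp/sine segments the voltage is frozen at the midpoint
  of substeps of at most 0.05 ms, a second-order (exponential-midpoint)
  rule.  The inner loop is numba-compiled.  Measured agreement with the
  reference simulator on the fixture protocol is ~1e-7 in state
  occupancies and well below 1e-5 nA in current — two orders of magnitude
  below the observation noise.

The initial condition is always the steady state at the protocol's t = 0
voltage (standard voltage-clamp practice; it also makes runs
deterministic).  Rate evaluation clips no exponents silently: any
exponent beyond ±700 raises, and inference treats the parameter set as
having zero probability.  Occupancies are verified to stay within
[−1e-8, 1+1e-8] along every trajectory and are clamped to [0, 1] for
output.

## The fitting problem

A fitting experiment binds four artefacts by name: the model, a JSON
voltage-protocol file, a CSV data table, and a JSON fitting
specification with entries `algorithm`, `arguments`, `output`,
`input`, `prior` (plus an optional `units` sidecar).  Simulation sample
times are taken from the data column bound via the `input` map, so a
protocol never needs editing when new data arrive; the `output` map pairs
a data column with the model output it constrains.  Units must match the
model's, with one narrow, explicit exception: a time column declared in
seconds is converted to ms (patch-clamp CSV exports conventionally store
seconds while channel kinetics live on milliseconds).

Priors are per-parameter `Uniform(lower, upper)` boxes or fixed `Point`
values.  The shipped hERG document uses `Uniform(1e-7, 0.1)` for the
eight kinetic parameters, `Uniform(0.0612, 0.612)` for `GKr`, and a
Point value 0.00463 nA for the observation-noise standard deviation
`obj:std` (it may equally be declared Uniform and learned).  On top of
the box, a physiological **rate constraint** assigns zero probability to
parameter sets whose transition rates are implausible: for each rate, its
maximum over the clamp window V ∈ [−120, 60] mV (attained at a window
endpoint, by monotonicity) must lie within [1.67e-5, 1000] ms⁻¹ — the
rate must be achievable somewhere in the window without ever becoming
faster than diffusion-limited kinetics.  Both the window and the rate
bounds are configurable.

The likelihood is Gaussian over the whole trace:
`log L = −n/2·log(2πσ²) − Σ(yᵢ−ŷᵢ)²/(2σ²)`.  A failed simulation yields
−∞ (rejection), and a zero-probability prior short-circuits evaluation so
no ODE solve is wasted.

## Inference pipeline

Two stages, as is conventional for whole-trace ion-channel fitting:

1. **Start-point selection** — `cmaOpt` independent restarts of CMA-ES
   (authored in-package: rank-1 + rank-μ covariance update, cumulative
   step-size adaptation, box constraints by resampling), each budgeted
   `cmaMaxFevals` objective evaluations.  Each restart screens 100
   admissible uniform prior draws (counted against its budget) and starts
   from the best; if a search stalls for 60 generations with budget left
   (typically a flat basin where the channel barely conducts), the
   remaining budget is reinvested from the next-best screened start.
2. **Sampling** — adaptive-covariance Metropolis in the Haario–Bardenet
   variant: multivariate-normal proposals
   `N(θ, 2.38²/d · λt · Σt)`, where after a 200-iteration initial phase
   the mean/covariance estimates and the global scale λ adapt with
   exponentially decaying weights `γt = t^(−0.6)`, the scale steered
   toward 23.4% acceptance.  Out-of-support proposals are rejected and
   counted.  The first `burn` of `numIters` iterations are discarded.

Three design choices matter for this model class and are on by default
(each can be switched off):

* **Log-scale coordinates.**  The kinetic parameters are positive scale
  parameters whose plausible values span six decades within a common
  prior box.  Both CMA-ES search and MCMC sampling therefore operate on
  log-transformed coordinates (the MCMC target carries the Jacobian
  correction, and chains are reported in natural units).  Untransformed
  sampling is available via `transform="linear"` but mis-scales proposals
  for the small rate prefactors by several orders of magnitude.
* **Conductance profiling (variable projection).**  The current is linear
  in `GKr`, so under its flat prior the conditionally optimal conductance
  is a closed-form least-squares coefficient.  CMA-ES searches only the
  remaining dimensions with `GKr` profiled out, removing the strongest
  correlation direction from the global search.  The MCMC stage samples
  all free parameters, including `GKr`.
* **Covariance hand-off.**  The winning CMA-ES search covariance (mapped
  to sampling coordinates) seeds the MCMC proposal covariance, falling
  back to a diagonal of (1% of each range)² where unavailable.  The
  proposal floor is relative — `1e-9 × diag(initial covariance)` — rather
  than an absolute jitter, which would swamp the posterior scale of the
  tightly constrained prefactors.

`cmaMaxFevals` is interpreted per restart, matching the semantics of a
max-evaluations option passed to each run of a restarted optimiser; a
`budget_per_restart=False` switch divides it as a total instead.  One
master seed drives everything; CMA-ES restarts and the MCMC chain use
sub-seeds derived from it, and identical inputs plus seed reproduce the
chain bit-for-bit.

## Posterior summaries

The MAP estimate is the argmax of the stored log-posteriors over the
starting point and the retained chain (ties to the earliest occurrence).
Credible intervals are equal-tailed empirical quantiles with linear
interpolation between order statistics.  Marginal histograms default to
50 bins over the retained-sample range.  Identifiability is flagged with
two operational heuristics: *flat* if the 95% credible interval exceeds
80% of the prior range, and *multimodal* if the 3-bin moving-average
smoothed histogram has more than one distinct mode — a local maximum
above 20% of the peak, where adjacent maxima merge unless the valley
between them drops below 50% of the smaller one (sampling noise on a
unimodal histogram produces shoulder maxima with shallow valleys, which
must not count).  The thresholds operationalise what a practitioner
judges by eye from a marginal histogram; they are configurable and
always reported alongside the raw marginals.

## Synthetic data

The generator produces exactly what the likelihood assumes: a noise-free
model trace on a regular grid plus i.i.d. Gaussian observation noise.
Defaults define the study conditions: σ = 0.00463 nA, sampling every
0.1 ms, and a 12 s fixture clamp — 2 s hold at −80 mV, a staircase of six
500 ms steps spanning −60…+40 mV each followed by 500 ms at −40 mV,
a 2 s sinusoid (offset −30 mV, amplitude 30 mV, period 200 ms), and a
final 2 s hold — chosen to excite activation, deactivation, inactivation
and recovery across the physiological voltage range so the nine
parameters are jointly identifiable.  The default "true" parameters are
synthetic constants in the style of published whole-trace hERG kinetics
(prefactors 3.45e-5…0.0873 ms⁻¹, sensitivities 0.0089…0.070 mV⁻¹,
GKr 0.1524 μS), strictly inside the prior box and the rate-constraint
region, with peak signal-to-noise ≈ 375.  Data files store time in
seconds (converted by the binder) and currents in nA.

What the generator deliberately omits: leak current, baseline drift,
capacitance transients, filtering, and any non-Gaussian or correlated
noise.  Passing recovery tests therefore demonstrate the correctness of
the simulator–likelihood–sampler chain under the model's own
assumptions, not robustness to the artefacts of raw patch-clamp
recordings, which are expected to be removed in pre-processing.

## Problem sizes and numerical choices

The verification suite runs a scaled-down recovery study: 1 ms sampling
(12,001 points), 2 CMA-ES restarts × 4,000 evaluations, 20,000 MCMC
iterations with 10,000 burn-in — roughly two minutes of computation —
rather than the full 0.1 ms / 5 × 20,000 / 100,000-iteration study the
shipped specification describes.  Under these reduced budgets the
recovery outcome is seed-sensitive: most seeds land the optimiser within
reach of the mode and recover the truth (95% intervals covering the
conductance and all eight kinetic parameters, MAP RMSE ≈ σ), but an
unlucky pair of restarts can leave the chain short of equilibrium within
the budget.  The full budgets remove this sensitivity in our experience;
the reduced-budget numbers are reported as computed.

Degenerate inputs are handled explicitly: empty protocols, non-positive
durations, non-factorisable initial states for the analytic oracle,
all-Point priors (representable, but rejected at binding since inference
needs at least one free parameter), ragged/duplicate/non-numeric CSV
content, and zero-probability MCMC starting points all raise typed
errors.  Ties in the MAP argmax resolve to the earliest point; histogram
mode detection treats plateaus as single candidates.

## Known limitations

* Only the built-in hERG topology ships; there is no CellML/SBML
  ingestion, temperature dependence, or drug-block term.
* Only Gaussian whole-trace likelihoods and box/point priors are
  supported; `objective` is reserved for future likelihood families.
* Convergence diagnostics beyond the acceptance rate (R-hat, effective
  sample size) are not computed.
* Unit handling converts time only; any other mismatch is an error by
  design rather than an automatic translation.
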