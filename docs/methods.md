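# Methods

## Generative model

A behavior stream is modeled as an alternating renewal process (ARP) in
equilibrium. Event durations are i.i.d. Exponential(μ), interim times
i.i.d. Exponential(λ), all mutually independent; under this model the
occupancy probability at any instant is constant at π = μ/(μ+λ).

Equilibrium initialization exploits memorylessness: the initial state is
Bernoulli(π), and the residual time of that state is drawn from the same
exponential as a full duration. This is exact for the exponential family;
for other duration families the residual would need the length-biased
equilibrium distribution, which is one reason the package ships only the
exponential (`DURATION_FAMILIES` is the extension point, deliberately left
with a single entry). The degenerate λ = 0 case (π = 1) returns a single
event spanning the session.

Events are half-open intervals [onset, offset); a final event still in
progress at session end keeps its onset and is clipped to the session
length. Generation is batched (whole cycles drawn per numpy call) so a
session costs a handful of vectorized draws regardless of event count, and
the draw order is fixed, making streams bit-reproducible per generator
state.

## Recording rules and boundary conventions

With n = floor(L/τ) intervals (a trailing partial interval is discarded
and never influences marks):

- **MTS** marks interval k iff the behavior occurs at t = kτ, with
  half-open membership onset ≤ t < offset.
- **PIR** marks iff some event overlaps the open interval ((k−1)τ, kτ)
  with positive measure.
- **WIR** marks iff one event covers the closed interval [(k−1)τ, kτ].
  Since events are separated by positive interims, a single covering event
  is equivalent to the behavior occurring throughout.

One boundary case needs an explicit convention. An event in progress at
session end is clipped to offset = L, and the final MTS sample falls at
t = L exactly; strict half-open membership would score it 0 while the
behavior is genuinely occurring, and would let WIR mark an interval MTS
does not. The rule adopted: at t = L only, an event whose clipped offset
equals L counts as occurring. With it, WIR ≤ MTS ≤ PIR holds elementwise
for every stream the generator can produce. Interior coincidences
(an offset exactly equal to a sample time or interval edge) have
probability zero under the continuous model and resolve deterministically
by the half-open/closed rules above; hand-constructed streams that place
an offset exactly on an interior sample point can still score WIR = 1,
MTS = 0 there, which is the known knife-edge of these definitions rather
than a property of simulated data.

## Estimators

From a mark vector: PF = r + n₀₁ (equivalently the number of marked runs),
θ = number of marked intervals, p̂ = θ/n, corrected p̂ = (θ − PF)/n for
PIR and (θ + PF)/n for WIR, and for PIR the frequency estimate
f̂ = −n·ln(1 − θ/n). Numerical conventions:

- Corrected estimates are clipped into [0, 1]. (θ−PF)/n cannot go negative
  because PF ≤ θ, but (θ+PF)/n exceeds 1 for strongly alternating records.
- f̂ at θ = n is singular; it returns NaN as a typed "undefined" flag.
  Summaries exclude NaN values and report an exclusion count
  (`n_undefined`) instead of propagating infinities or aborting a run.
- Relative bias (p̂ − π)/π is computed against both baselines — the
  generating parameter and the session's continuous-recording prevalence —
  and reported side by side; it is undefined (error, or None inside
  `estimate_set`) when the truth is 0.

## Experiment design

`run_experiment` walks a prevalence grid (default 0.05–0.95 in steps of
0.05, 19 points), derives λ from (μ, π) per point, simulates `replicates`
sessions, and within each replicate applies every requested procedure *to
the same stream*. The common-stream choice leaves all marginal summaries
unchanged in expectation but makes cross-procedure comparisons
positively coupled and preserves the WIR ≤ MTS ≤ PIR ordering at the
replicate level. Replicate substreams are seeded from
(seed, grid index, replicate index) via numpy's `SeedSequence` mechanism,
so any cell reproduces in isolation and the whole result is deterministic
per seed.

Summaries per (procedure, π) cell: mean and sample SD (n−1 denominator) of
each estimator, ±1 and ±2 SD bands (omitted for a single replicate), mean
continuous prevalence and count, and the relative biases of the mean
estimate. Typical designs are sessions of 10–60 min, τ of 2–20 s, μ of
2–120 s and 1, 100 or 1000 replicates; all are free parameters.

## What the simulations do and do not show

The generator emulates a single behavior category recorded by an error-free
observer under exponential ARP dynamics. Real observational data add
observer reaction time and perception error, possible dependence between
successive bout lengths, non-exponential (often heavy-tailed) durations,
and multi-category coding — none of which are modeled. Passing tests
therefore establish the *sampling-theoretic* properties of the recording
rules and estimators (bias directions, μ/τ scaling, precision orderings),
not the field reliability of any particular observation protocol.

Two printed-value caveats are documented rather than matched: the
incidence range endpoints conventionally quoted for the μ = 18 and μ = 2
designs, 0.1 and 28.6 per minute, are rounded differently than the direct
computation 60/(μ+λ) at the grid extremes gives (0.17 and 28.5); the
package always reports the unrounded values.

## Test and check sizes

Stochastic checks use fixed seeds and 3 Monte-Carlo standard errors.
Problem sizes were chosen as the smallest that leave Monte-Carlo error
well below the effects being detected: 1000 replicates for unbiasedness
and ratio checks (SE of a mean prevalence ≈ 0.001–0.002), 100 replicates
for the bias-direction designs where the effects are an order of magnitude
larger, 200 random streams for exact oracle agreement. A joint 19-point
3 SE unbiasedness check has roughly a 5% intrinsic false-alarm rate under
the null; the estimator itself was verified to have grand-mean deviation
indistinguishable from zero across independent seeds.

## Known limitations

- Only exponential durations; no dependence structures; one behavior
  category.
- WIR frequency estimation is not provided (no supported estimator).
- The millisecond-grid oracle used in tests requires stream boundaries on
  the 1 ms grid; it is a test instrument, not part of the library surface.
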