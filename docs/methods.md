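# Methods

## Model and assumptions

The circuit is a deterministic mass-action model of a type I toxin–antitoxin
module: toxin mRNA (*m*) and antitoxin sRNA (*s*) are transcribed from *g*
plasmid copies, bind reversibly (h⁺, h⁻) into a translationally silent
complex (*c*) with its own decay rate (β_c), and free mRNA is translated
into toxin protein (*p*). Concentrations are molecule numbers per cell
volume treated as dimensionless; all times are minutes. Simplifications
inherited from the modeling tradition for these circuits:

* mRNA folding/processing states are averaged into effective synthesis and
  degradation rates;
* dilution by growth is folded into the degradation rates (so β's are
  bounded below by the growth rate in realistic parameterizations);
* no stochasticity — molecule numbers are taken large enough for rate
  equations, which is why random sampling enforces α_m > β_m and
  α_s > β_s;
* no feedback of the toxin on growth or plasmid replication, and no
  explicit killing decision: the readout is the fold-increase of the toxin,
  not cell fate.

The plasmid copy number *g* is a continuous non-negative parameter so that
copy-number scans are expressible; event schedules normally step it through
integers.

## Default parameters

The canonical set (units 1/min except *g*) is literature-derived:
α_m = 1.0, β_m = 0.2, α_s = 6.0, β_s = 1.0, α_p = 5.0, β_p = 0.035,
h⁺ = 20.0, h⁻ = 1.0, β_c = 0.1, g = 6. The competitor defaults are
α₂ = 4.0, β₂ = 0.6, k⁺ = 60.0, k⁻ = 1.0, β_c₂ = 0.1. The interesting
ratios are α_m/α_s < 1 (sRNA excess), β_m/β_s < 1 (mRNA outlives sRNA) and
β_c/β_s < 1 (complex outlives sRNA): all three are required for a strong
post-loss toxin burst, as the scans and the sampled cloud show.

## Steady states

At a fixed point the nonlinear binding terms cancel between the *m* and
*s* balances, so with K = h⁺β_c/(h⁻+β_c) the sRNA level solves

    (K β_s) s*² + (β_s β_m + (α_m − α_s) g K) s* − α_s g β_m = 0,

whose "+" branch is the only non-negative root (the discriminant exceeds
the square of the linear coefficient). Back-substitution gives m*, c*, p*.
Degenerate guards: g = 0 → all zero; K = 0 (no binding or indestructible
complex) → decoupled birth–death; β_m = 0 or β_s = 0 with g > 0 → error
(no finite fixed point guaranteed); β_p = 0 → p* = ∞ sentinel, and
transient metrics fall back to the trajectory value. Every solution is
residual-checked at 1e-8 relative — far above double-precision noise,
far below any dynamical scale of the default set.

With an active competitor the same elimination leaves a cubic in m*
(coefficients derived from the six fixed-point conditions; the derivation
is spelled out in `tasim/competitor.py`). Roots are located by scanning
10⁴ uniform subintervals of [0, α_m g/β_m] (the no-repression bound on m)
for sign changes and bisecting to 1e-12 relative. A root is physical iff
all six back-substituted concentrations are non-negative and the residual
check passes; should several qualify, a confirmation integration picks the
attracting one — there is no silent heuristic pick.

## Integration

Classical fixed-step RK4, base step dt = 1e-4 min, horizon 300 min,
sampled every 0.01 min; event times (copy-number steps, competitor
induction) are hit exactly by shortening the crossing step, and the
competitor species are reset to zero at induction. Two adaptivity
mechanisms:

* **Negativity rejection** — a step producing a component below −1e-12 is
  rejected and retried at half the step, down to dt_min = 1e-9 min (then
  an error naming the failure time). After a clean streak at reduced step
  the step doubles back toward the base step; the required streak starts
  at 100 and doubles (to at most 10⁶) whenever a rejection follows shortly
  after a doubling, so marginally unstable regimes are not re-entered
  every 100 steps. Negatives in (−1e-12, 0) are round-off and are clamped.
* **Stability cap** — each step is also capped at 2/L, where L sums the
  state-dependent first-order rates (h⁺(m+s), h⁻, all β's, competitor
  analogues) and therefore bounds the Jacobian's spectral radius. This
  keeps RK4 well inside its real-axis stability interval (≈2.79/λ) for
  stiff-but-stable parameter sets — e.g. huge h⁺·s — where weakly growing
  oscillations would otherwise evade the negativity trigger for long
  stretches and bias the slow species. For the default set the cap
  (~3e-3 min) is far above the base step and changes nothing.

With both mechanisms, trajectories for random Table-range parameter sets
agree with SciPy's LSODA at rtol 1e-11 to ~1e-9 relative; step-halving
ratios confirm fourth-order convergence. Runs are additionally bounded by
`max_steps` (2×10⁸ by default, 2×10⁷ inside sweeps ≈ a couple of seconds
per run); a run exceeding it errors and is recorded as failed in sweep
tables rather than silently truncated.

## Transient metrics

`R` is the maximum post-event protein level divided by the level at the
last sample at or before the event (a trajectory quantity, so metrics stay
meaningful for un-equilibrated runs; a warning fires if it deviates >1%
from the analytic p*). The discrete maximum is refined by a three-point
quadratic fit. `R = 0` encodes "no peak": the post-event maximum sits at
the event itself, or no maximum exceeds the pre-event level by more than
1e-4 relative. The margin matters: circuits just past the peak-abolishing
thresholds (e.g. α_m > α_s) still show genuine micro-bumps of a few 1e-6
relative immediately after the event from residual complex release; the
1e-4 margin classifies those as peakless, matching how the field reads
"the peak disappears", while real peaks are orders of magnitude above it.

`T_p` is the full width at the **absolute** half level p_peak/2, crossings
located by linear interpolation; this convention reproduces the published
48-min width for the default circuit (a baseline-subtracted convention was
the alternative; it was not needed). For partial-loss events whose
post-event plateau sits above p_peak/2, the width is measured above
(p_peak + p_end)/2 and flagged; flagged and unresolved widths stay in
sweep tables with a status column but are excluded from the
valid-measurement population. If the protein has not fallen below the
half level by the horizon, the metric raises ("peak not resolved; extend
t_end") unless asked to return partial, NaN-width metrics — the β_p = 0
saturating rise is the canonical such case, and its R (the plateau over
the pre-loss level, ≈4 for the defaults) is still well-defined.

## Instant-release approximation

Dropping the binding dynamics after total loss and releasing the complex
pool at once gives m(t) = (m*+c*)e^(−β_m t) and a double-exponential p(t)
whose peak has a closed form; it overestimates the simulated peak because
the complex actually releases mRNA gradually. The released fraction φ of
the complex pool is exposed (default 1 — the plain formula); fitting φ to
the simulation is out of scope. The sign of the reduced mRNA equation is
decay (−β_m m), and the initial mRNA is m*+c*, consistent with the
double-exponential solution. The confluent case β_m = β_p errors rather
than guessing the t·e^(−βt) form; β_p = 0 returns the asymptote as an
infinite-time peak.

## Parameter exploration

Scans vary one rate in isolation and run the loss experiment per value
(competitor scans report the analytic steady fold-increase R̃ instead —
the competitor readout is a steady state, so no integration is needed).
Per-row failures are recorded in the table, never fatal.

Random sampling draws from the nine-parameter box (g = 6 fixed): the
(α_m, α_s) and (β_m, β_s) pairs are drawn so that the log of their ratio
is uniform over the achievable range (draw u = log-ratio, then the
denominator uniform over the compatible interval), the remaining five
rates uniform; every value is snapped to its per-parameter resolution
grid anchored at the lower bound, and draws violating α_m > β_m or
α_s > β_s are redrawn. This is one concrete procedure consistent with the
one-sentence description of log-uniform ratio sampling that accompanies
the published parameter table; a per-parameter log-uniform draw was also
evaluated and produces a qualitatively different (and much less
structured) cloud, so the ratio-based procedure is the one shipped.
Tables carry seed and spec hash and serialize to TSV with commented
headers; identical spec + seed reproduces tables byte-for-byte.

## What the tests show — and don't

All inputs are generated by the package itself from printed parameter
values; there is no external data. Passing tests therefore demonstrate
internal consistency (analytic vs numeric fixed points, closed forms vs
brute-force oracles, convergence order, published anchor values of the
default circuit) and the qualitative parameter-space structure at n = 500
samples — not biological fidelity of any particular rate estimate, nor
behavior under stochastic fluctuations at the most relevant low molecule
numbers. The sampled-cloud fractions are stochastic at n = 500; the
sample size keeps the default test run in minutes on one CPU, and the
structural statements tested (synthesis-ratio threshold, complex-stability
split) are robust at that size even though individual percentages move by
a point or two across seeds.

## Known limitations

* The marginal region α_m/α_s ∈ (0.8, 1) genuinely contains a small
  fraction of circuits with modest peaks (R up to ~4); the 0.8 threshold
  is an approximate boundary, not a sharp one.
* Extremely stiff draws (β_s at the grid floor with large h⁺) can exceed
  the sweep step budget and are reported as failed rows (~3-4% of Table-
  range draws) rather than integrated at unbounded cost.
* The competitor analysis covers steady states and induction dynamics;
  transient peaks of the competitor scenario are not a supported metric.
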