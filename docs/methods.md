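# Methods

## The model

`alternanspop` simulates a single human ventricular **epicardial**
myocyte with the 2004 ten Tusscher–Noble–Noble–Panfilov formulation: a
Hodgkin–Huxley-type membrane equation

dV/dt = −(I_ion + I_stim),

with currents carried per unit membrane capacitance (pA/pF) and

I_ion = I_Na + I_K1 + I_to + I_Kr + I_Ks + I_CaL + I_NaCa + I_NaK
      + I_pCa + I_pK + I_bCa + I_bNa.

The state comprises V, 12 gating variables (fast-Na m/h/j, L-type
d/f/fCa, transient-outward r/s, slow-delayed xs, rapid-delayed xr1/xr2,
and the SR release gate g) and the concentrations Na_i, K_i, Ca_i and
Ca_SR with rapid-equilibrium cytosolic and SR calcium buffering.  All
equations and fixed parameters are the published epicardial values.

Ten maximal conductances are exposed for scaling (table order):
g_Ks 0.245, g_Kr 0.096, g_K1 5.405, g_Na 14.838, g_bNa 0.00029,
g_CaL 1.75e-4, g_bCa 0.000592, g_to 0.294, g_pCa 0.825, g_pK 0.0146
(reference-model units: nS/pF except g_CaL in cm³·µF⁻¹·s⁻¹ and g_pCa in
pA/pF).  The defaults are the reference model's published epicardial
values; a scenario scales each of the ten by 0.5, 1.0 or 1.5, giving the
3¹⁰ = 59,049-member population.  Pump/exchanger/SR maxima (P_NaK,
k_NaCa, Vmax_up, V_leak, a_rel, c_rel) are fixed constants, never
scaled, though they are fields of `ConductanceSet` for restartability.

Two formulation details worth knowing:

* the published fCa steady state slightly exceeds 1 (up to ≈1.048) at
  diastolic Ca_i; it is deliberately left unclamped (clamping would
  change I_CaL by up to ~5%), and state validation allows fCa ∈ [0, 1.05];
* fCa and g may not move toward larger (recovered) values while
  V > −60 mV, the reference model's voltage-conditional freeze.

## Numerics

Rush–Larsen exponential updates for all Hodgkin–Huxley gates, forward
Euler for V and the concentrations, fixed step **dt = 0.02 ms**
(configurable).  Halving dt changes baseline APD90 at 1000 ms pacing by
well under 1 ms (tested), and quartering it moves the worked-scenario
biomarkers negligibly.  The L-type driving force uses the exact
GHK-like expression with a series expansion within |2VF/RT| < 1e-7 of
the removable singularity at V = 0.  Integration is JIT-compiled
(numba); a full descending protocol with deep steady-state
initialization runs in roughly two to four minutes on one core.

The stimulus is −52 pA/pF for 1 ms, the conventional twice-threshold
pulse of the reference implementation.  Because the stimulus charge is
booked into the K_i balance, its size shifts the paced ionic steady
state and therefore the alternans bifurcation; −52 pA/pF·ms is the
value under which the package reproduces the worked scenarios' onset
cycle lengths (see "Reproduction fidelity" below), and it is
configurable in `IntegratorConfig`.

## Pacing protocol

The clinical alternans-provocation protocol: initialize to a paced
steady state at 750 ms cycle length, then descend 750→350 ms in 50 ms
decrements and 340→180 ms in 10 ms decrements (26 cycle lengths), with
74 stimuli at each cycle length and **continuous state carry-over**
between cycle lengths.  Re-initializing at every cycle length was tested
and rejected: it produces alternans at implausibly long cycle lengths
and incomplete capture immediately below them, contradicting the
dynamic-restitution behavior the protocol is designed to elicit.

Steady-state initialization paces at a fixed cycle length until the
maximum relative change of any state variable sampled at stimulus times
falls below 1e-6, capped at 8000 beats.  The tolerance is deliberately
strict: the slow Na⁺/K⁺ drift takes thousands of beats to finish, and
the alternans onset of calcium-loaded scenarios depends on it (with only
a few hundred pre-pacing beats, the longest-onset scenario loses its
alternans at 550 ms entirely).  In practice the relative change plateaus
near 1e-5 — beat-to-beat jitter of the paced limit cycle — so the
8000-beat cap is the operative condition; it is part of the protocol
definition, and because a marginally unstable cycle length amplifies the
residual entry-state mismatch exponentially over the 74-beat train,
near-onset ANM values (and in extreme cases the onset cycle length
itself) shift if the pre-pacing depth is changed.

## Biomarkers

* **APD90** per beat: time from the maximum upstroke (steepest sampled
  dV/dt after the stimulus) to the linearly interpolated downward
  crossing of V_rest + 0.1·(V_peak − V_rest), with V_rest the
  pre-stimulus potential and V_peak the beat maximum.  The analysis
  window of a beat is [stimulus, next stimulus).  Traces are sampled at
  0.1 ms; the interpolated crossing makes the sampling rate
  non-limiting (tested at 0.05 ms).
* **Capture**: a beat whose upstroke amplitude (V_peak − V_rest) is
  below 30 mV, or with no 90% crossing inside its window, is
  unmeasurable (an amplitude criterion, because genuine APs at short
  cycle lengths can peak below 0 mV while failed responses stay within
  ~25 mV of rest); a cycle length whose trailing window
  contains such beats is excluded from onset determination and flags the
  scenario (`incomplete_capture`) rather than contributing silent zeros.
* **AM**: mean of the 10 absolute successive APD90 differences over the
  last 11 beats of a cycle length. **meanAPD**: mean APD90 of the last
  10 beats. **ANM** = AM / meanAPD; alternans is declared when
  ANM > 0.05 (strict).
* **AOCL**: scanning the schedule from the longest cycle length, the
  first cycle length with ANM > 0.05; **AO meanAPD** is that cycle
  length's meanAPD.  Both are 0 when no cycle length qualifies.

The "amplitude" entering AM is the beat's APD90, not its voltage
amplitude: only that reading makes AM/meanAPD dimensionless and
consistent with the worked numbers (|66.3 − 48.8|/56.7 ≈ 0.309).

## Population sweep and aggregation

Scenarios are enumerated as a base-3 counter over the table-ordered
channels (index 0 = all at 50%, index 59,048 = all at 150%).  Runs are
independent and deterministic, so sweep results are identical for any
worker count and execution order, and a sweep resumes from its output
CSV by skipping completed scenario ids.  Early stopping after the first
alternans-positive cycle length is sound for AOCL / AO meanAPD sweeps
because both biomarkers depend only on cycle lengths down to the onset.

Aggregation reports the max/min AOCL strata (counts, AO meanAPD mean and
range), the non-alternans count, and the Pearson correlation between
AOCL and AO meanAPD.  The primary correlation is computed over
alternans-positive scenarios only — including the (0, 0) rows would let
zero-inflation dominate — with the all-rows variant reported alongside.
Quality-flagged rows are excluded from every statistic and their count
reported.  The full 59,049-scenario sweep is a cluster-scale computation
(days on one core); the package is exercised and tested on sub-factorials
and on the three worked scenarios, which run at desk scale.

## Dimensional stacking

A d-channel factorial is embedded in 2-D by assigning the
sensitivity-ranked channels alternately to the x and y axes (rank 1 =
outermost x, rank 2 = outermost y, …), nesting outermost (stride
3^(k−1)) to innermost (stride 1); level 0.5/1.0/1.5 → digit 0/1/2.  For
10 channels this gives the 243×243 map in which each scenario owns one
pixel; non-alternans scenarios keep their value 0 (gray in rendering)
and remain real pixels of the objective.

The axis-order objective is the per-cell sum of absolute differences to
the four lattice neighbors, out-of-grid terms omitted; each adjacent
pair is therefore counted twice, which rescales the objective without
moving its minimizers.  Exchanging the x- and y-groups transposes the
grid and preserves the objective, so only d!/2 orderings are distinct
for even d; the exhaustive optimizer deduplicates accordingly and breaks
ties toward the lexicographically smallest permutation.  Exhaustive
search is refused above 7 channels unless forced (10!/2 ≈ 1.8 M grid
evaluations); the default heuristic seeds from the per-axis
total-variation ranking plus random restarts, anneals over pairwise
swaps with a seeded generator, and finishes with greedy swap descent.

A structural note discovered while validating the optimizer on planted
separable fields (value = Σ_k w_k·f(level_k)): when every axis pair
satisfies w_outer > 2·w_inner (with equally spaced level effects) the
objective collapses to a constant multiple of Σ|w_k|, so many orderings
tie, and for odd channel counts the optimum generically places the
second-heaviest channel x-innermost rather than y-outermost.  Exact
ranking recovery therefore holds on even (square) designs with a unique
optimal pairing — the 10-channel study design is such a case — and the
test suite asserts exactly that, plus heaviest-outermost for odd
designs.

## Synthetic fixtures

* The AP-train generator is analytic, not ODE-derived: a sin² upstroke
  (maximum slope at its midpoint) followed by a logistic repolarization
  whose 90% crossing is placed in closed form at the planted APD90.
  This makes biomarker tests a genuine two-implementation check of the
  APD90/ANM extraction.  It emulates AP shape and beat timing only — no
  calcium transients, rate-dependent morphology or restitution memory —
  so passing fixture tests validates the measurement pipeline, not the
  electrophysiology.
* The planted scalar field is separable with distinct weight magnitudes;
  its degeneracies are discussed above.
* The summary-table generator plants a linear AOCL–AO meanAPD relation
  with a chosen non-alternans fraction, giving closed-form expectations
  for the aggregation statistics.

All generators are seed-deterministic and emit their ground truth.

## Reproduction fidelity and known limitations

With the reference conductance table, deep steady-state initialization
and the −52 pA/pF stimulus, the package reproduces the study's worked
scenarios' onset structure exactly: the two maximal-onset scenarios
first alternate at a 550 ms cycle length (with sub-threshold ANM at
600 ms), and the minimal-meanAPD scenario at 240 ms with a stable
250 ms (ANM ≈ 1e-4).  Continuous quantities track to a few percent:
meanAPD values run ~2–4% long and near-onset ANM somewhat low,
consistent with unstated solver and stimulus details of the original
implementation.  Two caveats:

* near the onset cycle length the alternans amplitude is still growing
  during the 74-beat train, so ANM at onset is sensitive to every
  upstream detail (pre-pacing depth, stimulus charge);
* in the second maximal-onset scenario our slightly longer action
  potentials leave the long-phase beats of the 550 ms alternans without
  a 90% crossing inside their beat windows (the crossing falls just
  beyond the next stimulus), so that cycle length is reported as
  incomplete capture rather than with an ANM value — the package
  surfaces this through its quality flag instead of inventing a number.

Tissue-level propagation, electrotonic coupling and transmural
heterogeneity are out of scope: all statements are single-cell.
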