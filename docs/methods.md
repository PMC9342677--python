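# Methods

## The problem

Cardiac ionic cell models are systems of nonlinear ODEs

    ds/dt = f(t, s),    s(0) = s0,

whose state vector s holds the transmembrane potential v, ionic
concentrations, and gating variables. Realistic simulations and parameter
sweeps need millions to billions of independent instances of such a system,
each advanced over 10^5–10^7 time steps, so the engineering questions —
which step operator, which memory layout, which loop nesting, whether to
tabulate expensive coefficient functions — dominate the cost. This package
implements those building blocks in numpy, with the correctness and
accuracy contracts testable at desk scale. It deliberately measures and
reports throughput without asserting hardware-specific numbers: wall-clock
performance of array code in Python says nothing about compiled SIMD
kernels, but the *mathematical equivalences* that justify those kernels
(layout invariance, loop-order invariance, padding transparency,
interpolation error bounds) are exactly reproducible here.

## Step operators

**Forward Euler (FE).** `s(t+dt) = s(t) + dt f(t, s(t))`. All derivative
components are evaluated at the pre-step state before any component is
written ("Jacobi-style"); no operator in this package has in-step
sequential dependence between state variables.

**Rush–Larsen (RL).** Gating variables obey the quasi-linear form
`dw/dt = (w∞(x) − w)/τ(x)` with x the gate's input (usually v). Freezing x
over one step makes this a linear scalar ODE with exact update

    w(t+dt) = a w(t) + b,   a = e^(−dt/τ(x)),   b = −w∞(x) (e^(−dt/τ(x)) − 1).

RL applies this to every declared gate and FE to everything else. Because
a ∈ (0, 1] and b = w∞(1 − a), the update is a convex combination of w and
w∞: gates stay in [0, 1] unconditionally, which is the scheme's practical
stability advantage for stiff gates.

**GRL1.** The first-order generalised Rush–Larsen scheme extends the
exponential update to every state via the diagonal linearisation
λ_j = ∂f_j/∂s_j:

    s_j(t+dt) = s_j + f_j dt φ(λ_j dt),   φ(x) = (e^x − 1)/x.

With λ_j = 0 the update is bit-for-bit FE (φ(0) := 1 exactly); on a scalar
linear ODE it is exact; on a declared gate with the analytic diagonal
λ = −1/τ it reduces to the RL update. Models may declare an analytic
diagonal (`CellModel.diag`); otherwise a central finite difference with
step `h = sqrt(eps_mach) · max(1, |s_j|)` is used. φ is evaluated as
`expm1(x)/x` with an exact-zero branch; `expm1` keeps the small-x path
accurate without a series expansion.

**Time accumulation.** Step times are formed as `t_ℓ = t0 + ℓ·dt` by
multiplication, never by running addition, so a 10^6-step run accumulates
no time drift.

**expm1 toggle.** Every `e^x − 1` in the package routes through one helper
with a flag selecting `expm1(x)` (default) or the literal `exp(x) − 1`.
The literal form mirrors environments where only a plain vectorised `exp`
exists; at dt = 1e-3 the two differ by under 1e-10 RRMS on gate
trajectories, which the suite checks as a sanity ceiling.

## Storage layouts and loop structures

`StateBlock` stores N state variables of C cells either cell-major ("array
of structs", AoS) or state-major ("struct of arrays", SoA). SoA pads each
per-state run to the next multiple of the lane width L (default 8, the
512-bit/64-bit case) so every run starts aligned; the padded lane count is
`(L − C mod L) mod L` — a cell count already on a lane boundary gets no
padding. Padded lanes are filled by **replicating the last live cell**
rather than zeros: they then stay finite under any model arithmetic
(no log(0), no division hazards) while contributing to no trace, metric or
output. The test suite fuzzes padded lanes with garbage and requires
bit-identical live-cell results.

Ensemble runs support three loop nestings — Cell–Time (cells outer),
Time–Cell (time outer, array-wide inner), and Cell–Time–Cell (batches of B
cells outer, default B = 32, last partial batch padded by row
replication). Since numpy applies the same elementwise operations in every
nesting, all three produce bit-identical trajectories here; the suite
asserts equivalence at 1e-13 RRMS and typically observes exactly 0. The
Cell–Time structure performs no hoisting of parameter-only subexpressions:
in this runtime there is no compiled-loop win, and keeping the arithmetic
literally identical across nestings makes the equivalence contract exact.

## Lookup tables

Expressions of one input variable are pre-evaluated at S equally spaced
nodes `x_i = v_min + i·v_step` and stored as an S×M row-major grid (one row
per node, all M expressions contiguous), so a query touches two adjacent
rows. Queries use shared-weight linear interpolation:

    i = floor((v − v_min)/v_step) clamped to [0, S−2],
    w_a = (x_{i+1} − v)/v_step,  w_b = 1 − w_a,
    f(v) ≈ w_a f(x_i) + w_b f(x_{i+1}).

One weight pair serves all M expressions of a table. Counting operations,
an interpolation is 3 FLOPs once the weights are shared, and the RL gate
recurrence `a·w + b` is 2 more: a LUT gate update costs 3 + 3 + 2 = 8
FLOPs (`gate_update_flops`).

Numerical choices:

* **Node snapping.** Floating-point index arithmetic cannot guarantee
  w_a = 1.0 exactly when v bit-equals a node, so the weight computation
  snaps to (1, 0)/(0, 1) on exact node hits. Sample-point queries therefore
  return stored rows bit-identically, which also makes a LUT-RL step at a
  node bit-equal to the exact RL step.
* **Out-of-range policy.** Default is clamp-to-boundary with a counter on
  the table (`out_of_range_count`); `policy="strict"` raises instead, for
  accuracy studies where silent clamping would bias results.
* **dt stamping.** RL coefficient tables depend on dt; each table carries a
  dt stamp and any step with a different dt is rejected before mutation.
* **Default v range** is [−100, 50] (units of the model's v — mV for
  physiological models), the conventional healthy-heart envelope; the
  default v_step = 0.05 is a repository choice, configurable everywhere.
  Non-voltage inputs (e.g. a calcium concentration) need explicit ranges.

The interpolation error is second order: for smooth f the worst-case error
falls by ≈4× per halving of v_step, which the suite asserts (ratio within
[3.5, 4.5] for f = exp on [−5, 5]) together with end-to-end monotone decay
of LUT-vs-exact trajectory RRMS through v_step ∈ {0.5, 0.25, 0.125}. Ulp
bounds in the tests are measured at the operand scale (e.g. ulps of w∞ for
the b = w∞(1−a) identity), since results much smaller than their operands
cannot be finer than the operands' rounding.

**Partitioned solver.** `partitioned_step` performs the same update as the
single-pass LUT-RL step organised as two passes: an array-wide pass for all
non-gate states, then a batched pass over cells doing the table lookups for
the gates — the structure that lets compiled implementations vectorise the
first pass while the second tolerates scattered loads. Both passes read
only captured pre-step values, so the result is bit-identical to the
single-pass operator (the contract is ≤ 1e-14 RRMS; observed 0).

## Built-in models

**FitzHugh–Nagumo.** dv/dt = v(v−α)(1−v) − w + I_stim, dw/dt = ε(v−γw),
with a single I_stim = −8 pulse on t ∈ [0, 0.5] (model time is
dimensionless). α = 0.13, ε = 0.01, γ = 1.0 are repository defaults — the
equation is conventionally written with symbolic parameters and different
sources pick different values — and all are overridable, as are the
stimulus settings. Under these defaults the −8 pulse drives v to about
−1.66 and the state then relaxes back toward rest over ~10 time units
without a regenerative upstroke; the trajectory tests assert exactly this
oracle-verified behaviour. The model declares no gates and exercises the
FE/GRL1 paths; its analytic diagonal is declared for GRL1.

**Synthetic gate model.** `synthetic_gate_model(n_gates, seed)` emulates
the *structure* of biophysical membrane models without transcribing any
particular one: a voltage-like driver with leak (τ_v = 20 ms toward
−85 mV), n_gates gated conductances with reversal potentials and
conductance parameters g_k, pacing at 1 Hz (2 ms, +8 mV/ms pulses), and
gates with logistic w∞ (range [0, 1]) and Gaussian-bump-plus-offset τ
(strictly positive, 1–60 ms) — the shapes real activation/inactivation
curves take. All shape constants derive from `default_rng(seed)`, so a
(n_gates, seed) pair is a reproducible fixture. What it does **not**
emulate: real channel kinetics, calcium handling, concentration dynamics,
or the stiffness contrast of production models — so passing tests establish
the solver contracts (exactness, equivalence, convergence), not
physiological fidelity of any particular model.

**TP06.** The ten Tusscher–Panfilov (2006) ventricular model (19 states, of
which 12 gates: 11 driven by v, 1 by the subspace calcium concentration) is
the natural production target for the partitioned solver, with a v table
(plus 6 auxiliary non-gate expressions) and a separate Ca_ss table. Its
equation set must be transcribed from the source publication or the CellML
repository; no transcription ships with this package, and `load_tp06()`
raises `UnsupportedModelError`. The `lut_inputs` / `auxiliary_lut_expressions`
plumbing is in place and exercised by the synthetic model.

## Drivers and metrics

The simulation driver records declared variables every `record_stride`
steps (live cells only). The ensemble driver takes a per-cell parameter
table (one row per cell; `parameter_grid` builds cartesian products with
the last parameter varying fastest) and any loop structure. Stimulus
protocols map onto the standard `stim_*` model parameters, so per-cell
ensembles can sweep stimulus settings like any other parameter.

Steady state under pacing is declared by comparing the last two pacing
periods of the recorded v in the RRMS sense
(`sqrt(Σ(v−v_ref)²)/sqrt(Σv_ref²)`); the deviation reported for multi-cell
traces is the worst cell, and the pacing period must be an integer multiple
of the recording interval (no resampling, so no interpolation error enters
an accuracy measurement).

Throughput is `cells × steps / wall seconds` ("cell steps per second"),
measured by `bench` as best-of-repeats after one warm-up, with the repeated
runs required to be bit-identical. Throughput is reported, never asserted
against published figures. Accuracy experiments run two solver
configurations from one initial state and report RRMS and max |Δv| of the
transmembrane potential (per-variable RRMS as labelled extras); the two
arms must share dt, step count and recording stride.

## Problem sizes used in the shipped checks

The acceptance checks run at desk scale: equivalence suites use C = 100
cells × 10^3 steps per scheme, LUT accuracy runs 10^4 steps × 8 cells,
RL exactness draws 10^4 random gates, and pacing checks cover two 1 Hz
beats at dt = 0.5 ms. These sizes were chosen so the full suite completes
in about a minute while every contract is exercised at its stated
tolerance; all are plain parameters and scale up freely.

## Known limitations

* No PDE/tissue coupling; single-cell ODE systems only.
* Python/numpy arithmetic: the package demonstrates the mathematical
  contracts of vectorisation-friendly structures, not their speed.
* One-dimensional tables only (multi-input tabulation grows exponentially
  in memory and is deliberately excluded).
* `a = e^(−dt/τ)` underflows to 0 for dt/τ ≳ 745; the positivity invariant
  0 < a holds for any practically resolved gate (dt ≪ 700 τ).
* The GRL1 finite-difference diagonal costs 2N rhs evaluations per step;
  declare analytic diagonals for production use.
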