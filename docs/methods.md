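# Methods

## Model

The plant is the autonomous continuous-time GRU flow

    ḣ = (1 − s) ⊙ (T − h),   s = U_s h + b_s (linear update gate),
    T = tanh(U_h (r ⊙ h)),    r = σ(U_r h + b_r),

specialized to d = 3 with U_r = b_r = b_h = 0.  With zero reset-gate
parameters the reset gate is the constant σ(0) = 1/2, so the effective
inner gain is half of U_h; the GRU rendering in
`BirhythmicConfig.to_gru_parameters` therefore carries a compensating
factor 2 so that `gru_rhs` and the explicit `birhythmic_rhs` agree to
machine precision (the extra z time constant γ lives outside the GRU
form; the identity is exact at γ = 1 and dz/dt scales by 1/γ otherwise).

Explicitly, with α the rotation angle, g_xy the planar gain, g_z the z
gain and κ the stimulation coupling:

    ẋ = (3/2 − z) [tanh(g_xy (x cos α − y sin α)) − x]
    ẏ = (3/2 − z) [tanh(g_xy (x sin α + y cos α)) − y]
    ż = (1/γ) { ½ [tanh(g_z z) − z] + κ S_out }

Structure that everything else builds on:

- **Decoupling.** ż depends only on z (and the stimulus).  The z axis and
  the plane z = 0 are invariant; without stimulation z never changes sign.
- **Bistable z subsystem.** For g_z > 1 the scalar equation has sinks at
  ±z\*, the nonzero roots of z = tanh(g_z z) (z\* = 0.858560 at
  g_z = 3/2), and an unstable root at 0.
- **Speed rescaling.** (3/2 − z) multiplies the planar flow, so both
  attractors share one planar orbit traversed at speeds (3/2 ∓ z\*):
  period ratio (3/2 + z\*)/(3/2 − z\*) ≈ 3.677 at the default gains.
- **Equilibria.** (0,0,0) plus (0,0,±z\*).  The origin is fully unstable
  (planar growth rate (3/2)(g_xy cos α − 1), z rate (g_z − 1)/(2γ)); the
  sinks of the z subsystem are saddle-foci (stable in z, unstable planar
  focus), which is why trajectories are funneled onto the cycles.

## Parameters

| name | default | units | meaning / why |
| --- | --- | --- | --- |
| α | π/5 | rad | rotation angle; a planar cycle requires α in (π/21, π/3.8) |
| g_xy | 3 | – | planar tanh gain; cycle exists iff g_xy·cos α > 1 |
| g_z | 3/2 | – | z-subsystem gain; sets z\* = 0.8586 (g_z = 3 gives 0.9949 and is kept as an option) |
| γ | 50 | – | z time constant; z is ~50× slower than the planar flow, which is what makes transitions hard.  Scales linearly: transition times and recording horizons are ∝ γ |
| κ | 1 | – | coupling of S_out into ż.  The qualitative outcome matrix is insensitive to κ over at least [0.2, 5] |
| amplitude | 4 | V | on-level of all stimulus protocols (voltages are treated as dimensionless simulation units) |

Construction validates the cycle conditions and rejects violations;
`BirhythmicConfig.unvalidated` bypasses validation for deliberate
exploration of degenerate regimes (e.g. a stable origin focus, which has
no periodic attractor at all).

## Stimulation

The raw stimulus S_in(t) is piecewise-constant between protocol switch
times (exactly true for the built-in constant, telegraph, square-wave and
gated protocols); the interface S_out = S_in·x·y is evaluated
continuously inside the right-hand side, as the analog multiplier does.
"Manually random" switching is formalized as a symmetric exponential
telegraph process (default rate 1 per time unit, the order of the
oscillation timescale; seed-reproducible).  The gated protocol models a
rectifying diode ahead of the stimulation node: an ideal half-wave
rectifier by default, with an optional constant forward drop (0.6 V
approximates a small-signal silicon diode) that attenuates passed
half-waves and blocks anything below the drop.

Why the outcome matrix looks the way it does: over whole orbits the mean
of x·y is ~10⁻⁸, so constant stimulation only adds a small zero-mean
ripple to ż (max |z − z\*| excursions ~0.03–0.14 depending on phase);
telegraph stimulation adds a zero-mean diffusion whose stationary spread
(~0.05) is an order of magnitude short of the 0.86 needed to reach the
separatrix.  The gated protocol produces a sustained drift of order
κ·amplitude·⟨|x·y|⟩/γ and crosses z = 0 after ≈1.1 γ time units.

## Closed-loop environment

`StimulationEnv` is a gym-style reset/step wrapper: reset draws an initial
state uniformly from the basin's initialization box
((−1.5,1.5)² × (0,1.5) slow, (−1.5,1.5)² × (−1.5,0) fast), relaxes it onto
the attractor and returns an observation; step holds the submitted
stimulus for dt (zero-order hold), passes it through the interface, and
reports done once z has held the opposite sign for ≥ 1 time unit.  The
observation model (channel subset + Gaussian noise, default noiseless full
state) generalizes the constraint that a stimulator lacks direct access to
the latent state; the vector field and parameters are never exposed.  A
stdin/stdout line protocol (`birhythm env-serve`) serves controllers
written in any language.

## Trial protocol and horizons

Attractor preparation exploits the exact decoupling: the scalar z
subsystem is settled to |ż| < 10⁻⁸ (bracketed in time, never more than
400 γ), then the full system runs for 80 rescaled planar time units
(80/(3/2 − z\*) ≈ 125 slow-side) so the planar coordinates land on the
cycle.  Fixed wall-clock-style horizons cannot do this job across γ: the
z relaxation time constant is ≈3.3 γ, so any fixed short relax window
would leave z unconverged and the cycle statistics biased.

Unstimulated cycle statistics record 100 time units (≈6 slow periods) per
trial; the period is the mean spacing of upward crossings of the Poincaré
section {y = 0, x > 0} with its standard error.  Stimulation trials
record up to 4 γ time units (default 200), enough for gated transitions
(≈1.1 γ) plus settling on the far attractor, and a trial stops early once
its outcome is decided: a sustained transition followed by
1.2 γ further units.  A transition is a z sign flip held continuously for
≥ 1 time unit, which ignores grazes of the separatrix; the transition
time is the interpolated z = 0 crossing that opens the sustained run.

Driving z beyond 3/2 (possible under prolonged gated stimulation *toward*
the slow basin after the transition has already happened) makes the
update gate negative, reverses the planar flow, and blows the ideal model
up in finite time — the physical circuit would rail instead.  Trials
whose transition is already decided truncate at the last valid sample in
that regime; undecided integration failures propagate as errors.

## Numerics

- Adaptive RK45 (`scipy.integrate.solve_ivp`), rtol = tol, atol = 10⁻³·tol;
  tol defaults to 10⁻⁸ for trajectories and 10⁻⁷ inside trial batteries.
  Integration is segmented at protocol switch times, so the solver never
  steps across a stimulus discontinuity; segment stimulus values are
  evaluated at segment midpoints (immune to floating-point jitter at the
  edges), and switch edges are generated from integer indices, never by
  accumulating remainders.
- An independent fixed-step forward-Euler oracle (`integrate_euler_oracle`)
  cross-checks the adaptive solver in the tests (agreement < 10⁻³ over one
  time unit at dt = 10⁻⁵, with the expected first-order convergence).
- z\* is found by Brent root bracketing on (0, 1 + 1/g_z] to |f| < 10⁻¹²;
  Jacobians use central differences with step 10⁻⁶.
- Plane crossings use linear interpolation with a half-open convention: a
  sample exactly on the level counts with the direction of the following
  step.
- Attractor counting clusters relaxed trajectories by the sign of mean z
  (|mean z| < 0.05 counts as "on the separatrix plane") and period
  agreement within 5%; starts whose planar amplitude falls below 10⁻³ are
  fixed-point convergents and not periodic attractors.
- Seeds: every battery spawns per-cell and per-trial children from the
  master seed via `numpy.random.SeedSequence`, so tables are reproducible
  bit-for-bit and independent of cell ordering changes within a run.

## What the emulation does and does not capture

`hardware.py` models the analog tanh stage V₀ = −tanh(k·V_in) with
k = R2/(2·R·V_T) (k = 1 at R2 = 520 Ω, R = 10 kΩ, V_T = 26 mV) and a
conventional 1.5 V op-amp headroom clip, and emulates build-to-build
component tolerance as independent lognormal jitter (relative spread =
tolerance) on g_xy, g_z, the speed offset and κ.  This reproduces the
qualitative signatures of a physical build — a slow-cycle level spread
around the ideal root with the two-attractor structure intact at ≤5%
tolerance — but it is a parameter-level emulation: it does not model the
fitted error curve of a particular tanh stage, multiplier nonideality,
supply-rail saturation of the state variables, temperature drift of V_T,
or recording quantization.  Consequently, absolute deviation statistics
under stimulation depend on the unspecified physical stimulation gain and
are reported but not treated as reference values; the reproducible content
is the outcome matrix and the attractor geometry.

## Problem sizes used by the test suite

Cycle statistics: 2–3 trials × 100 (slow) / 20–30 (fast) time units.
Attractor counting: 10–20 random starts.  Outcome matrix: 10 trials per
cell at γ = 50 with up-to-200-unit recordings.  Structural properties:
1000 random starts integrated as one batched 3000-dimensional system for
50 units.  These sizes give measurement noise far below every asserted
tolerance (periods stable to <0.1%, cycle levels to <10⁻⁶).
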