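# birhythm

A simulator and closed-loop testbed for **birhythmic** brain-like dynamics:
a three-dimensional continuous-time gated recurrent unit (ct-GRU) whose
flow carries two coexisting stable limit cycles of different periods, plus
a state-dependent nonlinear stimulation interface that makes transitions
between the two cycles deliberately hard to induce.

## Who this is for

Developers of closed-loop neurostimulation algorithms need a plant that is
(i) multistable, (ii) resistant to naive open-loop stimulation, and
(iii) fully observable and reproducible in software.  Under the hypothesis
that some neurological conditions correspond to being stuck in a
pathological attractor, a candidate "intelligent" stimulator should prove
it can drive the state across a basin boundary before being tried on
anything real.  This package provides that plant, the baseline strategies
it must beat, and the analysis tooling to score it.

## The model

The hidden state is h = (x, y, z).  With rotation angle α = π/5, planar
gain g = 3, z gain 3/2 and time constant γ:

    dx/dt = (3/2 − z) [tanh(g (x cos α − y sin α)) − x]
    dy/dt = (3/2 − z) [tanh(g (x sin α + y cos α)) − y]
    dz/dt = (1/γ) { ½ [tanh(3z/2) − z] + κ S_out }

This is the ct-GRU flow ḣ = (1 − s) ⊙ (T − h) with a linear update gate
s = U_s h + b_s: the factor (3/2 − z) is the gate's speed modulation, so
the two attractors are the *same* planar orbit traversed at different
speeds.  The z subsystem is decoupled and bistable: its sinks sit at
±z\*, where z\* ≈ 0.8586 solves z = tanh(3z/2).  The plane z = 0 is an
invariant separatrix, and the period ratio of the slow (z > 0) and fast
(z < 0) cycles is (3/2 + z\*)/(3/2 − z\*) ≈ 3.68.

All stimulation enters through the stimulator interface

    S_out(t) = S_in(t) · x(t) · y(t),

summed into dz/dt.  Since x·y averages to zero over an orbit, constant,
random, or periodic S_in produces no sustained drift in z — open-loop
strategies fail.  Passing only one sign of S_out (a rectifying diode ahead
of the stimulation node) breaks the cancellation and transitions reliably;
that gated strategy is the existence proof a learning controller must
rediscover from observations.

## Worked example

`python examples/01_two_limit_cycles.py` prints:

```
z* = positive root of z = tanh(1.5 z) = 0.8586

Equilibria (all on the z axis):
  z = +0.0000  unstable     unstable directions: 3
  z = +0.8586  saddle-focus unstable directions: 2
  z = -0.8586  saddle-focus unstable directions: 2

slow cycle: mean z = +0.8586, period = 16.625 time units (6 returns)

fast cycle: mean z = -0.8586, period = 4.521 time units (7 returns)

predicted period ratio (3/2 + z*)/(3/2 - z*) = 3.677
```

The measured cycle levels equal ±z\*, and the measured period ratio
16.625 / 4.521 = 3.677 matches the speed-factor prediction.  A bench
realization of the same dynamics measured the slow-cycle level at
0.858 V — the root of z = tanh(3z/2) to within its measurement spread.

`python examples/02_stimulation_strategies.py` runs the trial battery
(3 trials per cell shown; the full battery uses 10):

```
        protocol basin  n_trials  n_transitions  mean_max_z_deviation
     constant 4V  slow         3              0                 0.138
     constant 4V  fast         3              0                 0.035
       random 4V  slow         3              0                 0.288
       random 4V  fast         3              0                 0.114
gated slow->fast  slow         3              3                 2.080
gated fast->slow  fast         3              3                 2.060
```

Open-loop cells never cross z = 0; the gated cells always do, with
transition times near 1.1 γ.  `examples/03_closed_loop_control.py` shows
the same gating rule implemented by a controller through the reset/step
environment, and `examples/04_hardware_imperfections.py` exercises the
analog tanh-unit model and component-tolerance jitter.

## Command line

```
birhythm simulate     --config cfg.json --basin slow --out traj.csv
birhythm experiment   --config cfg.json --out results/run1
birhythm fixed-points --config cfg.json
birhythm env-serve    --config cfg.json --basin slow --dt 0.5
```

`env-serve` speaks a one-line-JSON-observation / one-line-stimulus
protocol on stdin/stdout so controllers in any language can drive the
plant.  All commands are deterministic given `--seed`.

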