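"""Closed-loop control through the reset/step environment.

A controller interacts with the plant only through observations — it never
sees the vector field.  Here a scripted controller implements the gating
rule in software: stimulate (4 V) whenever the observed x and y have
opposite signs, which makes S_out = S_in * x * y negative and pushes z
down toward the fast basin.
"""

from birhythm import BirhythmicConfig, ObservationModel, StimulationEnv

cfg = BirhythmicConfig()
env = StimulationEnv(cfg, observation=ObservationModel(channels="full"))

obs = env.reset(basin="slow", seed=3)
print(f"start on slow cycle: x={obs.values[0]:+.3f} "
      f"y={obs.values[1]:+.3f} z={obs.values[2]:+.3f}")

done = False
steps = 0
while not done and steps < 2000:
    x, y = obs.values[0], obs.values[1]
    s_in = 4.0 if x * y < 0 else 0.0
    obs, done = env.step(s_in, dt=0.25)
    steps += 1

print(f"transitioned: {done} after {steps} steps "
      f"(t = {obs.time:.1f} time units), final z = {obs.values[2]:+.3f}")
print("The episode ends once z has held the opposite sign for >= 1 time")
print("unit; an intelligent stimulator must discover this gating rule from")
print("observations alone (try ObservationModel(channels='z', noise_std=...)).")
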