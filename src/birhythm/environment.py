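"""Closed-loop plant environment for external stimulation controllers.

A controller interacts with the birhythmic plant through a gym-style
reset/step interface.  By design the controller never sees the vector
field or its parameters — only observations of (a configurable subset of)
the state, optionally corrupted by additive Gaussian noise, mirroring the
situation of a neurostimulator that must discover the latent dynamics from
measurements alone.

Every stimulus value sent through :meth:`StimulationEnv.step` is held
constant for the step duration (zero-order hold) and passes through the
nonlinear stimulator interface ``S_out = S_in * x * y`` before being summed
into dz/dt.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass

import numpy as np

from .analysis import BASIN_BOXES, _uniform_in_box, prepare_on_attractor
from .dynamics import BirhythmicConfig
from .simulate import final_state
from .stimulation import StimulationProtocol

__all__ = ["ObservationModel", "EnvObservation", "StimulationEnv", "serve_stdio"]

_CHANNEL_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class ObservationModel:
    """What the controller is allowed to see.

    ``channels`` is ``"full"``, a single channel name, or a sequence of
    channel names; ``noise_std`` adds i.i.d. Gaussian noise per channel.
    """

    channels: object = "full"
    noise_std: float = 0.0

    def indices(self) -> list[int]:
        if self.channels == "full":
            return [0, 1, 2]
        if isinstance(self.channels, str):
            return [_CHANNEL_INDEX[self.channels]]
        return [_CHANNEL_INDEX[c] for c in self.channels]


@dataclass(frozen=True)
class EnvObservation:
    """Observed channel values at a given plant time."""

    values: np.ndarray
    channels: tuple
    time: float


class StimulationEnv:
    """Reset/step environment around the birhythmic plant.

    Parameters
    ----------
    config
        Plant parameters (hidden from the controller).
    observation
        Observation model; defaults to noiseless full state.
    sustain
        How long z must continuously hold the opposite sign before the
        episode is flagged done (guards against separatrix grazes).
    """

    def __init__(self, config: BirhythmicConfig,
                 observation: ObservationModel = ObservationModel(),
                 sustain: float = 1.0, tol: float = 1e-8):
        self.config = config
        self.observation = observation
        self.sustain = sustain
        self.tol = tol
        self._state = None
        self._t = None
        self._rng = None
        self._init_sign = None
        self._flip_since = None

    def reset(self, basin: str = "slow", seed: int = 0) -> EnvObservation:
        """Draw a random start in the basin box and relax onto the attractor."""
        if basin not in BASIN_BOXES:
            raise ValueError(f"basin must be 'slow' or 'fast', got {basin!r}")
        self._rng = np.random.default_rng(seed)
        x0 = _uniform_in_box(self._rng, BASIN_BOXES[basin])
        self._state = prepare_on_attractor(self.config, x0)
        self._t = 0.0
        self._init_sign = 1 if basin == "slow" else -1
        self._flip_since = None
        return self._observe()

    def step(self, s_in: float, dt: float):
        """Advance the plant ``dt`` time units under a held stimulus.

        Returns ``(observation, done)``; ``done`` becomes true once z has
        held the sign opposite to the initial attractor for at least
        ``sustain`` time units.
        """
        if self._state is None:
            raise RuntimeError("step() called before reset()")
        if dt <= 0:
            raise ValueError(f"dt must be positive, got {dt}")
        protocol = _SignedConstant(float(s_in))
        self._state = final_state(self.config, self._state, protocol,
                                  (self._t, self._t + dt), tol=self.tol)
        self._t += dt
        z = self._state[2]
        if z * self._init_sign < 0:
            if self._flip_since is None:
                self._flip_since = self._t
        else:
            self._flip_since = None
        done = (self._flip_since is not None
                and self._t - self._flip_since >= self.sustain)
        return self._observe(), done

    def _observe(self) -> EnvObservation:
        idx = self.observation.indices()
        vals = self._state[idx].astype(float).copy()
        if self.observation.noise_std > 0:
            vals = vals + self._rng.normal(0.0, self.observation.noise_std,
                                           size=len(vals))
        names = tuple("xyz"[i] for i in idx)
        return EnvObservation(values=vals, channels=names, time=self._t)


class _SignedConstant(StimulationProtocol):
    """Constant stimulus held over one environment step (sign allowed)."""

    kind = "held"

    def __init__(self, value: float):
        self._value = value

    def s_in(self, t: float) -> float:
        return self._value


def serve_stdio(env: StimulationEnv, basin: str, seed: int, dt: float,
                max_steps: int = 100000,
                infile=None, outfile=None) -> bool:
    """Line-protocol server for language-agnostic controllers.

    Writes one JSON observation per line to ``outfile`` and reads one
    stimulus value (a bare number) per line from ``infile``; terminates
    when the episode is done, on end-of-input, or after ``max_steps``.
    Returns whether a transition was achieved.
    """
    infile = infile if infile is not None else sys.stdin
    outfile = outfile if outfile is not None else sys.stdout
    obs = env.reset(basin=basin, seed=seed)
    done = False
    for _ in range(max_steps):
        print(json.dumps({
            "t": obs.time,
            "channels": list(obs.channels),
            "values": [float(v) for v in obs.values],
            "done": done,
        }), file=outfile, flush=True)
        if done:
            return True
        line = infile.readline()
        if not line:
            return done
        s_in = float(line.strip())
        obs, done = env.step(s_in, dt)
    print(json.dumps({
        "t": obs.time,
        "channels": list(obs.channels),
        "values": [float(v) for v in obs.values],
        "done": done,
    }), file=outfile, flush=True)
    return done
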