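"""Stimulation interface and baseline stimulation strategies.

All external stimulation enters the plant through a state-dependent
nonlinear interface: the stimulator circuit multiplies the raw stimulus by
the instantaneous planar state,

    S_out(t) = S_in(t) * x(t) * y(t),

and S_out is summed into dz/dt.  Because x*y averages to zero over an
unperturbed orbit, open-loop strategies (constant, random, periodic
stimulus trains) cannot produce the sustained z drift needed to cross the
separatrix at z = 0.  The gated (rectified-diode) strategy demonstrates
that transitions are nevertheless achievable: a diode ahead of the
stim_out node passes only the half-waves of S_out whose sign pushes z
toward the target basin.

Protocols are piecewise-constant in the raw stimulus S_in.  Each protocol
exposes ``s_in(t)``, the switch times ``breakpoints(t0, t1)``, and the
interface map ``s_out(s_in, x, y)`` (the plain product for all protocols;
rectified for the gated one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "stimulator_output",
    "StimulationProtocol",
    "NoStimulation",
    "ConstantProtocol",
    "RandomTelegraphProtocol",
    "PeriodicProtocol",
    "GatedProtocol",
    "constant_protocol",
    "random_protocol",
    "periodic_protocol",
    "gated_protocol",
    "make_protocol",
]


def stimulator_output(s_in: float, state) -> float:
    """Stimulator-circuit output ``S_in * x * y`` at the given state."""
    if not (math.isfinite(s_in) and math.isfinite(state[0]) and math.isfinite(state[1])):
        raise ValueError("non-finite stimulator input")
    return float(s_in) * float(state[0]) * float(state[1])


class StimulationProtocol:
    """Base class: zero stimulus, plain multiplicative interface."""

    kind = "none"

    def s_in(self, t: float) -> float:
        return 0.0

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        """Switch times of the piecewise-constant raw stimulus in (t0, t1)."""
        return np.empty(0)

    def s_out(self, s_in: float, x: float, y: float) -> float:
        return s_in * x * y

    def spec(self) -> dict:
        """JSON-serializable description of this protocol."""
        return {"kind": self.kind}

    def __repr__(self):
        items = ", ".join(f"{k}={v!r}" for k, v in self.spec().items() if k != "kind")
        return f"{type(self).__name__}({items})"


class NoStimulation(StimulationProtocol):
    kind = "none"


@dataclass(repr=False)
class ConstantProtocol(StimulationProtocol):
    """Constant raw stimulus of the given amplitude (default 4 V)."""

    amplitude: float = 4.0
    kind = "constant"

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def s_in(self, t: float) -> float:
        return self.amplitude

    def spec(self) -> dict:
        return {"kind": self.kind, "amplitude": self.amplitude}


@dataclass(repr=False)
class RandomTelegraphProtocol(StimulationProtocol):
    """On/off telegraph stimulus with exponential holding times.

    Formalizes "manually random" on/off switching as a symmetric telegraph
    process: holding times in each of the on (amplitude) and off (0) states
    are exponential with rate ``switch_rate`` per time unit, the initial
    state is on or off with probability 1/2, and the whole train is a
    deterministic function of ``seed``.
    """

    amplitude: float = 4.0
    switch_rate: float = 1.0
    seed: int = 0
    kind = "random"

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.switch_rate <= 0:
            raise ValueError("switch_rate must be positive")
        rng = np.random.default_rng(self.seed)
        self._start_on = bool(rng.random() < 0.5)
        self._rng = rng
        self._switches = [0.0]  # switch times measured from t = 0

    def _extend(self, t: float) -> None:
        while self._switches[-1] <= t:
            self._switches.append(
                self._switches[-1] + self._rng.exponential(1.0 / self.switch_rate)
            )

    def _on_at_index(self, idx: int) -> bool:
        return self._start_on if idx % 2 == 0 else not self._start_on

    def s_in(self, t: float) -> float:
        if t < 0:
            return 0.0
        self._extend(t)
        idx = int(np.searchsorted(self._switches, t, side="right")) - 1
        return self.amplitude if self._on_at_index(idx) else 0.0

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        self._extend(t1)
        sw = np.asarray(self._switches)
        return sw[(sw > t0) & (sw < t1)]

    def spec(self) -> dict:
        return {"kind": self.kind, "amplitude": self.amplitude,
                "switch_rate": self.switch_rate, "seed": self.seed}


@dataclass(repr=False)
class PeriodicProtocol(StimulationProtocol):
    """Square-wave stimulus: on for ``duty * period``, off for the rest."""

    amplitude: float = 4.0
    period: float = 1.0
    duty: float = 0.5
    phase: float = 0.0
    kind = "periodic"

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not (0.0 < self.duty <= 1.0):
            raise ValueError("duty must be in (0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def s_in(self, t: float) -> float:
        pos = math.fmod(t + self.phase, self.period)
        if pos < 0:
            pos += self.period
        return self.amplitude if pos < self.duty * self.period else 0.0

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        if self.duty == 1.0:
            return np.empty(0)
        # edge times k*P - phase and (k + duty)*P - phase, by integer index
        k0 = math.floor((t0 + self.phase) / self.period) - 1
        k1 = math.ceil((t1 + self.phase) / self.period) + 1
        ks = np.arange(k0, k1 + 1)
        edges = np.concatenate([
            ks * self.period - self.phase,
            (ks + self.duty) * self.period - self.phase,
        ])
        edges.sort()
        return edges[(edges > t0) & (edges < t1)]

    def spec(self) -> dict:
        return {"kind": self.kind, "amplitude": self.amplitude,
                "period": self.period, "duty": self.duty, "phase": self.phase}


@dataclass(repr=False)
class GatedProtocol(StimulationProtocol):
    """Constant stimulus with a rectifying diode ahead of the stim_out node.

    The raw stimulus is always on, but the interface passes only the
    half-waves of ``S_out = S_in * x * y`` whose sign drives z toward the
    target basin: negative S_out for slow->fast, positive for fast->slow.
    ``diode_drop`` models the diode forward voltage (0 = ideal rectifier;
    0.6 approximates a small-signal silicon diode); passed half-waves are
    attenuated by the drop, and anything below it is blocked.
    """

    amplitude: float = 4.0
    target: str = "slow_to_fast"
    diode_drop: float = 0.0
    kind = "gated"

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.target not in ("slow_to_fast", "fast_to_slow"):
            raise ValueError(
                f"target must be 'slow_to_fast' or 'fast_to_slow', got {self.target!r}"
            )
        if self.diode_drop < 0:
            raise ValueError("diode_drop must be >= 0")

    def s_in(self, t: float) -> float:
        return self.amplitude

    def s_out(self, s_in: float, x: float, y: float) -> float:
        raw = s_in * x * y
        if self.target == "slow_to_fast":
            return raw + self.diode_drop if raw < -self.diode_drop else 0.0
        return raw - self.diode_drop if raw > self.diode_drop else 0.0

    def spec(self) -> dict:
        return {"kind": self.kind, "amplitude": self.amplitude,
                "target": self.target, "diode_drop": self.diode_drop}


def constant_protocol(amplitude: float = 4.0) -> StimulationProtocol:
    """Constant stimulation; amplitude 0 is identical to no stimulation."""
    return ConstantProtocol(amplitude=amplitude)


def random_protocol(amplitude: float = 4.0, switch_rate: float = 1.0,
                    seed: int = 0) -> RandomTelegraphProtocol:
    """Seed-reproducible on/off telegraph stimulation."""
    return RandomTelegraphProtocol(amplitude=amplitude, switch_rate=switch_rate,
                                   seed=seed)


def periodic_protocol(amplitude: float = 4.0, period: float = 1.0,
                      duty: float = 0.5, phase: float = 0.0) -> StimulationProtocol:
    """Square-wave stimulation; duty 1.0 degenerates to the constant protocol."""
    if duty == 1.0:
        return ConstantProtocol(amplitude=amplitude)
    return PeriodicProtocol(amplitude=amplitude, period=period, duty=duty,
                            phase=phase)


def gated_protocol(amplitude: float = 4.0, target: str = "slow_to_fast",
                   diode_drop: float = 0.0) -> GatedProtocol:
    """Rectified (diode-gated) constant stimulation toward the target basin."""
    return GatedProtocol(amplitude=amplitude, target=target,
                         diode_drop=diode_drop)


_PROTOCOL_KINDS = {
    "none": lambda seed, **kw: NoStimulation(),
    "constant": lambda seed, **kw: ConstantProtocol(**kw),
    "random": lambda seed, **kw: RandomTelegraphProtocol(seed=seed, **kw),
    "periodic": lambda seed, **kw: PeriodicProtocol(**kw),
    "gated": lambda seed, **kw: GatedProtocol(**kw),
}


def make_protocol(spec: dict, seed: int = 0) -> StimulationProtocol:
    """Instantiate a protocol from its serialized spec.

    ``spec`` is ``{"kind": ..., **params}``; ``seed`` overrides the spec's
    seed for seeded kinds so trial runners can split a master seed.
    """
    spec = dict(spec)
    kind = spec.pop("kind")
    if kind not in _PROTOCOL_KINDS:
        raise ValueError(f"unknown protocol kind {kind!r}; "
                         f"expected one of {sorted(_PROTOCOL_KINDS)}")
    spec.pop("seed", None)
    return _PROTOCOL_KINDS[kind](seed, **spec)
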