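"""Analog tanh-unit model and component-tolerance imperfections.

The nonlinearity of the circuit is realized by an op-amp/transistor tanh
unit whose input-output relation is ``V0 = -tanh(k * Vin)`` with
``k = R2 / (2 R VT)``, VT the transistor thermal voltage.  The reference
component choice (R2 = 520 ohm, R = 10 kohm, VT = 26 mV) makes k = 1.

Real resistors carry a manufacturing tolerance, so a breadboard build of
the system realizes slightly perturbed gains.  ``perturb_components``
emulates this by jittering each effective gain of the ideal model with an
independent lognormal factor of the given relative spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .dynamics import BirhythmicConfig

__all__ = [
    "TanhUnitComponents",
    "tanh_unit_gain",
    "tanh_unit_response",
    "perturb_components",
]


@dataclass(frozen=True)
class TanhUnitComponents:
    """Component values of one analog tanh unit.

    Resistances in ohms, voltages in volts.  ``VT`` is the transistor
    thermal voltage at room temperature (~26 mV); ``VCC``/``VEE`` are the
    op-amp supply rails.
    """

    R2: float = 520.0
    R: float = 10e3
    R3: float = 1e3
    R4: float = 1e3
    R11: float = 11e3
    VT: float = 0.026
    VCC: float = 15.0
    VEE: float = -15.0

    def __post_init__(self):
        for name in ("R2", "R", "R3", "R4", "R11"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.VT <= 0:
            raise ValueError("VT must be positive")
        if not (self.VEE < 0 < self.VCC):
            raise ValueError("supplies must satisfy VEE < 0 < VCC")


def tanh_unit_gain(components: TanhUnitComponents = TanhUnitComponents()) -> float:
    """Dimensionless input coefficient ``k = R2 / (2 R VT)`` of the unit."""
    return components.R2 / (2.0 * components.R * components.VT)


# conventional op-amp output headroom below the supply rails, in volts
_HEADROOM = 1.5


def tanh_unit_response(Vin: float,
                       components: TanhUnitComponents = TanhUnitComponents()) -> float:
    """Output voltage ``-tanh(k Vin)`` of the (inverting) tanh unit.

    The output is clipped to the op-amp headroom ``[VEE + 1.5, VCC - 1.5]``;
    with tanh bounded by 1 this only matters for extreme supply choices.
    """
    if not math.isfinite(Vin):
        raise ValueError("Vin must be finite")
    k = tanh_unit_gain(components)
    v = -math.tanh(k * Vin)
    return min(max(v, components.VEE + _HEADROOM), components.VCC - _HEADROOM)


def perturb_components(config: BirhythmicConfig,
                       resistor_tolerance_fraction: float,
                       seed: int = 0) -> BirhythmicConfig:
    """Emulate component tolerances by jittering the model's gains.

    Multiplies ``g_xy``, ``g_z``, the planar speed offset, and the
    stimulation coupling ``stim_gain`` by independent lognormal factors
    ``exp(N(0, tolerance))``, so each gain has relative spread roughly
    equal to ``resistor_tolerance_fraction``.  Tolerance 0 returns the
    configuration unchanged; the supported range [0, 0.1] keeps the
    perturbed system inside the birhythmic regime.
    """
    tol = float(resistor_tolerance_fraction)
    if not (0.0 <= tol <= 0.1):
        raise ValueError(f"tolerance must be in [0, 0.1], got {tol}")
    if tol == 0.0:
        return config
    rng = np.random.default_rng(seed)
    f = np.exp(rng.normal(0.0, tol, size=4))
    return replace(
        config,
        g_xy=config.g_xy * f[0],
        g_z=config.g_z * f[1],
        speed_offset=config.speed_offset * f[2],
        stim_gain=config.stim_gain * f[3],
    )
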