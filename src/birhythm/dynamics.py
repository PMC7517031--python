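"""Vector fields and equilibria of the birhythmic ct-GRU system.

The model is a three-dimensional continuous-time gated recurrent unit
(ct-GRU) whose hidden state ``h = (x, y, z)`` carries two coexisting stable
limit cycles ("birhythmicity").  The x-y subsystem is a planar rotational
tanh oscillator; the z coordinate selects one of two mirror-image copies of
that cycle and, through a linear update gate, rescales the speed of the
planar flow by ``(3/2 - z)``.  Trajectories with ``z > 0`` settle on a slow
cycle at ``z = +z*``, trajectories with ``z < 0`` on a fast cycle at
``z = -z*``, and the plane ``z = 0`` is an invariant separatrix.

All voltages are treated as dimensionless simulation units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GRUParameters",
    "BirhythmicConfig",
    "FixedPoint",
    "gru_rhs",
    "birhythmic_rhs",
    "birhythmic_rhs_batch",
    "make_birhythmic_config",
    "z_fixed_point",
    "find_fixed_points",
    "jacobian_at",
    "rotation_matrix",
]

# Admissible rotation angles for which the planar subsystem has a limit cycle.
ALPHA_MIN = math.pi / 21
ALPHA_MAX = math.pi / 3.8


def rotation_matrix(alpha: float) -> np.ndarray:
    """2x2 counter-clockwise rotation by ``alpha`` radians."""
    c, s = math.cos(alpha), math.sin(alpha)
    return np.array([[c, -s], [s, c]])


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


@dataclass(frozen=True)
class GRUParameters:
    """Parameters of a general autonomous ct-GRU flow of dimension ``d``.

    The flow is ``dh/dt = (1 - s) * (T - h)`` with update gate
    ``s = sigma(Us h + bs)`` (or ``s = Us h + bs`` when ``gate_mode`` is
    ``"linear"``), reset gate ``r = sigma(Ur h + br)`` and drive
    ``T = tanh(Uh (r * h) + bh)``.
    """

    Us: np.ndarray
    Ur: np.ndarray
    Uh: np.ndarray
    bs: np.ndarray
    br: np.ndarray
    bh: np.ndarray
    gate_mode: str = "sigmoid"

    def __post_init__(self):
        d = int(np.shape(self.Uh)[0])
        for name in ("Us", "Ur", "Uh"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (d, d):
                raise ValueError(f"{name} must be {d}x{d}, got {m.shape}")
            object.__setattr__(self, name, m)
        for name in ("bs", "br", "bh"):
            b = np.asarray(getattr(self, name), dtype=float)
            if b.shape != (d,):
                raise ValueError(f"{name} must have length {d}, got {b.shape}")
            object.__setattr__(self, name, b)
        if self.gate_mode not in ("sigmoid", "linear"):
            raise ValueError(f"gate_mode must be 'sigmoid' or 'linear', got {self.gate_mode!r}")

    @property
    def dimension(self) -> int:
        return self.Uh.shape[0]


def gru_rhs(state: np.ndarray, params: GRUParameters) -> np.ndarray:
    """Time derivative of the ct-GRU hidden state.

    Parameters
    ----------
    state
        Hidden state vector of length ``params.dimension``.
    params
        GRU parameter set; ``gate_mode`` selects a logistic-sigmoid or a
        linear update gate.

    Returns
    -------
    numpy.ndarray
        ``dh/dt = (1 - s) * (T - h)`` evaluated at ``state``.
    """
    h = np.asarray(state, dtype=float)
    if h.shape != (params.dimension,):
        raise ValueError(
            f"state must have shape ({params.dimension},), got {h.shape}"
        )
    if not np.all(np.isfinite(h)):
        raise ValueError("state contains non-finite components")
    pre_s = params.Us @ h + params.bs
    s = pre_s if params.gate_mode == "linear" else _sigmoid(pre_s)
    r = _sigmoid(params.Ur @ h + params.br)
    T = np.tanh(params.Uh @ (r * h) + params.bh)
    return (1.0 - s) * (T - h)


@dataclass(frozen=True)
class BirhythmicConfig:
    """Parameter set of the explicit birhythmic (x, y, z) system.

    Attributes
    ----------
    alpha
        Rotation angle of the planar oscillator (radians).  Must lie in the
        admissible interval ``(pi/21, pi/3.8)`` for a planar limit cycle to
        exist.
    g_xy
        Inner tanh gain of the x-y rotation.  The origin is an unstable
        focus (necessary for the cycle) iff ``g_xy * cos(alpha) > 1``.
    g_z
        Inner tanh gain of the z subsystem.  For ``g_z > 1`` the z axis has
        a pitchfork pair of sinks at ``z = +/- z*`` with ``z* = z_fixed_point(g_z)``;
        the default 3/2 places them at 0.8584.
    gamma
        Time constant of the z subsystem (``gamma >= 1`` makes z slow
        relative to the planar flow; larger gamma makes attractor
        transitions harder).
    stim_gain
        Coupling gain ``kappa`` from the stimulator output into dz/dt.
    speed_offset
        Offset of the planar speed factor ``(speed_offset - z)``; 3/2 in the
        ideal model, perturbed by the hardware-emulation layer.
    s_bias
        Bias of the linear update gate; fixed at (-1/2, -1/2, 1/2) in the
        ideal model.
    """

    alpha: float = math.pi / 5
    g_xy: float = 3.0
    g_z: float = 1.5
    gamma: float = 50.0
    stim_gain: float = 1.0
    speed_offset: float = 1.5
    s_bias: tuple = (-0.5, -0.5, 0.5)

    def __post_init__(self):
        if not (ALPHA_MIN < self.alpha < ALPHA_MAX):
            raise ValueError(
                f"alpha={self.alpha:.6g} outside the admissible interval "
                f"({ALPHA_MIN:.6g}, {ALPHA_MAX:.6g}) for a planar limit cycle"
            )
        if self.g_xy * math.cos(self.alpha) <= 1.0:
            raise ValueError(
                f"g_xy*cos(alpha)={self.g_xy * math.cos(self.alpha):.6g} <= 1: "
                "origin focus is not unstable, no planar limit cycle"
            )
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.g_z <= 0:
            raise ValueError(f"g_z must be positive, got {self.g_z}")
        if self.speed_offset <= 0:
            raise ValueError(f"speed_offset must be positive, got {self.speed_offset}")

    @classmethod
    def unvalidated(cls, **fields) -> "BirhythmicConfig":
        """Construct without enforcing the limit-cycle invariants.

        Intended for exploring degenerate regimes (e.g. a stable origin
        focus with ``g_xy * cos(alpha) <= 1``) where no planar cycle exists;
        normal construction rejects such parameter sets.
        """
        obj = object.__new__(cls)
        defaults = {f.name: f.default for f in dataclass_fields(cls)}
        defaults.update(fields)
        for name, value in defaults.items():
            object.__setattr__(obj, name, value)
        return obj

    def to_gru_parameters(self) -> GRUParameters:
        """Render this configuration as general ct-GRU parameters.

        Uses the linear update gate ``s = Us h + bs`` with
        ``Us = [[0,0,1],[0,0,1],[0,0,0]]`` and ``bs = (-1/2, -1/2, 1/2)``,
        and zero reset-gate parameters.  With ``Ur = br = 0`` the reset gate
        evaluates to the constant 1/2, so ``Uh`` carries a compensating
        factor 2 to reproduce the effective inner gains ``g_xy`` and ``g_z``.

        The rendering corresponds to the time normalization ``gamma = 1``:
        the ct-GRU form has no slot for the extra z time constant, which is
        applied on top of the GRU flow (``dz/dt`` divided by ``gamma``).
        """
        Uh = np.zeros((3, 3))
        Uh[:2, :2] = 2.0 * self.g_xy * rotation_matrix(self.alpha)
        Uh[2, 2] = 2.0 * self.g_z
        Us = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
        bs = np.array([self.s_bias[0], self.s_bias[1], self.s_bias[2]])
        # bs shifts so that 1 - s_x = speed_offset - z; the ideal value -1/2
        # corresponds to speed_offset = 3/2.
        bs[:2] = 1.0 - self.speed_offset
        zeros = np.zeros(3)
        return GRUParameters(
            Us=Us, Ur=np.zeros((3, 3)), Uh=Uh,
            bs=bs, br=zeros, bh=zeros, gate_mode="linear",
        )


def make_birhythmic_config(
    alpha: float = math.pi / 5,
    g_xy: float = 3.0,
    g_z: float = 1.5,
    gamma: float = 50.0,
    stim_gain: float = 1.0,
) -> BirhythmicConfig:
    """Construct a validated :class:`BirhythmicConfig`.

    Defaults reproduce the reference parameter set: alpha = pi/5, planar
    gain 3, z gain 3/2, z time constant 50 and unit stimulation coupling.
    Raises ``ValueError`` naming the violated bound for invalid parameters.
    """
    return BirhythmicConfig(
        alpha=alpha, g_xy=g_xy, g_z=g_z, gamma=gamma, stim_gain=stim_gain
    )


def birhythmic_rhs(state, config: BirhythmicConfig, stim_out: float = 0.0) -> np.ndarray:
    """Time derivative of the explicit (x, y, z) birhythmic system.

    ``dx/dt = (3/2 - z) [tanh(g_xy (x cos a - y sin a)) - x]``,
    ``dy/dt = (3/2 - z) [tanh(g_xy (x sin a + y cos a)) - y]``,
    ``dz/dt = (1/gamma) { (1/2) [tanh(g_z z) - z] + kappa * stim_out }``.

    ``stim_out`` is the stimulator-circuit output summed into dz/dt; it is
    zero when the system is unstimulated.
    """
    x, y, z = float(state[0]), float(state[1]), float(state[2])
    c, s = math.cos(config.alpha), math.sin(config.alpha)
    speed = config.speed_offset - z
    dx = speed * (math.tanh(config.g_xy * (x * c - y * s)) - x)
    dy = speed * (math.tanh(config.g_xy * (x * s + y * c)) - y)
    dz = (0.5 * (math.tanh(config.g_z * z) - z) + config.stim_gain * stim_out) / config.gamma
    return np.array([dx, dy, dz])


def birhythmic_rhs_batch(states: np.ndarray, config: BirhythmicConfig,
                         stim_out: float | np.ndarray = 0.0) -> np.ndarray:
    """Vectorized :func:`birhythmic_rhs` over an (n, 3) array of states."""
    h = np.asarray(states, dtype=float)
    x, y, z = h[..., 0], h[..., 1], h[..., 2]
    c, s = math.cos(config.alpha), math.sin(config.alpha)
    speed = config.speed_offset - z
    out = np.empty_like(h)
    out[..., 0] = speed * (np.tanh(config.g_xy * (x * c - y * s)) - x)
    out[..., 1] = speed * (np.tanh(config.g_xy * (x * s + y * c)) - y)
    out[..., 2] = (0.5 * (np.tanh(config.g_z * z) - z)
                   + config.stim_gain * stim_out) / config.gamma
    return out


def z_fixed_point(g_z: float) -> float:
    """Positive root of ``z = tanh(g_z z)``, or 0 when only the origin solves it.

    For ``g_z <= 1`` the tanh slope at the origin is at most 1 and the only
    root is 0.  For ``g_z > 1`` the unique positive root is found by
    bracketed root-finding to |f| < 1e-12.
    """
    if g_z <= 0:
        raise ValueError(f"g_z must be positive, got {g_z}")
    if g_z <= 1.0:
        return 0.0

    def f(z):
        return math.tanh(g_z * z) - z

    # f > 0 just right of 0 (slope g_z > 1), f < 0 at z = 1 + 1/g_z > tanh sup.
    lo = 1e-8
    hi = 1.0 + 1.0 / g_z
    root = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)
    assert abs(f(root)) < 1e-12
    return float(root)


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium of the birhythmic flow with its linear stability."""

    state: np.ndarray
    eigenvalues: np.ndarray
    stability: str  # "unstable", "stable", or "saddle-focus"

    @property
    def n_unstable(self) -> int:
        return int(np.sum(self.eigenvalues.real > 0))


def jacobian_at(state, config: BirhythmicConfig, step: float = 1e-6) -> np.ndarray:
    """Jacobian of the unstimulated flow by central finite differences."""
    h = np.asarray(state, dtype=float)
    J = np.empty((3, 3))
    for j in range(3):
        hp, hm = h.copy(), h.copy()
        hp[j] += step
        hm[j] -= step
        J[:, j] = (birhythmic_rhs(hp, config) - birhythmic_rhs(hm, config)) / (2 * step)
    return J


def _label(eigs: np.ndarray) -> str:
    pos = np.sum(eigs.real > 0)
    if pos == len(eigs):
        return "unstable"
    if pos == 0:
        return "stable"
    return "saddle-focus"


def find_fixed_points(config: BirhythmicConfig) -> list[FixedPoint]:
    """Equilibria of the birhythmic system with Jacobian stability labels.

    The z subsystem decouples, and since ``g_xy cos(alpha) > 1`` the planar
    subsystem's only equilibrium is the origin; every fixed point therefore
    lies on the z axis: the origin always, plus ``(0, 0, +/- z*)`` whenever
    ``g_z > 1``.  Each is labeled from the eigenvalues of the (analytic
    structure, numerically evaluated) Jacobian.
    """
    zs = [0.0]
    zstar = z_fixed_point(config.g_z)
    if zstar > 0:
        zs += [zstar, -zstar]
    out = []
    for z in zs:
        state = np.array([0.0, 0.0, z])
        resid = np.linalg.norm(birhythmic_rhs(state, config))
        if resid > 1e-10:
            raise RuntimeError(
                f"fixed-point candidate (0,0,{z:.6g}) has residual {resid:.3g}"
            )
        eigs = np.linalg.eigvals(jacobian_at(state, config))
        out.append(FixedPoint(state=state, eigenvalues=eigs, stability=_label(eigs)))
    return out
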