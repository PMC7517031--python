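"""Numerical integration of the birhythmic flow with stimulation.

The integrator treats the raw stimulus ``S_in`` as piecewise-constant
between protocol-defined switch times (zero-order hold), while the
state-dependent stimulator interface ``S_out = S_in * x * y`` is evaluated
continuously inside the right-hand side, exactly as the analog interface
circuit multiplies the instantaneous state.  Integration therefore proceeds
segment by segment between switch times with an adaptive high-order solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import BirhythmicConfig

__all__ = [
    "Trajectory",
    "IntegrationError",
    "integrate",
    "integrate_euler_oracle",
    "detect_plane_crossings",
]

_COORD_INDEX = {"x": 0, "y": 1, "z": 2}


class IntegrationError(RuntimeError):
    """Raised when the solver fails; carries the last valid time."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(f"{message} (last valid time t={last_valid_time:.6g})")
        self.last_valid_time = last_valid_time


@dataclass
class Trajectory:
    """Uniformly sampled time series of state, stimulus and stimulator output."""

    t: np.ndarray
    states: np.ndarray  # shape (n, 3)
    stim_in: np.ndarray
    stim_out: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.stim_in = np.asarray(self.stim_in, dtype=float)
        self.stim_out = np.asarray(self.stim_out, dtype=float)
        n = len(self.t)
        if self.states.shape != (n, 3):
            raise ValueError(f"states must be ({n}, 3), got {self.states.shape}")
        if len(self.stim_in) != n or len(self.stim_out) != n:
            raise ValueError("stim_in/stim_out length mismatch with t")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.states)) and np.all(np.isfinite(self.t))):
            raise ValueError("trajectory contains non-finite values")

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_csv(self, path_or_buf) -> None:
        """Write columns t, x, y, z, stim_in, stim_out with 9 significant digits."""
        data = np.column_stack(
            [self.t, self.states, self.stim_in, self.stim_out]
        )
        header = "t,x,y,z,stim_in,stim_out"
        if hasattr(path_or_buf, "write"):
            np.savetxt(path_or_buf, data, fmt="%.9g", delimiter=",",
                       header=header, comments="")
        else:
            with open(path_or_buf, "w") as fh:
                np.savetxt(fh, data, fmt="%.9g", delimiter=",",
                           header=header, comments="")

    @classmethod
    def from_csv(cls, path_or_buf) -> "Trajectory":
        data = np.loadtxt(path_or_buf, delimiter=",", skiprows=1)
        data = np.atleast_2d(data)
        return cls(t=data[:, 0], states=data[:, 1:4],
                   stim_in=data[:, 4], stim_out=data[:, 5])


def _scalar_rhs(config: BirhythmicConfig, s_in: float, s_out_fn):
    """Fast scalar-math RHS closure for one constant-``S_in`` segment."""
    c = math.cos(config.alpha)
    s = math.sin(config.alpha)
    g = config.g_xy
    gz = config.g_z
    off = config.speed_offset
    kappa = config.stim_gain
    gamma = config.gamma

    def rhs(t, h):
        x, y, z = h
        sp = off - z
        so = s_out_fn(s_in, x, y)
        return (
            sp * (math.tanh(g * (x * c - y * s)) - x),
            sp * (math.tanh(g * (x * s + y * c)) - y),
            (0.5 * (math.tanh(gz * z) - z) + kappa * so) / gamma,
        )

    return rhs


def _zero_s_out(s_in, x, y):
    return 0.0


def _protocol_pieces(protocol, t0: float, t1: float):
    """Yield (ta, tb, s_in) segments covering [t0, t1] with constant S_in."""
    if protocol is None:
        yield t0, t1, 0.0
        return
    bps = np.asarray(protocol.breakpoints(t0, t1), dtype=float)
    bps = bps[(bps > t0 + 1e-12) & (bps < t1 - 1e-12)]
    edges = np.concatenate([[t0], np.sort(bps), [t1]])
    for ta, tb in zip(edges[:-1], edges[1:]):
        if tb - ta <= 1e-13:
            continue
        # evaluate at the midpoint: unambiguous under FP jitter at edges
        yield ta, tb, float(protocol.s_in(0.5 * (ta + tb)))


def integrate(
    config: BirhythmicConfig,
    x0,
    protocol=None,
    t_span=(0.0, 5.0),
    dt_out: float = 0.01,
    tol: float = 1e-8,
) -> Trajectory:
    """Integrate the birhythmic system with adaptive RK45.

    Parameters
    ----------
    config
        Model parameters.
    x0
        Initial state ``(x, y, z)``.
    protocol
        A stimulation protocol (see :mod:`birhythm.stimulation`) or ``None``
        for the unstimulated plant.  The protocol supplies the
        piecewise-constant raw stimulus and the stimulator-interface map.
    t_span
        ``(t0, t1)``; the output grid is ``t0 + k * dt_out``.
    dt_out
        Output sampling interval.
    tol
        Relative tolerance of the adaptive solver, in ``[1e-12, 1e-3]``.

    Returns
    -------
    Trajectory
        State, raw stimulus and stimulator output on the uniform grid.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not (math.isfinite(t0) and math.isfinite(t1)) or t1 <= t0:
        raise ValueError(f"invalid t_span {t_span}")
    if not (1e-12 <= tol <= 1e-3):
        raise ValueError(f"tol must be in [1e-12, 1e-3], got {tol}")
    if dt_out <= 0:
        raise ValueError(f"dt_out must be positive, got {dt_out}")

    n_out = int(round((t1 - t0) / dt_out))
    if abs(t0 + n_out * dt_out - t1) > 1e-9 * max(1.0, abs(t1)):
        n_out = int(math.floor((t1 - t0) / dt_out + 1e-12))
    grid = t0 + dt_out * np.arange(n_out + 1)
    t_end = grid[-1]

    s_out_fn = protocol.s_out if protocol is not None else _zero_s_out

    h = np.asarray(x0, dtype=float)
    if h.shape != (3,) or not np.all(np.isfinite(h)):
        raise ValueError(f"x0 must be a finite 3-vector, got {x0!r}")

    times = [grid[0]]
    states = [h.copy()]
    next_idx = 1  # next grid point to fill

    for ta, tb, s_val in _protocol_pieces(protocol, t0, t_end):
        # grid points strictly inside (ta, tb]
        hi = np.searchsorted(grid, tb + 1e-12 * max(1.0, abs(tb)))
        t_eval = list(grid[next_idx:hi])
        endpoint_on_grid = bool(t_eval) and abs(t_eval[-1] - tb) <= 1e-12 * max(1.0, abs(tb))
        if not endpoint_on_grid:
            t_eval.append(tb)  # always integrate to the segment end
        rhs = _scalar_rhs(config, s_val, s_out_fn)
        sol = solve_ivp(
            rhs, (ta, tb), h, method="RK45", t_eval=t_eval,
            rtol=tol, atol=tol * 1e-3, dense_output=False,
        )
        if sol.status != 0 or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(
                f"integration failed: {sol.message}",
                last_valid_time=float(sol.t[-1]) if len(sol.t) else ta,
            )
        n_grid = hi - next_idx
        for k in range(n_grid):
            times.append(grid[next_idx + k])
            states.append(sol.y[:, k])
        next_idx = hi
        h = sol.y[:, -1].copy()

    t_arr = np.asarray(times)
    st_arr = np.asarray(states)
    # raw stimulus recorded right-continuously at the sample instants
    if protocol is not None:
        si_arr = np.array([float(protocol.s_in(tv)) for tv in t_arr])
    else:
        si_arr = np.zeros(len(t_arr))
    so_arr = np.array(
        [s_out_fn(si, s[0], s[1]) for si, s in zip(si_arr, st_arr)]
    )
    meta = {
        "config": config,
        "t_span": (t0, float(t_end)),
        "dt_out": dt_out,
        "tol": tol,
        "protocol": repr(protocol) if protocol is not None else "none",
    }
    return Trajectory(t=t_arr, states=st_arr, stim_in=si_arr,
                      stim_out=so_arr, meta=meta)


def integrate_euler_oracle(
    config: BirhythmicConfig,
    x0,
    protocol=None,
    t_span=(0.0, 1.0),
    dt: float = 1e-5,
) -> Trajectory:
    """Fixed-step forward-Euler reference integrator.

    A deliberately naive first-order scheme used as an independent check of
    the adaptive solver in the test suite.  ``dt`` must be at most 1e-3.
    The raw stimulus is evaluated at the left endpoint of every step.
    """
    if dt > 1e-3:
        raise ValueError(f"oracle requires dt <= 1e-3, got {dt}")
    t0, t1 = float(t_span[0]), float(t_span[1])
    n = int(round((t1 - t0) / dt))
    s_out_fn = protocol.s_out if protocol is not None else _zero_s_out

    c = math.cos(config.alpha)
    s = math.sin(config.alpha)
    g, gz = config.g_xy, config.g_z
    off, kappa, gamma = config.speed_offset, config.stim_gain, config.gamma

    x, y, z = (float(v) for v in x0)
    times = np.empty(n + 1)
    states = np.empty((n + 1, 3))
    stim_in = np.empty(n + 1)
    stim_out = np.empty(n + 1)
    for i in range(n + 1):
        t = t0 + i * dt
        si = float(protocol.s_in(t)) if protocol is not None else 0.0
        so = s_out_fn(si, x, y)
        times[i] = t
        states[i] = (x, y, z)
        stim_in[i] = si
        stim_out[i] = so
        if i == n:
            break
        sp = off - z
        dx = sp * (math.tanh(g * (x * c - y * s)) - x)
        dy = sp * (math.tanh(g * (x * s + y * c)) - y)
        dz = (0.5 * (math.tanh(gz * z) - z) + kappa * so) / gamma
        x += dt * dx
        y += dt * dy
        z += dt * dz
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            raise IntegrationError("Euler oracle diverged", last_valid_time=t)
    return Trajectory(t=times, states=states, stim_in=stim_in,
                      stim_out=stim_out, meta={"config": config, "dt": dt})


def final_state(
    config: BirhythmicConfig,
    x0,
    protocol=None,
    t_span=(0.0, 5.0),
    tol: float = 1e-8,
) -> np.ndarray:
    """End state of an integration without dense output (fast path)."""
    t0, t1 = float(t_span[0]), float(t_span[1])
    s_out_fn = protocol.s_out if protocol is not None else _zero_s_out
    h = np.asarray(x0, dtype=float)
    for ta, tb, s_val in _protocol_pieces(protocol, t0, t1):
        rhs = _scalar_rhs(config, s_val, s_out_fn)
        sol = solve_ivp(rhs, (ta, tb), h, method="RK45", t_eval=[tb],
                        rtol=tol, atol=tol * 1e-3)
        if sol.status != 0 or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(
                f"integration failed: {sol.message}", last_valid_time=ta
            )
        h = sol.y[:, -1]
    return h


def detect_plane_crossings(traj: Trajectory, coordinate: str, level: float):
    """Linear-interpolated crossing times of one coordinate through a level.

    Uses the half-open sample convention: a sample lying exactly on the
    level counts as a crossing with the direction of the following step.

    Returns
    -------
    list of (time, direction)
        ``direction`` is +1 for an upward crossing, -1 for downward.
    """
    if coordinate not in _COORD_INDEX:
        raise ValueError(f"coordinate must be one of x, y, z, got {coordinate!r}")
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    v = traj.states[:, _COORD_INDEX[coordinate]] - level
    t = traj.t
    out = []
    for i in range(len(v) - 1):
        a, b = v[i], v[i + 1]
        if a == 0.0:
            if b > 0:
                out.append((float(t[i]), +1))
            elif b < 0:
                out.append((float(t[i]), -1))
            continue
        if a < 0 < b or a > 0 > b:
            frac = -a / (b - a)
            tc = t[i] + frac * (t[i + 1] - t[i])
            out.append((float(tc), +1 if b > a else -1))
    return out
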