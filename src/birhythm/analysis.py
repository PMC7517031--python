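"""Attractor characterization and stimulation-trial statistics.

Exploits the exact structure of the model where it is safe to do so: the z
subsystem decouples from (x, y), so basin membership and the asymptotic z
level can be computed from the scalar z equation alone, and trajectories
are placed on an attractor by first settling z and then letting the planar
coordinates relax onto the cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import BirhythmicConfig, z_fixed_point
from .simulate import (
    IntegrationError,
    Trajectory,
    detect_plane_crossings,
    final_state,
    integrate,
)

__all__ = [
    "BASIN_BOXES",
    "PeriodEstimate",
    "LimitCycleSummary",
    "TrialResult",
    "classify_basin",
    "settle_z",
    "prepare_on_attractor",
    "estimate_period",
    "limit_cycle_summary",
    "count_attractors",
    "max_z_deviation",
    "detect_transition",
    "run_trial_battery",
]

# Initialization boxes of the two basins of attraction (x, y, z ranges).
BASIN_BOXES = {
    "slow": ((-1.5, 1.5), (-1.5, 1.5), (0.0, 1.5)),
    "fast": ((-1.5, 1.5), (-1.5, 1.5), (-1.5, 0.0)),
}


def _z_rhs(config: BirhythmicConfig):
    gz, gamma = config.g_z, config.gamma

    def rhs(t, z):
        return [0.5 * (math.tanh(gz * z[0]) - z[0]) / gamma]

    return rhs


def settle_z(config: BirhythmicConfig, z0: float, dz_tol: float = 1e-8,
             max_horizon: float | None = None) -> float:
    """Integrate the decoupled z subsystem until |dz/dt| < ``dz_tol``.

    Returns the settled z value.  Raises ``RuntimeError`` if the derivative
    has not fallen below the threshold within ``max_horizon`` (default
    400 * gamma) time units.
    """
    if max_horizon is None:
        max_horizon = 400.0 * config.gamma
    rhs = _z_rhs(config)
    z = float(z0)
    t = 0.0
    chunk = 20.0 * config.gamma
    while True:
        if abs(rhs(0.0, [z])[0]) < dz_tol:
            return z
        if t >= max_horizon:
            raise RuntimeError(
                f"z subsystem did not settle below |dz/dt|={dz_tol:g} "
                f"within {max_horizon:g} time units (z={z:.6g})"
            )
        sol = solve_ivp(rhs, (t, t + chunk), [z], rtol=1e-10, atol=1e-12,
                        t_eval=[t + chunk])
        z = float(sol.y[0, -1])
        t += chunk


def classify_basin(x0, config: BirhythmicConfig, delta: float = 1e-6) -> str:
    """Basin label of an initial state: ``slow``, ``fast`` or ``boundary``.

    The z = 0 plane is invariant, so a start with |z0| <= ``delta`` is on
    the separatrix ("boundary").  Otherwise the decoupled z subsystem is
    integrated until it settles and the sign of the limit decides.
    """
    x0 = np.asarray(x0, dtype=float)
    if not np.all(np.isfinite(x0)):
        raise ValueError("initial state must be finite")
    z0 = float(x0[2])
    if abs(z0) <= delta:
        return "boundary"
    z_inf = settle_z(config, z0)
    if z_inf > delta:
        return "slow"
    if z_inf < -delta:
        return "fast"
    return "boundary"


def prepare_on_attractor(config: BirhythmicConfig, x0,
                         tol: float = 1e-9) -> np.ndarray:
    """Relax an initial state onto its attractor.

    Two stages, both exact consequences of the z decoupling: (1) settle the
    scalar z subsystem to its limit; (2) integrate the full system with z
    already settled until the planar coordinates have converged onto the
    cycle (80 time units of rescaled planar time, several orbital periods
    and many planar contraction times).
    """
    x0 = np.asarray(x0, dtype=float)
    z_inf = settle_z(config, float(x0[2]))
    speed = config.speed_offset - z_inf
    if speed <= 0:
        raise RuntimeError(f"settled z={z_inf:.6g} gives non-positive planar speed")
    t_land = 80.0 / speed
    start = np.array([x0[0], x0[1], z_inf])
    if abs(start[0]) + abs(start[1]) < 1e-9:
        # the z axis is invariant; nudge off it so the planar cycle is reached
        start[0] = 1e-6
    return final_state(config, start, None, (0.0, t_land), tol=tol)


@dataclass(frozen=True)
class PeriodEstimate:
    """Oscillation period from Poincare-section return times."""

    period: float
    stderr: float
    n_returns: int

    def __float__(self):
        return self.period


def estimate_period(traj: Trajectory) -> PeriodEstimate:
    """Period as the mean spacing of upward crossings of {y = 0, x > 0}.

    The trajectory should already lie on (or near) an attractor and cover
    several cycles.  Raises ``ValueError`` with fewer than two section
    crossings.
    """
    crossings = detect_plane_crossings(traj, "y", 0.0)
    x_interp = np.interp([tc for tc, _ in crossings], traj.t, traj.x)
    times = [tc for (tc, d), xv in zip(crossings, x_interp) if d > 0 and xv > 0]
    if len(times) < 2:
        raise ValueError(
            f"need >= 2 Poincare-section crossings to estimate a period, got {len(times)}"
        )
    gaps = np.diff(times)
    stderr = float(gaps.std(ddof=1) / math.sqrt(len(gaps))) if len(gaps) > 1 else float("nan")
    return PeriodEstimate(period=float(gaps.mean()), stderr=stderr,
                          n_returns=len(times))


@dataclass(frozen=True)
class LimitCycleSummary:
    """Trial-aggregate statistics of one limit cycle."""

    basin: str
    mean_z: float       # mean across trials of the per-trial mean z
    std_z: float        # std across the trial means
    period: float       # mean of per-trial period estimates
    period_stderr: float
    orbit: np.ndarray   # sampled (x, y) closed curve from one trial


def _uniform_in_box(rng: np.random.Generator, box) -> np.ndarray:
    return np.array([rng.uniform(lo, hi) for lo, hi in box])


def limit_cycle_summary(
    config: BirhythmicConfig,
    basin: str,
    n_trials: int = 10,
    seed: int = 0,
    record_time: float = 100.0,
    dt_out: float = 0.01,
):
    """Statistics of one limit cycle over randomly initialized trials.

    Each trial draws an initial state uniformly from the basin's
    initialization box, relaxes onto the attractor, records for
    ``record_time`` time units, and reports the per-trial mean and standard
    deviation of z plus a Poincare period estimate.  The aggregate is the
    mean of the trial means and the standard deviation across trial means.

    Returns
    -------
    (LimitCycleSummary, pandas.DataFrame)
        The aggregate summary and the per-trial table.
    """
    if basin not in BASIN_BOXES:
        raise ValueError(f"basin must be 'slow' or 'fast', got {basin!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_trials)
    rows = []
    orbit = None
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        x0 = _uniform_in_box(rng, BASIN_BOXES[basin])
        start = prepare_on_attractor(config, x0)
        traj = integrate(config, start, None, (0.0, record_time), dt_out=dt_out)
        pe = estimate_period(traj)
        rows.append({
            "trial": i,
            "x0": x0[0], "y0": x0[1], "z0": x0[2],
            "mean_z": float(traj.z.mean()),
            "std_z": float(traj.z.std()),
            "period": pe.period,
            "period_stderr": pe.stderr,
        })
        if orbit is None:
            orbit = np.column_stack([traj.x, traj.y])
    df = pd.DataFrame(rows)
    summary = LimitCycleSummary(
        basin=basin,
        mean_z=float(df["mean_z"].mean()),
        std_z=float(df["mean_z"].std(ddof=1)) if n_trials > 1 else 0.0,
        period=float(df["period"].mean()),
        period_stderr=float(df["period"].std(ddof=1) / math.sqrt(n_trials))
        if n_trials > 1 else float("nan"),
        orbit=orbit,
    )
    return summary, df


def count_attractors(config: BirhythmicConfig, n_samples: int = 20,
                     seed: int = 0, record_time: float = 100.0) -> int:
    """Number of distinct periodic attractors found from random starts.

    Samples initial states uniformly from [-1.5, 1.5]^3 (excluding a thin
    slab |z| < 0.05 around the separatrix), relaxes each onto its limit
    set, and clusters the outcomes by the sign of the mean z level and by
    period agreement within 5%.  Starts that converge to a fixed point
    (planar amplitude below 1e-3) are not counted as periodic attractors.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    clusters: list[tuple[int, float]] = []
    for _ in range(n_samples):
        while True:
            x0 = rng.uniform(-1.5, 1.5, size=3)
            if abs(x0[2]) >= 0.05:
                break
        start = prepare_on_attractor(config, x0)
        traj = integrate(config, start, None, (0.0, record_time), dt_out=0.01)
        amp = float(np.hypot(traj.x, traj.y).max())
        if amp < 1e-3:
            continue  # spiraled into a fixed point: not periodic
        mean_z = float(traj.z.mean())
        zsign = 0 if abs(mean_z) < 0.05 else (1 if mean_z > 0 else -1)
        period = estimate_period(traj).period
        for csign, cperiod in clusters:
            if csign == zsign and abs(period - cperiod) <= 0.05 * max(period, cperiod):
                break
        else:
            clusters.append((zsign, period))
    return len(clusters)


def max_z_deviation(traj: Trajectory, z_ref: float) -> float:
    """Largest excursion of z from the reference attractor level."""
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    return float(np.abs(traj.z - z_ref).max())


def detect_transition(traj: Trajectory, initial_sign: int,
                      sustain: float = 1.0):
    """First time z flips sign and stays flipped for >= ``sustain`` time units.

    Returns ``(transitioned, transition_time)``; ``transition_time`` is the
    interpolated z = 0 crossing that opens the sustained run, or ``None``.
    Requiring a sustained flip prevents counting grazes of the separatrix.
    """
    if initial_sign not in (-1, 1):
        raise ValueError("initial_sign must be +1 or -1")
    opp = (traj.z * initial_sign) < 0
    t = traj.t
    n = len(t)
    i = 0
    while i < n:
        if not opp[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and opp[j + 1]:
            j += 1
        if t[j] - t[i] >= sustain:
            if i > 0:
                za, zb = traj.z[i - 1], traj.z[i]
                frac = -za / (zb - za) if zb != za else 0.0
                tc = t[i - 1] + frac * (t[i] - t[i - 1])
            else:
                tc = t[0]
            return True, float(tc)
        i = j + 1
    return False, None


def _record_trial(config, start, protocol, record_time, dt_out, tol,
                  init_sign, sustain=1.0):
    """Record one stimulation trial, stopping once its outcome is decided.

    Integrates in chunks and terminates early after a sustained transition
    has had ``~1.2 * gamma`` further time units to settle onto the far
    attractor.  Driving z beyond the linear update gate's positivity region
    (z > 3/2) reverses the planar flow and eventually blows up the ideal
    model; a trial whose transition is already decided is truncated at the
    last valid sample instead of failing.
    """
    chunk = max(dt_out, math.ceil(25.0 / dt_out) * dt_out)
    settle_margin = sustain + 1.2 * config.gamma
    pieces = []
    h = np.asarray(start, dtype=float)
    t0 = 0.0
    transitioned, t_trans = False, None
    while t0 < record_time - 1e-9:
        t1 = min(t0 + chunk, record_time)
        try:
            seg = integrate(config, h, protocol, (t0, t1), dt_out=dt_out,
                            tol=tol)
        except IntegrationError:
            if transitioned:
                break  # post-transition blowup: outcome already decided
            raise
        pieces.append(seg)
        h = seg.final_state
        t0 = t1
        if not transitioned:
            joined = _concat(pieces)
            transitioned, t_trans = detect_transition(joined, init_sign,
                                                      sustain=sustain)
        if transitioned and t0 >= t_trans + settle_margin:
            break
    return _concat(pieces), transitioned, t_trans


def _concat(pieces):
    if len(pieces) == 1:
        return pieces[0]
    t = [pieces[0].t]
    states = [pieces[0].states]
    si = [pieces[0].stim_in]
    so = [pieces[0].stim_out]
    for seg in pieces[1:]:
        t.append(seg.t[1:])  # drop duplicated chunk-boundary sample
        states.append(seg.states[1:])
        si.append(seg.stim_in[1:])
        so.append(seg.stim_out[1:])
    return Trajectory(t=np.concatenate(t), states=np.concatenate(states),
                      stim_in=np.concatenate(si), stim_out=np.concatenate(so),
                      meta=pieces[0].meta)


@dataclass(frozen=True)
class TrialResult:
    """Outcome of a single stimulation trial."""

    protocol: str
    basin: str
    trial: int
    seed: int
    initial_state: np.ndarray
    max_z_deviation: float
    transitioned: bool
    transition_time: float | None


def run_trial_battery(
    config: BirhythmicConfig,
    protocols: dict,
    n_trials_per_cell: int = 10,
    seed: int = 0,
    basins=("slow", "fast"),
    record_time: float | None = None,
    dt_out: float = 0.05,
    tol: float = 1e-7,
):
    """Seeded battery of stimulation trials over a protocol x basin grid.

    ``protocols`` maps a name to either a protocol spec dict
    (``{"kind": ..., **params}``; seeded kinds get a per-trial seed split
    from the master seed) or a ready protocol instance (reused across
    trials).  Each trial initializes randomly inside the basin box, relaxes
    onto the attractor, records for ``record_time`` (default ``4 * gamma``,
    long enough for the z subsystem to traverse the separatrix under
    effective stimulation), and reports the maximum z excursion from the
    attractor level plus the sustained-transition flag and time.

    Returns
    -------
    (pandas.DataFrame, pandas.DataFrame)
        Per-trial table and per-cell summary (transition counts, deviation
        statistics).
    """
    from .stimulation import StimulationProtocol, make_protocol

    if record_time is None:
        record_time = 4.0 * config.gamma
    zstar = z_fixed_point(config.g_z)
    root_ss = np.random.SeedSequence(seed)
    cell_seeds = root_ss.spawn(len(protocols) * len(basins))
    rows = []
    idx = 0
    for name, proto_spec in protocols.items():
        for basin in basins:
            trial_seeds = cell_seeds[idx].spawn(n_trials_per_cell)
            idx += 1
            z_ref = zstar if basin == "slow" else -zstar
            init_sign = 1 if basin == "slow" else -1
            for k, tss in enumerate(trial_seeds):
                rng = np.random.default_rng(tss)
                trial_seed = int(rng.integers(0, 2**31 - 1))
                x0 = _uniform_in_box(rng, BASIN_BOXES[basin])
                start = prepare_on_attractor(config, x0)
                if isinstance(proto_spec, StimulationProtocol):
                    protocol = proto_spec
                elif proto_spec is None:
                    protocol = None
                else:
                    protocol = make_protocol(proto_spec, seed=trial_seed)
                traj, transitioned, t_trans = _record_trial(
                    config, start, protocol, record_time, dt_out, tol,
                    init_sign,
                )
                result = TrialResult(
                    protocol=name, basin=basin, trial=k, seed=trial_seed,
                    initial_state=x0,
                    max_z_deviation=max_z_deviation(traj, z_ref),
                    transitioned=transitioned, transition_time=t_trans,
                )
                rows.append({
                    "protocol": result.protocol,
                    "basin": result.basin,
                    "trial": result.trial,
                    "seed": result.seed,
                    "x0": x0[0], "y0": x0[1], "z0": x0[2],
                    "max_z_deviation": result.max_z_deviation,
                    "transitioned": result.transitioned,
                    "transition_time": result.transition_time,
                })
    trials = pd.DataFrame(rows)
    summary = (
        trials.groupby(["protocol", "basin"], sort=False)
        .agg(
            n_trials=("trial", "count"),
            n_transitions=("transitioned", "sum"),
            mean_max_z_deviation=("max_z_deviation", "mean"),
            std_max_z_deviation=("max_z_deviation", "std"),
            mean_transition_time=("transition_time", "mean"),
        )
        .reset_index()
    )
    return trials, summary
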