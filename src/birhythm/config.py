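"""Run configuration: JSON schema, validation and seed splitting.

A run configuration gathers everything needed to reproduce an experiment:
model parameters, hardware-emulation settings, stimulation protocol
spec(s), trial counts and horizons, and a master seed.  Unknown keys are
rejected at every level (fail-loud), and serialization round-trips
losslessly.  Every random operation downstream consumes a seed derived
from the master seed through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .dynamics import BirhythmicConfig
from .hardware import TanhUnitComponents, perturb_components

__all__ = ["RunConfig", "load_run_config", "parse_run_config"]

_MODEL_KEYS = {"alpha", "g_xy", "g_z", "gamma", "stim_gain", "speed_offset"}
_HW_KEYS = {"tolerance", "components"}
_COMPONENT_KEYS = {f.name for f in dataclasses.fields(TanhUnitComponents)}
_TRIAL_KEYS = {"n_trials_per_cell", "basins"}
_HORIZON_KEYS = {"record_time", "dt_out", "t_final", "tol"}
_TOP_KEYS = {"model", "hardware", "protocol", "protocols", "trials",
             "horizons", "seed"}


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


@dataclass
class RunConfig:
    """Parsed, validated run configuration."""

    model: BirhythmicConfig = field(default_factory=BirhythmicConfig)
    hardware_tolerance: float = 0.0
    components: TanhUnitComponents = field(default_factory=TanhUnitComponents)
    protocol: dict | None = None            # single-protocol runs (simulate)
    protocols: dict | None = None           # grid runs (experiment)
    n_trials_per_cell: int = 10
    basins: tuple = ("slow", "fast")
    record_time: float | None = None        # None -> 4 * gamma
    t_final: float | None = None
    dt_out: float = 0.05
    tol: float = 1e-8
    seed: int = 0

    def effective_model(self, seed: int | None = None) -> BirhythmicConfig:
        """Model with hardware tolerance applied (seeded), if any."""
        if self.hardware_tolerance == 0.0:
            return self.model
        return perturb_components(self.model, self.hardware_tolerance,
                                  seed=self.seed if seed is None else seed)

    def to_dict(self) -> dict:
        d = {
            "model": {
                "alpha": self.model.alpha,
                "g_xy": self.model.g_xy,
                "g_z": self.model.g_z,
                "gamma": self.model.gamma,
                "stim_gain": self.model.stim_gain,
                "speed_offset": self.model.speed_offset,
            },
            "hardware": {
                "tolerance": self.hardware_tolerance,
                "components": dataclasses.asdict(self.components),
            },
            "trials": {
                "n_trials_per_cell": self.n_trials_per_cell,
                "basins": list(self.basins),
            },
            "horizons": {
                "record_time": self.record_time,
                "t_final": self.t_final,
                "dt_out": self.dt_out,
                "tol": self.tol,
            },
            "seed": self.seed,
        }
        if self.protocol is not None:
            d["protocol"] = self.protocol
        if self.protocols is not None:
            d["protocols"] = self.protocols
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def parse_run_config(data: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a plain dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValueError("run config must be a JSON object")
    _reject_unknown(data, _TOP_KEYS, "run config")

    model_d = dict(data.get("model", {}))
    _reject_unknown(model_d, _MODEL_KEYS, "model")
    model = BirhythmicConfig(**model_d)

    hw = dict(data.get("hardware", {}))
    _reject_unknown(hw, _HW_KEYS, "hardware")
    tol_frac = float(hw.get("tolerance", 0.0))
    comp_d = dict(hw.get("components", {}))
    _reject_unknown(comp_d, _COMPONENT_KEYS, "hardware.components")
    components = TanhUnitComponents(**comp_d)

    trials = dict(data.get("trials", {}))
    _reject_unknown(trials, _TRIAL_KEYS, "trials")
    basins = tuple(trials.get("basins", ("slow", "fast")))
    for b in basins:
        if b not in ("slow", "fast"):
            raise ValueError(f"unknown basin {b!r} in trials.basins")

    horizons = dict(data.get("horizons", {}))
    _reject_unknown(horizons, _HORIZON_KEYS, "horizons")

    seed = int(data.get("seed", 0))

    return RunConfig(
        model=model,
        hardware_tolerance=tol_frac,
        components=components,
        protocol=data.get("protocol"),
        protocols=data.get("protocols"),
        n_trials_per_cell=int(trials.get("n_trials_per_cell", 10)),
        basins=basins,
        record_time=horizons.get("record_time"),
        t_final=horizons.get("t_final"),
        dt_out=float(horizons.get("dt_out", 0.05)),
        tol=float(horizons.get("tol", 1e-8)),
        seed=seed,
    )


def load_run_config(path) -> RunConfig:
    """Read and validate a JSON run-configuration file."""
    with open(path) as fh:
        data = json.load(fh)
    return parse_run_config(data)
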