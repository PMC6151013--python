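"""Configuration files, trajectory CSV round-trips, seeds and run logs."""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ConfigurationError, Scenario, SolverSettings, Trajectory

__all__ = ["RunConfig", "load_config", "save_config", "write_trajectory",
           "read_trajectory", "derive_seed", "write_run_log",
           "scenario_from_config"]

_TOP_KEYS = {"variant", "scenario", "overrides", "solver", "search",
             "output", "seed"}
_SCEN_KEYS = {"kind", "s1_0", "s2_0", "b_0", "t_end", "pulse_size",
              "doublings", "e2_high", "initial", "pulses"}
_SOLVER_KEYS = {f.name for f in
                __import__("dataclasses").fields(SolverSettings)}


@dataclass
class RunConfig:
    """Fully serialisable description of one run."""

    variant: str = "base"
    scenario: dict = field(default_factory=lambda: {"kind": "batch"})
    overrides: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    search: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    from .variants import ENSEMBLE

    valid = set(ENSEMBLE) | {"base", "base_dfba"}
    if cfg.variant not in valid:
        raise ConfigurationError(f"unknown variant id {cfg.variant!r}")
    bad = set(cfg.scenario) - _SCEN_KEYS
    if bad:
        raise ConfigurationError(f"unknown scenario key(s): {sorted(bad)}")
    bad = set(cfg.solver) - _SOLVER_KEYS
    if bad:
        raise ConfigurationError(f"unknown solver key(s): {sorted(bad)}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def scenario_from_config(cfg: RunConfig, spec=None) -> Scenario:
    from .scenarios import make_batch, make_preculture, make_pulse

    sc = dict(cfg.scenario)
    kind = sc.pop("kind", "batch")
    initial = sc.pop("initial", {}) or {}
    pulses = sc.pop("pulses", []) or []
    base = make_batch(S1_0=sc.get("s1_0", 1.0), S2_0=sc.get("s2_0", 1.0),
                      B_0=sc.get("b_0", 0.01), t_end=sc.get("t_end", 50.0))
    base.initial.update({k.lower(): v for k, v in initial.items()})
    if kind == "batch":
        base.pulses = [(t, inc) for t, inc in pulses]
        return base
    if kind == "pulse":
        return make_pulse(spec, base, pulse_size=sc.get("pulse_size", 1.0),
                          doublings=sc.get("doublings", 2.0))
    if kind == "preculture":
        return make_preculture(spec, E2_high=sc.get("e2_high", 1.0),
                               base_scenario=base)
    raise ConfigurationError(f"unknown scenario kind {kind!r}")


# ---------------------------------------------------------------------------
# trajectory CSV
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("t", "s1", "s2", "b")


def write_trajectory(traj: Trajectory, path) -> None:
    """CSV with header, fixed column order, full float precision."""
    data = {"t": traj.t}
    data.update(traj.states)
    for k, v in traj.rates.items():
        data[k] = np.broadcast_to(v, traj.t.shape)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    frame = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"trajectory file misses column(s) {missing}")
    state_cols = [c for c in frame.columns
                  if c in ("s1", "s2", "b", "x1", "x2", "m", "bp",
                           "e1", "e2", "e1p")]
    rate_cols = [c for c in frame.columns
                 if c.startswith("r_") or c in ("mu", "f1", "f2")]
    t = frame["t"].to_numpy()
    states = {c: frame[c].to_numpy() for c in state_cols}
    rates = {c: frame[c].to_numpy() for c in rate_cols}
    return Trajectory(t=t, states=states, rates=rates,
                      meta={"initial": {k: (v[0] if len(v) else 0.0)
                                        for k, v in states.items()},
                            "core": {}})


# ---------------------------------------------------------------------------
# seeds and provenance
# ---------------------------------------------------------------------------

def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derivation from a single global seed."""
    key = zlib.crc32(stage.encode()) & 0xffff
    return int(np.random.SeedSequence(entropy=int(global_seed),
                                      spawn_key=(key,)).generate_state(1)[0]
               % (2 ** 31 - 1))


def write_run_log(cfg: RunConfig, path) -> None:
    """Provenance log sufficient to replay a CLI run."""
    import scipy

    from . import __version__

    log = {"config_digest": cfg.digest(), "seed": cfg.seed,
           "config": asdict(cfg),
           "versions": {"diauxie": __version__, "numpy": np.__version__,
                        "scipy": scipy.__version__}}
    Path(path).write_text(json.dumps(log, indent=2, default=str))
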