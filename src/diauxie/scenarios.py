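"""Experimental designs and the synthetic-observation generator.

Three designs mirror classic diauxie experiments with E. coli on glucose
(S1) and lactose (S2):

* ``make_batch`` — the reference two-substrate batch culture;
* ``make_pulse`` — a glucose pulse applied during exponential growth on
  lactose, with the pulse time adapted to each model's growth rate (the
  pulse is placed after a fixed number of biomass doublings on
  lactose-only medium, so slower-growing models are pulsed later);
* ``make_preculture`` — a lactose preculture followed by a mixed main
  culture, represented as a high initial concentration of the
  lactose-pathway enzyme E2 (a LacZ stand-in).

``synthetic_observations`` samples noisy pseudo-data (substrates, biomass
and a rate-based E2 activity proxy) from simulated trajectories; it stands
in for experimental time-courses in all fitting and discrimination tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (ConfigurationError, ModelSpec, Scenario, SolverSettings,
                   Trajectory, simulate)

__all__ = ["ScenarioInfeasibleError", "ObservationSet", "make_batch",
           "make_pulse", "make_preculture", "synthetic_observations",
           "CHANNELS"]


class ScenarioInfeasibleError(RuntimeError):
    """The requested experimental design cannot be realised for this model."""


#: observation channels -> how they are read off a trajectory
CHANNELS = ("S1", "S2", "B", "E2_activity")


def _channel_series(traj: Trajectory, channel: str) -> np.ndarray:
    key = channel.lower()
    if key in traj.states:
        return traj.states[key]
    if channel == "E2_activity":
        k_s2 = traj.meta.get("core", {}).get("k_s2", 1.0)
        return k_s2 * traj.states["e2"]
    raise ConfigurationError(f"unknown observation channel {channel!r}")


@dataclass
class ObservationSet:
    """Noisy samples of observable channels; deterministic given the seed."""

    t_obs: np.ndarray
    y_obs: dict
    noise_sd: float
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def channels(self):
        return tuple(self.y_obs)

    def to_frame(self):
        import pandas as pd

        rows = []
        for ch, y in self.y_obs.items():
            for t, v in zip(self.t_obs, y):
                rows.append({"t": t, "channel": ch, "value": v})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame, noise_sd=0.0, seed=0):
        t_obs = np.unique(frame["t"].to_numpy())
        y_obs = {}
        for ch, sub in frame.groupby("channel"):
            sub = sub.sort_values("t")
            y_obs[ch] = sub["value"].to_numpy()
        return cls(t_obs=t_obs, y_obs=y_obs, noise_sd=noise_sd, seed=seed)


def make_batch(S1_0: float = 1.0, S2_0: float = 1.0, B_0: float = 0.01,
               t_end: float = 50.0, **initial_extra) -> Scenario:
    """Standard two-substrate batch scenario (rescaled units)."""
    if min(S1_0, S2_0, B_0) < 0:
        raise ConfigurationError("initial concentrations must be >= 0")
    initial = {"s1": S1_0, "s2": S2_0, "b": B_0}
    initial.update({k.lower(): v for k, v in initial_extra.items()})
    return Scenario(initial=initial, t_end=t_end, kind="batch")


def make_pulse(spec: ModelSpec, base_scenario: Scenario = None,
               pulse_size: float = 1.0, doublings: float = 2.0,
               settings: SolverSettings = None, probe_t_end: float = 150.0,
               post_window: float = 30.0) -> Scenario:
    """Growth-rate-adapted glucose pulse during growth on lactose.

    A probe simulation on S2-only medium locates the time at which the
    biomass has completed ``doublings`` doublings; the pulse of S1 is
    applied there.  Models growing more slowly on lactose are therefore
    pulsed proportionally later.
    """
    base = base_scenario or make_batch()
    b0 = base.initial.get("b", 0.01)
    probe_init = dict(base.initial, s1=0.0)
    probe = simulate(spec, Scenario(initial=probe_init, t_end=probe_t_end,
                                    kind="probe"),
                     settings or SolverSettings(rtol=1e-6, atol=1e-9, n_out=1501))
    target = b0 * 2.0 ** doublings
    b = probe.states["b"]
    above = np.nonzero(b >= target)[0]
    if len(above) == 0:
        raise ScenarioInfeasibleError(
            f"{spec.variant_id}: no growth on S2 alone; pulse cannot be timed")
    i = above[0]
    if i == 0:
        t_p = probe.t[0]
    else:
        # linear interpolation of the crossing time
        t0, t1 = probe.t[i - 1], probe.t[i]
        f = (target - b[i - 1]) / (b[i] - b[i - 1])
        t_p = t0 + f * (t1 - t0)
    t_p = float(t_p)
    pulses = [(t_p, {"s1": pulse_size})] if pulse_size != 0 else []
    return Scenario(initial=probe_init, pulses=pulses,
                    t_end=t_p + post_window, kind="pulse",
                    meta={"t_pulse": t_p, "pulse_size": pulse_size})


def make_preculture(spec: ModelSpec, E2_high: float = 1.0,
                    base_scenario: Scenario = None) -> Scenario:
    """Mixed-substrate batch started with abundant lactose enzyme E2."""
    if spec.variant_id == "N2":
        raise ConfigurationError(
            "N2 imposes an initial condition conflicting with the conditions "
            "of the experiment (its asymmetry is the initial enzyme level)")
    base = base_scenario or make_batch()
    initial = dict(base.initial, e2=E2_high)
    return Scenario(initial=initial, t_end=base.t_end, kind="preculture",
                    meta={"E2_high": E2_high})


def synthetic_observations(traj: Trajectory, channels=CHANNELS, t_obs=None,
                           noise_sd: float = 0.05, seed: int = 0) -> ObservationSet:
    """Pseudo-data: interpolated channels plus truncated Gaussian noise.

    The noise standard deviation is ``noise_sd`` times the dynamic range of
    each channel, and values are truncated at zero (concentrations cannot
    be negative).
    """
    if t_obs is None:
        t_obs = np.linspace(traj.t[0], traj.t[-1], 50)
    t_obs = np.asarray(t_obs, dtype=float)
    if t_obs.min() < traj.t[0] - 1e-12 or t_obs.max() > traj.t[-1] + 1e-12:
        raise ConfigurationError("t_obs outside the trajectory support")
    rng = np.random.default_rng(seed)
    y_obs = {}
    for ch in channels:
        series = _channel_series(traj, ch)
        clean = np.interp(t_obs, traj.t, series)
        scale = noise_sd * (series.max() - series.min() or 1.0)
        y_obs[ch] = np.maximum(clean + rng.normal(0.0, scale, size=clean.shape)
                               if noise_sd > 0 else clean, 0.0)
    return ObservationSet(t_obs=t_obs, y_obs=y_obs, noise_sd=noise_sd,
                          seed=seed, meta={"variant": traj.meta.get("variant")})
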