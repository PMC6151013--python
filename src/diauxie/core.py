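"""Core reaction scheme shared by every model variant in the ensemble.

The network couples two extracellular substrates ``S1``, ``S2`` and total
biomass ``B`` to four intracellular pools: the substrate-derived metabolites
``X1``, ``X2``, a central metabolite ``M`` (a stand-in for PEP / FBP-like
flux messengers), and the main biomass component ``B'`` (protein, RNA, ...).
Uptake is catalysed by enzymes ``E1``, ``E2``.  Mass balances::

    dS_i/dt = -r_si * w_i * B          dX_i/dt = r_si - r_di
    dB /dt  =  mu * B                  dM /dt  = r_d1 + r_d2 - r_b
    dE_i/dt =  r_ei - mu * E_i         dB'/dt  = r_b - mu * B'

with Michaelis-Menten uptake ``r_si = k_si E_i S_i/(K_i+S_i)``, linear
consumption ``r_di = k_xi X_i``, biomass synthesis ``r_b = k_m M``,
enzyme synthesis ``r_ei = k_i f_i`` and growth rate
``mu = Y1 r_s1 + Y2 r_s2``.  Growth dilution is neglected for the fast
metabolites ``X_i`` and ``M``'s pool is drained only by ``r_b`` (plus
variant-specific terms).

Model variants plug into this scheme through :class:`Hooks` (multiplicative
regulation factors) and, for the structurally different resource-allocation
variants, through the ``structure`` tag of :class:`ModelSpec`.

All rate computations broadcast over trailing sample axes, so the same code
serves single trajectories and vectorised populations of parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve


class InvalidStateError(ValueError):
    """A state vector contains a concentration below -tolerance."""


class ConfigurationError(ValueError):
    """Unknown variant id or malformed configuration."""


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the last time that integrated cleanly."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class QSSInfeasibleError(RuntimeError):
    """No non-negative quasi-steady state exists for the fast subsystem."""


# ---------------------------------------------------------------------------
# parameters and state bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class CoreParameters:
    """Kinetic constants of the shared scheme.

    Units refer to the unscaled model: ``k_si`` (1/h per enzyme unit),
    ``K_i`` (g/l), ``k_i`` (mol/gDW/h), ``k_xi``, ``k_m`` (1/h),
    ``Y_i`` (gDW/mol), ``w_i`` (g/mol).  In the rescaled regime every field
    defaults to 1 so that only ratio parameters remain.
    """

    k_s1: float = 1.0
    k_s2: float = 1.0
    K1: float = 1.0
    K2: float = 1.0
    k1: float = 1.0
    k2: float = 1.0
    k_x1: float = 1.0
    k_x2: float = 1.0
    k_m: float = 1.0
    Y1: float = 1.0
    Y2: float = 1.0
    w1: float = 1.0
    w2: float = 1.0

    def validate(self) -> None:
        for name, value in self.__dict__.items():
            if np.any(np.asarray(value) <= 0):
                raise ConfigurationError(f"core parameter {name} must be > 0")

    def copy(self, **overrides) -> "CoreParameters":
        return replace(self, **overrides)


KINETIC_STATES = ("s1", "s2", "b", "x1", "x2", "m", "bp", "e1", "e2")
A5_STATES = KINETIC_STATES + ("e1p",)
A1_STATES = ("s1", "s2", "b", "x1", "x2", "m", "bp")
DFBA_STATES = ("s1", "s2", "b", "e1", "e2")

#: default initial conditions in the rescaled regime; variants override
#: selected entries (e.g. an initial energy pool for the PTS variant).
DEFAULT_INITIAL = {
    "s1": 1.0, "s2": 1.0, "b": 0.01,
    "x1": 0.0, "x2": 0.0, "m": 0.0, "bp": 0.0,
    "e1": 0.01, "e2": 0.01, "e1p": 0.0,
}


class SV(NamedTuple):
    """View on the model state; fields are scalars or aligned arrays."""

    s1: np.ndarray
    s2: np.ndarray
    b: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    m: np.ndarray
    bp: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    e1p: Optional[np.ndarray] = None


class Rates(NamedTuple):
    """Reaction rates and regulation factors at one (or many) states."""

    r_s1: np.ndarray
    r_s2: np.ndarray
    r_d1: np.ndarray
    r_d2: np.ndarray
    r_b: np.ndarray
    r_e1: np.ndarray
    r_e2: np.ndarray
    mu: np.ndarray
    f1: np.ndarray
    f2: np.ndarray


@dataclass
class Hooks:
    """Multiplicative regulation hooks installed by the variants.

    ``uptake*`` and ``consume*`` receive ``(sv, vp)`` and return a factor in
    [0, 1]; ``f1``/``f2`` receive ``(sv, vp, r_s1, r_s2)`` and return the
    enzyme-synthesis regulation factor.  ``None`` means the factor is 1.
    """

    uptake1: Optional[Callable] = None
    uptake2: Optional[Callable] = None
    consume1: Optional[Callable] = None
    consume2: Optional[Callable] = None
    f1: Optional[Callable] = None
    f2: Optional[Callable] = None


@dataclass
class ModelSpec:
    """One member of the ensemble: structure + hooks + parameters."""

    variant_id: str
    group: int
    kind: str = "kinetic"            # "kinetic" or "dfba"
    structure: str = "kinetic"       # kinetic | a1 | a2 | a4 | a5 | a6 | base | C1..C4
    core: CoreParameters = field(default_factory=CoreParameters)
    variant_params: dict = field(default_factory=dict)
    hooks: Hooks = field(default_factory=Hooks)
    state_names: tuple = KINETIC_STATES
    initial_overrides: dict = field(default_factory=dict)
    free_params: tuple = ()
    param_boxes: dict = field(default_factory=dict)   # per-parameter search boxes
    description: str = ""
    enzyme_supplier: Optional[Callable] = None   # A1: (t, cols, p, vp) -> (e1, e2)

    @property
    def n_states(self) -> int:
        return len(self.state_names)


@dataclass
class Scenario:
    """Initial conditions, pulse events and integration horizon."""

    initial: dict = field(default_factory=dict)
    pulses: list = field(default_factory=list)   # [(time, {state: increment})]
    t_end: float = 50.0
    kind: str = "batch"
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.t_end <= 0:
            raise ConfigurationError("t_end must be > 0")
        for value in self.initial.values():
            if value < 0:
                raise ConfigurationError("initial concentrations must be >= 0")
        for t_p, _ in self.pulses:
            if not 0 <= t_p <= self.t_end:
                raise ConfigurationError("pulse time outside [0, t_end]")


@dataclass
class SolverSettings:
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    n_out: int = 2001
    dfba_dt: float = 0.01
    dfba_scheme: str = "rk4"         # "rk4" | "heun"


@dataclass
class Trajectory:
    """Time grid with state and rate histories; the universal exchange object."""

    t: np.ndarray
    states: dict
    rates: dict
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def state(self, name: str) -> np.ndarray:
        return self.states[name]

    def to_frame(self):
        import pandas as pd

        data = {"t": self.t}
        data.update({k: v for k, v in self.states.items()})
        data.update({f"r_{k}" if not k.startswith(("r_", "mu", "f")) else k: v
                     for k, v in self.rates.items()})
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def _pos(x):
    return np.maximum(x, 0.0)


def variant_rates(t, sv: SV, spec: ModelSpec, p: CoreParameters = None,
                  vp: dict = None, control: Optional[Callable] = None) -> Rates:
    """All reaction rates of ``spec`` at state ``sv`` (vectorised).

    ``control`` supplies the allocation fractions ``(u1(t), u2(t))`` for the
    optimal-control structures a2/a6 and is ignored otherwise.
    """
    p = spec.core if p is None else p
    vp = spec.variant_params if vp is None else vp
    hooks = spec.hooks

    s1, s2 = _pos(sv.s1), _pos(sv.s2)
    x1, x2, m, bp = _pos(sv.x1), _pos(sv.x2), _pos(sv.m), _pos(sv.bp)
    e1, e2 = _pos(sv.e1), _pos(sv.e2)
    svc = sv._replace(s1=s1, s2=s2, x1=x1, x2=x2, m=m, bp=bp, e1=e1, e2=e2)

    sig1 = s1 / (p.K1 + s1)
    sig2 = s2 / (p.K2 + s2)
    g1 = hooks.uptake1(svc, vp) if hooks.uptake1 else 1.0
    g2 = hooks.uptake2(svc, vp) if hooks.uptake2 else 1.0
    if spec.structure == "a5":
        e1p = _pos(sv.e1p)
        r_s1 = p.k_s1 * e1p * sig1 * g1
    else:
        r_s1 = p.k_s1 * e1 * sig1 * g1
    r_s2 = p.k_s2 * e2 * sig2 * g2

    c1 = hooks.consume1(svc, vp) if hooks.consume1 else 1.0
    c2 = hooks.consume2(svc, vp) if hooks.consume2 else 1.0
    r_d1 = p.k_x1 * x1 * c1
    r_d2 = p.k_x2 * x2 * c2
    r_b = p.k_m * m

    if spec.structure in ("a2", "a6"):
        if control is None:
            u1 = u2 = np.broadcast_to(0.5, np.shape(r_s1))
        else:
            u1, u2 = control(t)
        u_max = vp.get("u_max", 1.0)
        r_e1 = u1 * u_max * bp
        r_e2 = u2 * u_max * bp
        # total biomass grows with everything taken up (the drain moves
        # mass from B' to enzymes, both of which are biomass)
        mu = p.Y1 * r_s1 + p.Y2 * r_s2
        f1, f2 = u1, u2
    else:
        f1 = hooks.f1(svc, vp, r_s1, r_s2) if hooks.f1 else np.ones(np.shape(r_s1))
        f2 = hooks.f2(svc, vp, r_s1, r_s2) if hooks.f2 else np.ones(np.shape(r_s1))
        if spec.structure == "a1":
            r_e1 = np.zeros(np.shape(r_s1))
            r_e2 = np.zeros(np.shape(r_s1))
        else:
            r_e1 = p.k1 * f1
            r_e2 = p.k2 * f2
        mu = p.Y1 * r_s1 + p.Y2 * r_s2

    return Rates(r_s1, r_s2, r_d1, r_d2, r_b, r_e1, r_e2, mu, f1, f2)


def reaction_rates(state: SV, p: CoreParameters, hooks: Hooks = None,
                   vp: dict = None, tol: float = 1e-6) -> Rates:
    """Kinetic rate laws of the shared scheme with optional regulation hooks.

    Raises :class:`InvalidStateError` if any concentration is below ``-tol``.
    """
    arrs = [a for a in state if a is not None]
    if min(np.min(np.asarray(a)) for a in arrs) < -tol:
        raise InvalidStateError("negative concentration beyond tolerance")
    spec = ModelSpec("base", 0, hooks=hooks or Hooks(), core=p,
                     variant_params=vp or {})
    return variant_rates(0.0, state, spec)


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def build_rhs(spec: ModelSpec, p: CoreParameters = None, vp: dict = None,
              control: Optional[Callable] = None) -> Callable:
    """Return ``rhs(t, Y)`` operating on ``Y`` of shape (n_samples, n_states)."""
    p = spec.core if p is None else p
    vp = dict(spec.variant_params if vp is None else vp)
    names = spec.state_names
    index = {nm: i for i, nm in enumerate(names)}
    structure = spec.structure
    supplier = spec.enzyme_supplier

    def rhs(t, Y):
        cols = {nm: Y[:, i] for nm, i in index.items()}
        zeros = np.zeros(Y.shape[0])
        if supplier is not None:
            e1, e2 = supplier(t, cols, p, vp)
            cols = dict(cols, e1=e1, e2=e2)
        sv = SV(cols["s1"], cols["s2"], cols["b"], cols.get("x1", zeros),
                cols.get("x2", zeros), cols.get("m", zeros),
                cols.get("bp", zeros), cols.get("e1", zeros),
                cols.get("e2", zeros), cols.get("e1p"))
        r = variant_rates(t, sv, spec, p, vp, control)
        d = {
            "s1": -r.r_s1 * p.w1 * sv.b,
            "s2": -r.r_s2 * p.w2 * sv.b,
            "b": r.mu * sv.b,
            "x1": r.r_s1 - r.r_d1,
            "x2": r.r_s2 - r.r_d2,
        }
        if structure == "a4":
            d["m"] = 2.0 * (r.r_d1 + r.r_d2) - r.r_b - r.r_s1 - r.r_s2
        elif structure == "a5":
            r_p = vp["k_p"] * _pos(sv.m) * _pos(sv.e1)
            d["m"] = 2.0 * r.r_d1 + r.r_d2 - r.r_b - r_p
        else:
            d["m"] = r.r_d1 + r.r_d2 - r.r_b
        if structure in ("a2", "a6"):
            u_max = vp.get("u_max", 1.0)
            d["bp"] = r.r_b - u_max * _pos(sv.bp) - r.mu * sv.bp
        else:
            d["bp"] = r.r_b - r.mu * sv.bp
        if "e1" in index:
            d["e1"] = r.r_e1 - r.mu * sv.e1
            d["e2"] = r.r_e2 - r.mu * sv.e2
            if structure == "a5":
                r_p = vp["k_p"] * _pos(sv.m) * _pos(sv.e1)
                d["e1"] = d["e1"] - r_p + r.r_s1
                d["e1p"] = r_p - r.r_s1 - r.mu * sv.e1p
        return np.stack([d[nm] for nm in names], axis=1)

    return rhs


def ode_rhs(t: float, state: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Time derivative of a kinetic variant's state vector (spec'd layout)."""
    if spec.kind != "kinetic":
        raise ConfigurationError(
            f"variant {spec.variant_id} is constraint-based; use dfba.simulate_dfba")
    rhs = build_rhs(spec)
    return rhs(t, np.asarray(state, dtype=float)[None, :])[0]


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

def initial_state(spec: ModelSpec, scen: Scenario) -> np.ndarray:
    init = dict(DEFAULT_INITIAL)
    init.update(spec.initial_overrides)
    init.update({k.lower(): v for k, v in scen.initial.items()})
    unknown = set(k.lower() for k in scen.initial) - set(DEFAULT_INITIAL)
    if unknown:
        raise ConfigurationError(f"unknown initial-state keys: {sorted(unknown)}")
    return np.array([init[nm] for nm in spec.state_names], dtype=float)


def record_rates(spec: ModelSpec, t: np.ndarray, Y: np.ndarray,
                 p: CoreParameters = None, vp: dict = None,
                 control: Optional[Callable] = None) -> dict:
    """Recompute the rate histories along a stored trajectory."""
    p = spec.core if p is None else p
    vp = spec.variant_params if vp is None else vp
    index = {nm: i for i, nm in enumerate(spec.state_names)}
    cols = {nm: Y[:, i] for nm, i in index.items()}
    zeros = np.zeros(len(t))
    if spec.enzyme_supplier is not None:
        e1, e2 = spec.enzyme_supplier(t, cols, p, vp)
        cols = dict(cols, e1=e1, e2=e2)
    sv = SV(cols["s1"], cols["s2"], cols["b"], cols.get("x1", zeros),
            cols.get("x2", zeros), cols.get("m", zeros), cols.get("bp", zeros),
            cols.get("e1", zeros), cols.get("e2", zeros), cols.get("e1p"))
    r = variant_rates(t, sv, spec, p, vp, control)
    out = dict(zip(Rates._fields, r))
    if spec.enzyme_supplier is not None:
        out["e1_alloc"] = cols["e1"]
        out["e2_alloc"] = cols["e2"]
    return out


def simulate(spec: ModelSpec, scen: Scenario,
             settings: SolverSettings = None,
             control: Optional[Callable] = None) -> Trajectory:
    """Integrate ``spec`` under ``scen``; pulses are stop-and-restart events."""
    if spec.kind == "dfba":
        from . import dfba

        return dfba.simulate_dfba(spec, scen, settings)
    settings = settings or SolverSettings()
    scen.validate()
    y0 = initial_state(spec, scen)
    rhs = build_rhs(spec, control=control)

    def rhs_flat(t, y):
        return rhs(t, y[None, :])[0]

    t_grid = np.linspace(0.0, scen.t_end, settings.n_out)
    pulses = sorted(scen.pulses, key=lambda e: e[0])
    breakpoints = [0.0] + [t for t, _ in pulses if 0.0 < t < scen.t_end] + [scen.t_end]

    ts, ys, events = [], [], []
    y = y0.copy()
    idx = {nm: i for i, nm in enumerate(spec.state_names)}
    pulse_iter = iter(pulses)
    next_pulse = next(pulse_iter, None)
    for a, b_ in zip(breakpoints[:-1], breakpoints[1:]):
        seg_eval = t_grid[(t_grid >= a) & (t_grid <= b_)]
        seg_eval = np.unique(np.concatenate([[a], seg_eval, [b_]]))
        sol = solve_ivp(rhs_flat, (a, b_), y, method=settings.method,
                        rtol=settings.rtol, atol=settings.atol, t_eval=seg_eval)
        if not sol.success:
            raise IntegrationError(sol.message, last_valid_time=sol.t[-1] if len(sol.t) else a)
        ts.append(sol.t)
        ys.append(sol.y.T)
        y = sol.y[:, -1].copy()
        while next_pulse is not None and abs(next_pulse[0] - b_) < 1e-12:
            for key, inc in next_pulse[1].items():
                y[idx[key.lower()]] += inc
            events.append((b_, f"pulse {next_pulse[1]}"))
            next_pulse = next(pulse_iter, None)

    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=0)
    # drop duplicate segment-boundary points; at a pulse time the later
    # (post-pulse) row wins so the stored state jumps by the increment
    last = {}
    for i, tv in enumerate(t):
        last[tv] = i
    sel = sorted(last.values())
    t, Y = t[sel], Y[sel]

    Y = np.where(np.abs(Y) < settings.atol * 10, np.maximum(Y, 0.0), Y)
    states = {nm: Y[:, i] for nm, i in idx.items()}
    rates = record_rates(spec, t, Y, control=control)
    if "e1_alloc" in rates:
        states = dict(states, e1=rates.pop("e1_alloc"), e2=rates.pop("e2_alloc"))
    meta = {"variant": spec.variant_id, "scenario": scen.kind,
            "initial": dict(DEFAULT_INITIAL, **spec.initial_overrides,
                            **{k.lower(): v for k, v in scen.initial.items()}),
            "core": dict(spec.core.__dict__), "variant_params": dict(spec.variant_params)}
    return Trajectory(t=t, states=states, rates=rates, events=events, meta=meta)


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingReport:
    """Multiplicative factors mapping original to dimensionless variables.

    ``scaled = original * state_scale[name]``; ``tau = time_scale * t``.
    """

    state_scale: dict
    time_scale: float
    ratios: dict


def rescale(p: CoreParameters, time_scale: float = 1.0):
    """Reduce ``p`` to the dimensionless ratio parameterisation.

    Substrates are scaled on their Michaelis constants (``s_i = S_i/K_i``),
    biomass on ``K1``, the first-substrate yield ``Y1`` and molecular weight
    ``w1`` (``b = B w1/(K1 Y1)``), and all intracellular states by ``Y1``.
    Returns the rescaled :class:`CoreParameters` and a :class:`ScalingReport`;
    simulating the rescaled system and unscaling reproduces the original
    trajectory (the round-trip identity).
    """
    p.validate()
    lam = time_scale
    if lam == 0:
        raise ConfigurationError("time_scale must be nonzero")
    scaled = CoreParameters(
        k_s1=p.k_s1 / lam, k_s2=p.k_s2 / lam,
        K1=1.0, K2=1.0,
        k1=p.Y1 * p.k1 / lam, k2=p.Y1 * p.k2 / lam,
        k_x1=p.k_x1 / lam, k_x2=p.k_x2 / lam, k_m=p.k_m / lam,
        Y1=1.0, Y2=p.Y2 / p.Y1,
        w1=1.0, w2=(p.w2 / p.w1) * (p.K1 / p.K2),
    )
    intra = p.Y1
    state_scale = {"s1": 1.0 / p.K1, "s2": 1.0 / p.K2,
                   "b": p.w1 / (p.K1 * p.Y1),
                   "x1": intra, "x2": intra, "m": intra, "bp": intra,
                   "e1": intra, "e2": intra, "e1p": intra}
    ratios = {"yield_ratio": p.Y2 / p.Y1,
              "uptake_ratio": p.k_s2 / p.k_s1,
              "weight_ratio": (p.w2 / p.w1) * (p.K1 / p.K2)}
    return scaled, ScalingReport(state_scale, lam, ratios)


def rescale_scenario(scen: Scenario, report: ScalingReport) -> Scenario:
    sc = report.state_scale
    initial = {k: v * sc[k.lower()] for k, v in scen.initial.items()}
    pulses = [(t * report.time_scale,
               {k: v * sc[k.lower()] for k, v in inc.items()})
              for t, inc in scen.pulses]
    return Scenario(initial=initial, pulses=pulses,
                    t_end=scen.t_end * report.time_scale, kind=scen.kind)


def unscale_trajectory(traj: Trajectory, report: ScalingReport) -> Trajectory:
    states = {k: v / report.state_scale[k] for k, v in traj.states.items()}
    return Trajectory(t=traj.t / report.time_scale, states=states,
                      rates=dict(traj.rates), events=list(traj.events),
                      meta=dict(traj.meta))


# ---------------------------------------------------------------------------
# quasi-steady state of the fast subsystem (X1, X2, M)
# ---------------------------------------------------------------------------

def qss_solve(slow: dict, p: CoreParameters, spec: ModelSpec = None):
    """Solve ``r_si = r_di`` and ``r_d1 + r_d2 = r_b`` for (X1, X2, M).

    ``slow`` provides s1, s2, e1, e2 (and optionally b).  For the base scheme
    the solution is closed-form; hooked variants are solved numerically and
    all distinct non-negative roots are returned (list of 3-tuples).
    """
    if p.k_x1 <= 0 or p.k_x2 <= 0 or p.k_m <= 0:
        raise ConfigurationError("consumption constants must be > 0")
    spec = spec or ModelSpec("base", 0, core=p)
    b = slow.get("b", 0.01)

    def make_sv(x1, x2, m):
        return SV(np.asarray(slow["s1"], float), np.asarray(slow["s2"], float),
                  np.asarray(b, float), np.asarray(x1, float),
                  np.asarray(x2, float), np.asarray(m, float),
                  np.asarray(slow.get("bp", 0.0), float),
                  np.asarray(slow["e1"], float), np.asarray(slow["e2"], float),
                  np.asarray(slow.get("e1p", 0.0), float))

    hooked = any(getattr(spec.hooks, h) for h in
                 ("uptake1", "uptake2", "consume1", "consume2")) or \
        spec.structure not in ("kinetic", "a1")
    if not hooked:
        r = variant_rates(0.0, make_sv(0, 0, 0), spec, p)
        x1 = r.r_s1 / p.k_x1
        x2 = r.r_s2 / p.k_x2
        m = (r.r_s1 + r.r_s2) / p.k_m
        return [(float(x1), float(x2), float(m))]

    def residual(z):
        x1, x2, m = z
        r = variant_rates(0.0, make_sv(x1, x2, m), spec, p)
        return [float(r.r_s1 - r.r_d1), float(r.r_s2 - r.r_d2),
                float(r.r_d1 + r.r_d2 - r.r_b)]

    starts = [(0.1, 0.1, 0.1)]
    base = variant_rates(0.0, make_sv(0, 0, 0), spec, p)
    starts.append((float(base.r_s1 / p.k_x1) + 1e-6,
                   float(base.r_s2 / p.k_x2) + 1e-6,
                   float((base.r_s1 + base.r_s2) / p.k_m) + 1e-6))
    for scale in (0.01, 1.0, 10.0):
        starts.append((scale, scale, scale))
    roots = []
    for z0 in starts:
        z, info, ier, _ = fsolve(residual, z0, full_output=True)
        if ier != 1:
            continue
        if np.min(z) < -1e-9:
            continue
        z = np.maximum(z, 0.0)
        if not any(np.allclose(z, r0, atol=1e-7) for r0 in roots):
            if np.max(np.abs(residual(z))) < 1e-8:
                roots.append(tuple(float(v) for v in z))
    if not roots:
        raise QSSInfeasibleError("no non-negative quasi-steady state found")
    return roots
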