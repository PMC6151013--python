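"""Dynamic flux balance analysis: the constraint-based variants C1-C4.

At every time step a linear program over the quasi-steady-state fluxes

    max  c^T x    s.t.   N' x = 0,   H x <= h,   lb <= x <= ub

is solved; the optimal biomass-synthesis flux ``r_b`` is the growth rate,
and the slow ODEs (substrates, biomass, enzymes) are advanced with the
optimal fluxes.  For the base system the flux vector is
``x = (E1, r_d1, E2, r_d2, r_b)`` with the enzymes pinned to their ODE
values, so the equalities determine the solution completely; the variants
add degrees of freedom (C1: by-product excretion and an inefficient biomass
route; C3: enzymes as decision variables under a membrane-space constraint;
C4: enzyme-synthesis rates under a cost-benefit budget) or a Boolean
regulatory mask (C2).

``solve_flux_lp`` is the general solver; the stepping loop uses closed-form
solutions of the same programs (``structured_fluxes``), which is what makes
ensemble-scale calibration affordable.  The two routes are cross-checked in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linprog, minimize

from .core import (ConfigurationError, CoreParameters, IntegrationError,
                   ModelSpec, Scenario, SolverSettings, Trajectory,
                   DEFAULT_INITIAL)

__all__ = ["saturation", "ConstraintSystem", "FluxSolution",
           "assemble_system", "solve_flux_lp", "structured_fluxes",
           "simulate_dfba", "variant_C2_rules", "variant_C3_crowding",
           "variant_C4_cost_benefit", "base_stoichiometric_matrix"]


def saturation(S, k_s, K):
    """Saturated per-enzyme uptake capacity ``h(S) = k_s S/(K+S)``."""
    if np.any(np.asarray(K) <= 0):
        raise ConfigurationError("K must be > 0")
    Sp = np.maximum(S, 0.0)
    return k_s * Sp / (K + Sp)


def base_stoichiometric_matrix():
    """Stoichiometric matrix N: rows X1, X2, M; columns r_s1, r_d1, r_s2, r_d2, r_b."""
    return np.array([[1.0, -1.0, 0.0, 0.0, 0.0],
                     [0.0, 0.0, 1.0, -1.0, 0.0],
                     [0.0, 1.0, 0.0, 1.0, -1.0]])


@dataclass
class ConstraintSystem:
    Nprime: np.ndarray
    x_labels: tuple
    H: Optional[np.ndarray]
    h: Optional[np.ndarray]
    lb: np.ndarray
    ub: np.ndarray
    c: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class FluxSolution:
    x: Optional[np.ndarray]
    objective: Optional[float]
    status: str                       # optimal | infeasible | unbounded | error
    active_constraints: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# variant rules / constraint builders
# ---------------------------------------------------------------------------

def variant_C2_rules(S1, threshold=0.01, K1=1.0) -> bool:
    """Boolean regulatory rule: E2 is active iff S1 is *not* available.

    Availability means ``S1 > threshold*K1``; at equality the tie goes to
    repression (E2 inactive).
    """
    return np.asarray(S1) < threshold * K1


def variant_C3_crowding(a1, a2, A_max, n_vars=5):
    """Membrane-space inequality ``a1*E1 + a2*E2 <= A_max`` as an H-row."""
    row = np.zeros(n_vars)
    row[0], row[2] = a1, a2
    return row, float(A_max)


def variant_C4_cost_benefit(cost, benefit, slack, n_vars=7):
    """Cost-benefit row: cost.r_e - benefit.r_d <= slack over the extended x."""
    row = np.zeros(n_vars)
    row[1], row[3] = -benefit[0], -benefit[1]
    row[5], row[6] = cost[0], cost[1]
    return row, float(slack)


def assemble_system(state: dict, p: CoreParameters, variant: str = "base",
                    vp: dict = None) -> ConstraintSystem:
    """Build the flux LP of ``variant`` at the current slow state.

    ``state`` supplies s1, s2 and the ODE enzyme levels e1, e2.
    """
    vp = vp or {}
    s1, s2 = state["s1"], state["s2"]
    e1, e2 = state["e1"], state["e2"]
    h1 = float(saturation(s1, p.k_s1, p.K1))
    h2 = float(saturation(s2, p.k_s2, p.K2))
    INF = np.inf

    if variant in ("base", "C2", "C3", "C4"):
        N = np.array([[h1, -1.0, 0.0, 0.0, 0.0],
                      [0.0, 0.0, h2, -1.0, 0.0],
                      [0.0, 1.0, 0.0, 1.0, -1.0]])
        labels = ("E1", "r_d1", "E2", "r_d2", "r_b")
        lb = np.array([e1, 0.0, e2, 0.0, 0.0])
        ub = np.array([e1, INF, e2, INF, INF])
        c = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        H = h = None
        if variant == "C2":
            if not bool(variant_C2_rules(s1, vp.get("s1_threshold", 0.01), p.K1)):
                lb[2] = ub[2] = 0.0
        elif variant == "C3":
            lb[0] = lb[2] = 0.0          # enzymes become decision variables
            row, bound = variant_C3_crowding(vp["a1"], vp["a2"], vp["A_max"])
            H, h = row[None, :], np.array([bound])
        elif variant == "C4":
            N = np.hstack([N, np.zeros((3, 2))])
            labels = labels + ("r_e1", "r_e2")
            lb = np.concatenate([lb, [0.0, 0.0]])
            ub = np.concatenate([ub, [p.k1, p.k2]])
            c = np.concatenate([c, [1e-3, 1e-3]])
            row, bound = variant_C4_cost_benefit(
                (vp["cost1"], vp["cost2"]),
                (vp.get("benefit1", 1.0), vp.get("benefit2", 1.0)),
                vp["slack"])
            H, h = row[None, :], np.array([bound])
        return ConstraintSystem(N, labels, H, h, lb, ub, c,
                                meta={"variant": variant, "h1": h1, "h2": h2})

    if variant == "C1":
        # M is central for S1 only; r_b1 (M -> B' + X2) co-produces X2,
        # which is excreted (v_x2 < 0) or converted by the capped r_b2.
        N = np.array([[h1, -1.0, 0.0, 0.0, 0.0],     # X1: uptake - r_d1
                      [0.0, 1.0, 0.0, -1.0, 0.0],    # M:  r_d1 - r_b1
                      [0.0, 0.0, 1.0, 1.0, -1.0]])   # X2: v_x2 + r_b1 - r_b2
        labels = ("E1", "r_d1", "v_x2", "r_b1", "r_b2")
        cap = vp.get("cap_frac", 0.5) * p.k_s1 * e1
        lb = np.array([e1, 0.0, -np.inf, 0.0, 0.0])
        ub = np.array([e1, np.inf, h2 * e2, np.inf, cap])
        c = np.array([0.0, 0.0, 0.0, 1.0, 1.0])
        return ConstraintSystem(N, labels, None, None, lb, ub, c,
                                meta={"variant": "C1", "h1": h1, "h2": h2})

    raise ConfigurationError(f"unknown dFBA variant {variant!r}")


# ---------------------------------------------------------------------------
# LP solver (general path)
# ---------------------------------------------------------------------------

def solve_flux_lp(sys: ConstraintSystem, norm_select: bool = True) -> FluxSolution:
    """Maximise ``c^T x``; among alternate optima return the min-norm one."""
    if np.any(sys.ub < sys.lb):
        return FluxSolution(None, None, "infeasible")
    bounds = list(zip(
        [v if np.isfinite(v) else None for v in sys.lb],
        [v if np.isfinite(v) else None for v in sys.ub]))
    res = linprog(-sys.c, A_ub=sys.H, b_ub=sys.h, A_eq=sys.Nprime,
                  b_eq=np.zeros(sys.Nprime.shape[0]), bounds=bounds,
                  method="highs")
    if res.status == 2:
        return FluxSolution(None, None, "infeasible")
    if res.status == 3:
        return FluxSolution(None, None, "unbounded")
    if res.status != 0:
        return FluxSolution(None, None, "error")
    x, obj = res.x, float(-res.fun)

    if norm_select:
        cons = [{"type": "eq", "fun": lambda z: sys.Nprime @ z},
                {"type": "eq", "fun": lambda z: sys.c @ z - obj}]
        if sys.H is not None:
            cons.append({"type": "ineq", "fun": lambda z: sys.h - sys.H @ z})
        qp = minimize(lambda z: z @ z, x, jac=lambda z: 2 * z,
                      bounds=bounds, constraints=cons, method="SLSQP",
                      options={"maxiter": 80, "ftol": 1e-12})
        if qp.success and np.max(np.abs(sys.Nprime @ qp.x)) < 1e-8 and \
                sys.c @ qp.x > obj - 1e-8:
            x = qp.x

    active = []
    if sys.H is not None:
        for i, (row, bi) in enumerate(zip(sys.H, sys.h)):
            if abs(row @ x - bi) < 1e-8:
                active.append(f"H[{i}]")
    for i, lbl in enumerate(sys.x_labels):
        if np.isfinite(sys.ub[i]) and abs(x[i] - sys.ub[i]) < 1e-9 and \
                sys.ub[i] != sys.lb[i]:
            active.append(f"ub[{lbl}]")
    return FluxSolution(x, float(sys.c @ x), "optimal", active)


# ---------------------------------------------------------------------------
# closed-form solutions of the structured programs (vectorised)
# ---------------------------------------------------------------------------

def structured_fluxes(variant: str, s1, s2, e1, e2, p: CoreParameters, vp: dict):
    """Optimal fluxes of the variant LPs, in closed form, broadcastable.

    Returns a dict with uptake rates (``r_s1``/``r_s2``; ``r_s2`` may be
    negative for C1, meaning excretion), consumption fluxes, growth rate
    ``mu`` (= optimal biomass flux) and enzyme-synthesis rates.
    """
    h1 = saturation(s1, p.k_s1, p.K1)
    h2 = saturation(s2, p.k_s2, p.K2)
    e1 = np.maximum(e1, 0.0)
    e2 = np.maximum(e2, 0.0)
    one = np.ones(np.shape(h1 * e1))
    re1, re2 = p.k1 * one, p.k2 * one

    if variant == "base":
        rd1, rd2 = h1 * e1, h2 * e2
        rb = rd1 + rd2
        out = dict(r_s1=rd1, r_s2=rd2, r_d1=rd1, r_d2=rd2, r_b=rb, mu=rb)
    elif variant == "C2":
        active2 = variant_C2_rules(s1, vp.get("s1_threshold", 0.01), p.K1)
        rd1 = h1 * e1
        rd2 = h2 * e2 * active2
        rb = rd1 + rd2
        out = dict(r_s1=rd1, r_s2=rd2, r_d1=rd1, r_d2=rd2, r_b=rb, mu=rb)
    elif variant == "C3":
        a1, a2, A = vp["a1"], vp["a2"], vp["A_max"]
        prefer1 = (h1 / a1) >= (h2 / a2)
        cap1 = np.minimum(e1, A / a1)
        cap2 = np.minimum(e2, A / a2)
        e1f = np.where(prefer1, cap1, np.minimum(e1, np.maximum(A - a2 * cap2, 0.0) / a1))
        e2f = np.where(prefer1, np.minimum(e2, np.maximum(A - a1 * cap1, 0.0) / a2), cap2)
        rd1, rd2 = h1 * e1f, h2 * e2f
        rb = rd1 + rd2
        out = dict(r_s1=rd1, r_s2=rd2, r_d1=rd1, r_d2=rd2, r_b=rb, mu=rb,
                   e1_eff=e1f, e2_eff=e2f)
    elif variant == "C4":
        rd1, rd2 = h1 * e1, h2 * e2
        rb = rd1 + rd2
        budget = vp["slack"] + vp.get("benefit1", 1.0) * rd1 + \
            vp.get("benefit2", 1.0) * rd2
        c1, c2 = vp["cost1"] * one, vp["cost2"] * one
        k_a = np.where(c1 <= c2, p.k1 * one, p.k2 * one)
        k_b = np.where(c1 <= c2, p.k2 * one, p.k1 * one)
        c_a = np.minimum(c1, c2)
        c_b = np.maximum(c1, c2)
        re_a = np.minimum(k_a, budget / np.maximum(c_a, 1e-300))
        rem = np.maximum(budget - c_a * re_a, 0.0)
        re_b = np.minimum(k_b, rem / np.maximum(c_b, 1e-300))
        re1 = np.where(c1 <= c2, re_a, re_b)
        re2 = np.where(c1 <= c2, re_b, re_a)
        out = dict(r_s1=rd1, r_s2=rd2, r_d1=rd1, r_d2=rd2, r_b=rb, mu=rb)
    elif variant == "C1":
        rb1 = h1 * e1                       # X1 and M balances force this
        cap = vp.get("cap_frac", 0.5) * p.k_s1 * e1
        rb2 = np.minimum(cap, rb1 + h2 * e2)
        vx2 = rb2 - rb1                     # negative = excretion of S2
        rb = rb1 + rb2
        out = dict(r_s1=rb1, r_s2=vx2, r_d1=rb1, r_d2=rb2, r_b=rb, mu=rb,
                   r_b1=rb1, r_b2=rb2)
    else:
        raise ConfigurationError(f"unknown dFBA variant {variant!r}")
    out.setdefault("r_e1", re1)
    out.setdefault("r_e2", re2)
    if variant == "C4":
        out["r_e1"], out["r_e2"] = re1, re2
    out["f1"] = out["r_e1"] / np.maximum(p.k1, 1e-300)
    out["f2"] = out["r_e2"] / np.maximum(p.k2, 1e-300)
    return out


# ---------------------------------------------------------------------------
# dFBA stepping
# ---------------------------------------------------------------------------

def _deriv(variant, y, p, vp):
    s1, s2, b, e1, e2 = y[..., 0], y[..., 1], y[..., 2], y[..., 3], y[..., 4]
    fx = structured_fluxes(variant, s1, s2, e1, e2, p, vp)
    return np.stack([
        -fx["r_s1"] * p.w1 * b,
        -fx["r_s2"] * p.w2 * b,
        fx["mu"] * b,
        fx["r_e1"] - fx["mu"] * e1,
        fx["r_e2"] - fx["mu"] * e2,
    ], axis=-1)


def step_dfba(variant, y, dt, p, vp, scheme="rk4"):
    """Advance the slow state by dt, re-solving the flux program per stage."""
    k1 = _deriv(variant, y, p, vp)
    if scheme == "euler":
        return y + dt * k1
    if scheme == "heun":
        k2 = _deriv(variant, y + dt * k1, p, vp)
        return y + 0.5 * dt * (k1 + k2)
    k2 = _deriv(variant, y + 0.5 * dt * k1, p, vp)
    k3 = _deriv(variant, y + 0.5 * dt * k2, p, vp)
    k4 = _deriv(variant, y + dt * k3, p, vp)
    return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_dfba(spec: ModelSpec, scen: Scenario,
                  settings: SolverSettings = None,
                  p: CoreParameters = None, vp: dict = None) -> Trajectory:
    """Fixed-step dynamic FBA of a group-1 variant under ``scen``."""
    if spec.kind != "dfba":
        raise ConfigurationError(f"{spec.variant_id} is not a dFBA variant")
    settings = settings or SolverSettings()
    scen.validate()
    p = p if p is not None else spec.core
    vp = vp if vp is not None else spec.variant_params
    variant = spec.structure

    init = dict(DEFAULT_INITIAL)
    init.update(spec.initial_overrides)
    init.update({k.lower(): v for k, v in scen.initial.items()})
    y = np.array([init["s1"], init["s2"], init["b"], init["e1"], init["e2"]])

    dt = settings.dfba_dt
    n_steps = int(round(scen.t_end / dt))
    pulse_steps = {}
    events = []
    for t_p, inc in sorted(scen.pulses, key=lambda e: e[0]):
        pulse_steps.setdefault(int(round(t_p / dt)), []).append(inc)

    names = ("s1", "s2", "b", "e1", "e2")
    ts = np.empty(n_steps + 1)
    Y = np.empty((n_steps + 1, 5))
    ts[0], Y[0] = 0.0, y
    for k in range(n_steps):
        if k in pulse_steps:
            for inc in pulse_steps[k]:
                for key, dv in inc.items():
                    y[names.index(key.lower())] += dv
                events.append((k * dt, f"pulse {inc}"))
            Y[k] = y
        y = step_dfba(variant, y, dt, p, vp, settings.dfba_scheme)
        y = np.maximum(y, 0.0)
        if not np.all(np.isfinite(y)):
            raise IntegrationError("dFBA state became non-finite",
                                   last_valid_time=k * dt)
        ts[k + 1] = (k + 1) * dt
        Y[k + 1] = y

    stride = max(1, (n_steps + 1) // settings.n_out)
    sel = np.unique(np.concatenate([np.arange(0, n_steps + 1, stride),
                                    [n_steps]]))
    ts, Y = ts[sel], Y[sel]
    states = {nm: Y[:, i] for i, nm in enumerate(names)}
    fx = structured_fluxes(variant, states["s1"], states["s2"],
                           states["e1"], states["e2"], p, vp)
    rates = {k: np.broadcast_to(v, ts.shape).astype(float)
             for k, v in fx.items()}
    meta = {"variant": spec.variant_id, "scenario": scen.kind,
            "initial": init, "core": dict(p.__dict__),
            "variant_params": dict(vp)}
    return Trajectory(t=ts, states=states, rates=rates, events=events, meta=meta)
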