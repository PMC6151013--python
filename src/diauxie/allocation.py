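"""Resource-allocation variants A1-A6.

Two sub-families:

* kinetic schemes with an allocation rule evaluated pointwise — A1 (static
  enzyme budget from the biomass component B'), A3 (cybernetic matching
  law), A4 (energy-coupled transport), A5 (PTS phosphorelay competition);
* dynamic optimisation schemes — A2 (maximise terminal biomass subject to a
  cap on the central metabolite pool) and A6 (maximise lifespan subject to
  a floor on B'), both solved by control-vector parameterisation:
  piecewise-constant allocation fractions u1(t), u2(t) on a uniform grid,
  path constraints enforced by a quadratic penalty with weight ramping, and
  the resulting nonlinear program solved by SLSQP from several seeded
  starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .core import (ConfigurationError, CoreParameters, ModelSpec, Scenario,
                   SolverSettings, Trajectory, SV, simulate, variant_rates)

__all__ = ["allocate_static_A1", "a1_enzyme_supplier", "cybernetic_u_A3",
           "energy_coupled_rates_A4", "pts_rates_A5", "ControlProfile",
           "OptimalControlResult", "allocate_dynamic_A2",
           "maximize_lifespan_A6"]


# ---------------------------------------------------------------------------
# pointwise allocation rules
# ---------------------------------------------------------------------------

def allocate_static_A1(Bprime, weights, bound_fraction, state: dict,
                       p: CoreParameters):
    """Instantaneous enzyme allocation maximising total uptake flux.

    Solves ``max r_s1 + r_s2`` over ``E1, E2 >= 0`` subject to the budget
    ``g1 E1 + g2 E2 <= bound_fraction * B'``.  The optimum is a corner: the
    whole budget goes to the pathway with the larger per-budget return
    ``k_si sigma_i / g_i`` (ties prefer pathway 1); with no return at all
    nothing is allocated.
    """
    g1, g2 = weights
    if g1 <= 0 or g2 <= 0 or not 0 < bound_fraction < 1:
        raise ConfigurationError("weights must be > 0 and 0 < bound_fraction < 1")
    budget = bound_fraction * max(float(Bprime), 0.0)
    s1 = max(state.get("s1", 0.0), 0.0)
    s2 = max(state.get("s2", 0.0), 0.0)
    v1 = p.k_s1 * s1 / (p.K1 + s1) / g1
    v2 = p.k_s2 * s2 / (p.K2 + s2) / g2
    if budget == 0.0 or (v1 == 0.0 and v2 == 0.0):
        return 0.0, 0.0
    if v1 >= v2:
        return budget / g1, 0.0
    return 0.0, budget / g2


def a1_enzyme_supplier(t, cols, p: CoreParameters, vp: dict):
    """Vectorised A1 allocation used inside the ODE right-hand side.

    The LP corner (winner takes the whole budget) is arbitrated smoothly:
    the budget share follows a steep sigmoid in the log-ratio of the two
    per-budget returns.  This keeps the right-hand side Lipschitz on the
    switching surface (where the LP itself is degenerate) and avoids
    sliding-mode chatter in the adaptive stepper; away from the surface
    it coincides with the exact corner of :func:`allocate_static_A1`.
    """
    g1, g2, phi = vp["g1"], vp["g2"], vp["phi"]
    kappa = vp.get("arbitration_sharpness", 40.0)
    budget = phi * np.maximum(cols["bp"], 0.0)
    s1 = np.maximum(cols["s1"], 0.0)
    s2 = np.maximum(cols["s2"], 0.0)
    tiny = 1e-12
    v1 = p.k_s1 * s1 / (p.K1 + s1) / g1
    v2 = p.k_s2 * s2 / (p.K2 + s2) / g2
    ratio = np.log((v1 + tiny) / (v2 + tiny))
    w = 1.0 / (1.0 + np.exp(-np.clip(kappa * ratio, -500, 500)))
    have_gain = np.where(v1 + v2 > 0, 1.0, 0.0)     # no return -> no enzymes
    return w * budget / g1 * have_gain, (1.0 - w) * budget / g2 * have_gain


def cybernetic_u_A3(r_s1, r_s2, delta: float = 0.0):
    """Matching law: allocate enzyme synthesis in proportion to returns.

    ``delta`` is an optional regularisation: ``u1 = (r1+delta)/(tot+2 delta)``
    tends smoothly to 1/2 as both rates vanish.  The ODE right-hand side
    uses a small positive delta so the allocation stays Lipschitz at
    substrate depletion; the exact matching law is delta = 0.
    """
    r1 = np.asarray(r_s1, dtype=float)
    tot = r1 + np.asarray(r_s2, dtype=float)
    if delta > 0:
        u1 = (r1 + delta) / (tot + 2 * delta)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            u1 = np.where(tot > 0, r1 / np.where(tot > 0, tot, 1.0), 0.5)
    return u1, 1.0 - u1


def energy_coupled_rates_A4(state: SV, p: CoreParameters, vp: dict = None):
    """Rates of the A4 scheme (uptake requires M; 2 M produced per X_i)."""
    from .variants import make_variant

    spec = make_variant("A4")
    vp = vp or spec.variant_params
    return variant_rates(0.0, state, spec, p, vp)


def pts_rates_A5(state: SV, p: CoreParameters, vp: dict = None):
    """Rates of the A5 PTS scheme; uptake of S1 is carried by E1~P."""
    from .variants import make_variant

    spec = make_variant("A5")
    vp = vp or spec.variant_params
    return variant_rates(0.0, state, spec, p, vp)


# ---------------------------------------------------------------------------
# control-vector parameterisation
# ---------------------------------------------------------------------------

@dataclass
class ControlProfile:
    """Piecewise-constant allocation fractions on a uniform time grid."""

    grid: np.ndarray          # interval edges, length K+1
    u: np.ndarray             # (K, 2) allocation fractions
    u_max: float = 1.0

    def validate(self):
        if np.any(self.u < -1e-9) or np.any(self.u.sum(axis=1) > 1 + 1e-9):
            raise ConfigurationError("need 0 <= u_i and u1 + u2 <= 1 per node")

    def __call__(self, t):
        idx = np.clip(np.searchsorted(self.grid, t, side="right") - 1,
                      0, len(self.u) - 1)
        return self.u[idx, 0], self.u[idx, 1]

    def to_frame(self):
        import pandas as pd

        mid = 0.5 * (self.grid[:-1] + self.grid[1:])
        return pd.DataFrame({"t": mid, "u1": self.u[:, 0], "u2": self.u[:, 1]})


@dataclass
class OptimalControlResult:
    profile: ControlProfile
    objective: float
    trajectory: Trajectory
    converged: bool
    iterations: int
    log: list = field(default_factory=list)


def _scalar_control(profile):
    import bisect

    edges = list(profile.grid)
    u = profile.u

    def c(t):
        i = min(max(bisect.bisect_right(edges, t) - 1, 0), len(u) - 1)
        return u[i, 0], u[i, 1]

    return c


def _fast_sim(spec: ModelSpec, scen: Scenario, control, t_end: float,
              rtol: float = 1e-6, n_out: int = 201, time_factor: float = 1.0):
    """Lean scalar-RHS integration of the a2/a6 structures.

    Used inside the optimal-control objective, where the generic vectorised
    right-hand side would dominate the runtime.  ``time_factor`` rescales
    all rate constants (the free-time transformation).
    """
    from scipy.integrate import solve_ivp

    from .core import initial_state

    p, vp = spec.core, spec.variant_params
    T = time_factor
    ks1, ks2, K1, K2 = p.k_s1 * T, p.k_s2 * T, p.K1, p.K2
    kx1, kx2, km = p.k_x1 * T, p.k_x2 * T, p.k_m * T
    w1, w2, Y1, Y2 = p.w1, p.w2, p.Y1, p.Y2
    u_max = vp.get("u_max", 1.0) * T
    cfun = _scalar_control(control) if control is not None else \
        (lambda t: (0.5, 0.5))
    y0 = initial_state(spec, scen)

    def rhs(t, y):
        s1, s2, b, x1, x2, m, bp, e1, e2 = y
        s1 = s1 if s1 > 0 else 0.0
        s2 = s2 if s2 > 0 else 0.0
        x1 = x1 if x1 > 0 else 0.0
        x2 = x2 if x2 > 0 else 0.0
        mm = m if m > 0 else 0.0
        bpp = bp if bp > 0 else 0.0
        rs1 = ks1 * (e1 if e1 > 0 else 0.0) * s1 / (K1 + s1)
        rs2 = ks2 * (e2 if e2 > 0 else 0.0) * s2 / (K2 + s2)
        rd1, rd2, rb = kx1 * x1, kx2 * x2, km * mm
        u1, u2 = cfun(t)
        drain = u_max * bpp
        mu = Y1 * rs1 + Y2 * rs2
        return (-rs1 * w1 * b, -rs2 * w2 * b, mu * b, rs1 - rd1, rs2 - rd2,
                rd1 + rd2 - rb, rb - drain - mu * bp,
                u1 * drain - mu * e1, u2 * drain - mu * e2)

    grid = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol,
                    atol=1e-9, t_eval=grid)
    if not sol.success:
        raise RuntimeError(sol.message)
    return sol.t, sol.y


def _sample_u(rng, k):
    u1 = rng.uniform(0.0, 1.0, size=k)
    u2 = rng.uniform(0.0, 1.0, size=k) * (1.0 - u1)
    return np.column_stack([u1, u2])


def _penalty_integral(t, series, bound, direction):
    """Trapezoidal integral of the squared path-constraint violation."""
    if direction == "upper":
        v = np.maximum(series - bound, 0.0)
    else:
        v = np.maximum(bound - series, 0.0)
    return float(np.trapezoid(v * v, t))


def allocate_dynamic_A2(spec: ModelSpec, scen: Scenario, grid_size: int = 10,
                        M_max: Optional[float] = None, seed: int = 0,
                        n_starts: int = 5, maxiter: int = 60,
                        sim_rtol: float = 1e-6,
                        penalty_weights=(50.0, 2000.0)) -> OptimalControlResult:
    """Dynamic resource allocation: maximise B(t_end) subject to M <= M_max.

    Controls are the enzyme-synthesis allocation fractions ``u1, u2`` on
    ``grid_size`` equal intervals; enzyme synthesis is ``r_ei = u_i u_max B'``
    and the drain ``u_max B'`` is charged to the B' balance.  The path
    constraint is enforced by a quadratic penalty whose weight is ramped.
    """
    if grid_size < 4:
        raise ConfigurationError("grid size must be >= 4")
    vp = dict(spec.variant_params)
    if M_max is not None:
        vp["M_max"] = M_max
    if vp.get("M_max", 0) <= 0:
        raise ConfigurationError("M_max must be > 0")
    edges = np.linspace(0.0, scen.t_end, grid_size + 1)
    rng = np.random.default_rng(seed)
    spec2 = ModelSpec(**{**spec.__dict__, "variant_params": vp})

    def objective(z, P):
        prof = ControlProfile(edges, z.reshape(2, grid_size).T, vp["u_max"])
        try:
            t, Ys = _fast_sim(spec2, scen, prof, scen.t_end, rtol=sim_rtol)
        except Exception:
            return 1e6
        viol = np.maximum(Ys[5] - vp["M_max"], 0.0) / vp["M_max"]
        pen = float(np.trapezoid(viol * viol, t))
        return -(Ys[2, -1] - P * pen)

    cons = [{"type": "ineq",
             "fun": lambda z: 1.0 - z[:grid_size] - z[grid_size:]}]
    bounds = [(0.0, 1.0)] * (2 * grid_size)
    best, best_val, log, n_iter = None, np.inf, [], 0
    converged = False
    for start in range(n_starts):
        z0 = _sample_u(rng, grid_size).T.ravel() if start else \
            np.full(2 * grid_size, 0.4)
        z = z0
        for P in penalty_weights:
            res = minimize(objective, z, args=(P,), method="SLSQP",
                           bounds=bounds, constraints=cons,
                           options={"maxiter": maxiter, "ftol": 1e-9,
                                    "eps": 1e-3})
            z = res.x
            n_iter += res.nit
        val = objective(z, penalty_weights[-1])
        log.append({"start": start, "objective": -val, "success": bool(res.success)})
        if val < best_val:
            best, best_val = z, val
            converged = bool(res.success)

    prof = ControlProfile(edges, best.reshape(2, grid_size).T, vp["u_max"])
    traj = simulate(spec2, scen, SolverSettings(rtol=1e-8, atol=1e-10),
                    control=prof)
    return OptimalControlResult(prof, float(traj.states["b"][-1]), traj,
                                converged, n_iter, log)


def maximize_lifespan_A6(spec: ModelSpec, scen: Scenario,
                         Bprime_min: Optional[float] = None, seed: int = 0,
                         n_starts: int = 5, grid_size: int = 10,
                         maxiter: int = 60, T_bounds=(1.0, 200.0),
                         penalty_weights=(50.0, 2000.0)) -> OptimalControlResult:
    """Free-time optimal control: maximise the lifespan t_end with B' >= B'_min.

    The horizon is rescaled to [0, 1] with t_end as an extra decision
    variable (standard free-time transformation); B' is drained at the
    constant protein-turnover rate ``u_max B'`` so that, once the substrates
    are gone, B' decays and the floor constraint bounds the lifespan.
    """
    vp = dict(spec.variant_params)
    if Bprime_min is not None:
        vp["bp_min"] = Bprime_min
    if vp.get("bp_min", 0) <= 0:
        raise ConfigurationError("Bprime_min must be > 0")
    base_spec = ModelSpec(**{**spec.__dict__, "variant_params": vp})
    tau_edges = np.linspace(0.0, 1.0, grid_size + 1)
    rng = np.random.default_rng(seed)
    tau_scen = Scenario(initial=dict(scen.initial), t_end=1.0, kind=scen.kind)

    def objective(z, P):
        u, T = z[:-1], z[-1]
        prof = ControlProfile(tau_edges, u.reshape(2, grid_size).T)
        try:
            t, Ys = _fast_sim(base_spec, tau_scen, prof, 1.0, rtol=1e-6,
                              time_factor=T)
        except Exception:
            return 1e6
        viol = np.maximum(vp["bp_min"] - Ys[6], 0.0) / vp["bp_min"]
        pen = float(np.trapezoid(viol * viol, t)) * T
        return -(T - P * pen)

    cons = [{"type": "ineq",
             "fun": lambda z: 1.0 - z[:grid_size] - z[grid_size:2 * grid_size]}]
    bounds = [(0.0, 1.0)] * (2 * grid_size) + [T_bounds]
    best, best_val, log, n_iter = None, np.inf, [], 0
    converged = False
    for start in range(n_starts):
        u0 = np.full(2 * grid_size, 0.4) if start == 0 else \
            _sample_u(rng, grid_size).T.ravel()
        z0 = np.concatenate([u0, [rng.uniform(*T_bounds) if start else 20.0]])
        z = z0
        for P in penalty_weights:
            res = minimize(objective, z, args=(P,), method="SLSQP",
                           bounds=bounds, constraints=cons,
                           options={"maxiter": maxiter, "ftol": 1e-9,
                                    "eps": 1e-3})
            z = res.x
            n_iter += res.nit
        val = objective(z, penalty_weights[-1])
        log.append({"start": start, "objective": -val, "success": bool(res.success)})
        if val < best_val:
            best, best_val = z, val
            converged = bool(res.success)

    u_best, T_best = best[:-1], float(best[-1])
    edges = tau_edges * T_best
    prof = ControlProfile(edges, u_best.reshape(2, grid_size).T,
                          vp.get("u_max", 1.0))
    real_scen = Scenario(initial=dict(scen.initial), t_end=T_best,
                         kind=scen.kind)
    traj = simulate(base_spec, real_scen, SolverSettings(rtol=1e-8, atol=1e-10),
                    control=prof)
    return OptimalControlResult(prof, T_best, traj, converged, n_iter, log)
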