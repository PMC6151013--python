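"""The model ensemble: variant catalogue and symmetry-breaking hooks.

Every variant differs from the shared base scheme in exactly one aspect:

* group 1 (C1-C4): constraint-based / dynamic-FBA modifications (see
  :mod:`diauxie.dfba`),
* group 2 (N1-N4): enzyme induction plus a single asymmetric parameter, so
  that growth dilution washes out the non-preferred enzyme,
* group 3 (R1-R5): a regulatory kinetic interaction (inducer exclusion,
  global transcription-factor activation, metabolite-level control,
  bistable product activation),
* group 4 (A1-A6): resource-allocation schemes (see
  :mod:`diauxie.allocation`).

Regulation factors are Hill forms; exponents are minimal (n=1) except where
bistability requires cooperativity (R5: n=2 product activation, n=4 enzyme
switch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (A1_STATES, A5_STATES, ConfigurationError, CoreParameters,
                   DFBA_STATES, Hooks, ModelSpec)

__all__ = [
    "induction_factor", "inhibition_factor", "activation_factor",
    "r5_enzyme_switch", "steady_state_branches", "make_variant",
    "list_variants", "BifurcationCurve", "ENSEMBLE", "GROUPS",
]


# ---------------------------------------------------------------------------
# regulation factors
# ---------------------------------------------------------------------------

def induction_factor(X, K_a, n=1.0):
    """Saturating induction of enzyme synthesis by an inducer metabolite."""
    if np.any(np.asarray(K_a) <= 0):
        raise ConfigurationError("K_a must be > 0")
    Xp = np.maximum(X, 0.0) ** n
    return Xp / (np.asarray(K_a) ** n + Xp)


def inhibition_factor(Z, K_I, n=1.0):
    """Multiplicative inhibition: 1 at Z=0, 1/2 at Z=K_I, -> 0 as Z grows."""
    Zp = np.maximum(Z, 0.0) ** n
    Kp = np.asarray(K_I) ** n
    return Kp / (Kp + Zp)


def activation_factor(M, K_A, n=1.0, eps=0.0):
    """Activation by M with optional basal offset so the system can leave 0."""
    Mp = np.maximum(M, 0.0) ** n
    return eps + (1.0 - eps) * Mp / (np.asarray(K_A) ** n + Mp)


def r5_enzyme_switch(M, threshold, steepness=4.0):
    """Reciprocal enzyme-synthesis switch: high M -> E1, low M -> E2."""
    f1 = induction_factor(M, threshold, steepness)
    return f1, 1.0 - f1


# ---------------------------------------------------------------------------
# R5 bistability
# ---------------------------------------------------------------------------

@dataclass
class BifurcationCurve:
    """Steady states of the fast M subsystem versus incoming flux."""

    flux_grid: np.ndarray
    branches: list            # per flux value: [(m_root, stable: bool), ...]

    def n_roots(self):
        return np.array([len(b) for b in self.branches])


def steady_state_branches(spec: ModelSpec, flux_range, n_grid: int = 201) -> BifurcationCurve:
    """Roots of ``phi * a(m) = k_m * m`` with product activation ``a``.

    ``phi`` is the incoming flux capacity to M (``sum_i k_xi X_i``); the
    product-activation factor is ``a(m) = eps + (1-eps) m^n/(K_A^n + m^n)``
    with n >= 2, which folds the steady-state curve and yields bistability
    over an interval of fluxes.  Stability is classified by the sign of
    ``d(dm/dt)/dm`` at the root.
    """
    vp = spec.variant_params
    n = vp.get("n_act", 2.0)
    if n < 2:
        raise ConfigurationError("product-activation exponent must be >= 2")
    K = vp["K_A"]
    eps = vp.get("eps", 0.01)
    k_m = spec.core.k_m
    flux_grid = np.linspace(*flux_range, n_grid) if isinstance(flux_range, tuple) \
        else np.asarray(flux_range, dtype=float)

    def g(m, phi):
        return phi * activation_factor(m, K, n, eps) - k_m * m

    branches = []
    for phi in flux_grid:
        if n == 2:
            # phi*(eps*(K^2+m^2) + (1-eps)m^2) = k_m m (K^2+m^2)
            coeffs = [k_m, -phi, k_m * K ** 2, -phi * eps * K ** 2]
            roots = np.roots(coeffs)
        else:
            grid = np.linspace(0.0, max(2.0 * phi / k_m, 4.0 * K), 4000)
            vals = g(grid, phi)
            roots = []
            for a, b in zip(grid[:-1], grid[1:]):
                if g(a, phi) == 0.0:
                    roots.append(a)
                elif g(a, phi) * g(b, phi) < 0:
                    from scipy.optimize import brentq
                    roots.append(brentq(g, a, b, args=(phi,), xtol=1e-12))
            roots = np.asarray(roots)
        here = []
        for r in np.atleast_1d(roots):
            if abs(np.imag(r)) > 1e-9 or np.real(r) < -1e-12:
                continue
            m0 = float(np.real(r))
            h = max(1e-7, 1e-7 * m0)
            slope = (g(m0 + h, phi) - g(m0 - h, phi)) / (2 * h)
            here.append((m0, bool(slope < 0)))
        here.sort()
        branches.append(here)
    return BifurcationCurve(np.asarray(flux_grid, dtype=float), branches)


# ---------------------------------------------------------------------------
# variant construction
# ---------------------------------------------------------------------------

def _induction_hooks():
    def f1(sv, vp, r_s1, r_s2):
        return induction_factor(sv.x1, vp["K_a1"], vp.get("n_ind", 1.0))

    def f2(sv, vp, r_s1, r_s2):
        return induction_factor(sv.x2, vp["K_a2"], vp.get("n_ind", 1.0))

    return f1, f2


def _r1_uptake2(sv, vp):
    return inhibition_factor(sv.x1, vp["K_I"], vp.get("n_inh", 1.0))


def _r2_f2(sv, vp, r_s1, r_s2):
    inh = inhibition_factor(sv.m, vp["K_I"], vp.get("n_inh", 1.0))
    if vp.get("induction", True):
        return induction_factor(sv.x2, vp["K_a2"], vp.get("n_ind", 1.0)) * inh
    return inh


def _r3_consume2(sv, vp):
    return activation_factor(sv.m, vp["K_A"], vp.get("n_act", 1.0))


def _r4_consume1(sv, vp):
    return inhibition_factor(sv.m, vp["K_I"], vp.get("n_inh", 1.0))


def _r5_f1(sv, vp, r_s1, r_s2):
    return r5_enzyme_switch(sv.m, vp["theta"], vp.get("n_switch", 4.0))[0]


def _r5_f2(sv, vp, r_s1, r_s2):
    return r5_enzyme_switch(sv.m, vp["theta"], vp.get("n_switch", 4.0))[1]


def _r5_consume(sv, vp):
    return activation_factor(sv.m, vp["K_A"], vp.get("n_act", 2.0),
                             vp.get("eps", 0.01))


def _a4_uptake(sv, vp):
    return sv.m / (vp["K_M"] + np.maximum(sv.m, 0.0))


def _a3_f1(sv, vp, r_s1, r_s2):
    from .allocation import cybernetic_u_A3

    return cybernetic_u_A3(r_s1, r_s2, delta=vp.get("u_delta", 1e-6))[0]


def _a3_f2(sv, vp, r_s1, r_s2):
    from .allocation import cybernetic_u_A3

    return cybernetic_u_A3(r_s1, r_s2, delta=vp.get("u_delta", 1e-6))[1]


#: symmetric parameter pairs; a variant may break at most its own
_SYM_PAIRS = {
    "core": [("k_s1", "k_s2"), ("K1", "K2"), ("k1", "k2"),
             ("k_x1", "k_x2"), ("Y1", "Y2"), ("w1", "w2")],
    "vp": [("K_a1", "K_a2")],
    "initial": [("e1", "e2")],
}

_ALLOWED_ASYMMETRY = {
    "N1": ("core", ("k1", "k2")),
    "N2": ("initial", ("e1", "e2")),
    "N3": ("vp", ("K_a1", "K_a2")),
    "N4": ("core", ("k_s1", "k_s2")),
    "A2": ("core", ("k_s1", "k_s2")),
    "A3": ("core", ("k_s1", "k_s2")),
    "A4": ("core", ("k_s1", "k_s2")),
}

GROUPS = {1: ("C1", "C2", "C3", "C4"),
          2: ("N1", "N2", "N3", "N4"),
          3: ("R1", "R2", "R3", "R4", "R5"),
          4: ("A1", "A2", "A3", "A4", "A5", "A6")}

ENSEMBLE = GROUPS[1] + GROUPS[2] + GROUPS[3] + GROUPS[4]


def _build(variant_id: str) -> ModelSpec:
    core = CoreParameters()
    ind = dict(K_a1=1.0, K_a2=1.0, n_ind=1.0)
    f1i, f2i = _induction_hooks()

    if variant_id == "base":
        return ModelSpec("base", 0, description="symmetric base kinetic model")
    if variant_id == "base_dfba":
        return ModelSpec("base_dfba", 0, kind="dfba", structure="base",
                         state_names=DFBA_STATES,
                         description="symmetric base dynamic-FBA model")

    if variant_id in GROUPS[1]:
        vp = {}
        free: tuple
        if variant_id == "C1":
            # the cap references the uptake-limited capacity k_s1*E1; with
            # saturation sigma <= s0/(1+s0) = 0.5 under the standard
            # scenario a 0.5 cap never binds, so the variant would never
            # show its defining phase-1 excretion
            vp = dict(cap_frac=0.2)
            free = ("cap_frac",)
            desc = "modified stoichiometry: M central for S1 only; S2 by-product"
        elif variant_id == "C2":
            vp = dict(s1_threshold=0.01)
            free = ("s1_threshold",)
            desc = "regulatory FBA: Boolean rule inactivates E2 while S1 available"
        elif variant_id == "C3":
            vp = dict(a1=1.0, a2=2.0, A_max=0.3)
            free = ("a1", "a2", "A_max")
            desc = "membrane-space (molecular crowding) constraint on E1, E2"
        else:  # C4
            vp = dict(cost1=1.0, cost2=2.0, benefit1=1.0, benefit2=1.0,
                      slack=0.01)
            free = ("cost1", "cost2", "slack")
            desc = "enzyme cost-benefit inequality on synthesis rates"
        return ModelSpec(variant_id, 1, kind="dfba", structure=variant_id,
                         state_names=DFBA_STATES, core=core, variant_params=vp,
                         free_params=free, description=desc)

    if variant_id in GROUPS[2]:
        hooks = Hooks(f1=f1i, f2=f2i)
        spec = ModelSpec(variant_id, 2, core=core, variant_params=dict(ind),
                         hooks=hooks,
                         description="enzyme induction + growth dilution")
        if variant_id == "N1":
            spec.core = core.copy(k1=2.0)
            spec.free_params = ("k1", "k2")
            spec.description += "; asymmetric maximal enzyme-synthesis rates"
        elif variant_id == "N2":
            spec.initial_overrides = {"e1": 0.02}
            spec.free_params = ("E1_0", "E2_0")
            spec.description += "; asymmetric initial enzyme concentrations"
        elif variant_id == "N3":
            spec.variant_params.update(K_a1=0.5, K_a2=1.0)
            spec.free_params = ("K_a1", "K_a2")
            spec.description += "; asymmetric inducer affinities"
        else:  # N4
            spec.core = core.copy(k_s1=2.0)
            spec.free_params = ("k_s1", "k_s2")
            spec.description += "; asymmetric maximal uptake rates"
        return spec

    if variant_id in GROUPS[3]:
        if variant_id == "R1":
            # the inducer pool X1 sits well below 1 early in growth, so
            # effective exclusion needs K_I far below the generic box
            vp = dict(ind, K_I=1e-3, n_inh=1.0)
            return ModelSpec("R1", 3, core=core, variant_params=vp,
                             hooks=Hooks(uptake2=_r1_uptake2, f1=f1i, f2=f2i),
                             free_params=("K_I",),
                             param_boxes={"K_I": (1e-4, 1e2)},
                             description="inducer exclusion: X1 inhibits E2 activity")
        if variant_id == "R2":
            vp = dict(ind, K_I=0.02, n_inh=1.0, induction=True)
            return ModelSpec("R2", 3, core=core, variant_params=vp,
                             hooks=Hooks(f1=f1i, f2=_r2_f2),
                             free_params=("K_I",),
                             description="global transcription factor: M inhibits E2 synthesis")
        if variant_id == "R3":
            vp = dict(ind, K_A=1.0, n_act=1.0)
            return ModelSpec("R3", 3, core=core, variant_params=vp,
                             hooks=Hooks(consume2=_r3_consume2, f1=f1i, f2=f2i),
                             free_params=("K_A",),
                             description="M activates consumption of X2")
        if variant_id == "R4":
            vp = dict(ind, K_I=0.2, n_inh=1.0)
            return ModelSpec("R4", 3, core=core, variant_params=vp,
                             hooks=Hooks(consume1=_r4_consume1, f1=f1i, f2=f2i),
                             free_params=("K_I",),
                             description="M inhibits consumption of X1")
        # R5
        vp = dict(theta=0.3, K_A=0.3, n_switch=4.0, n_act=2.0, eps=0.01)
        return ModelSpec("R5", 3, core=core, variant_params=vp,
                         hooks=Hooks(f1=_r5_f1, f2=_r5_f2,
                                     consume1=_r5_consume, consume2=_r5_consume),
                         initial_overrides={"m": 1.0},
                         free_params=("theta", "K_A"),
                         description="bistable switch: product activation of M synthesis")

    if variant_id in GROUPS[4]:
        from . import allocation

        if variant_id == "A1":
            vp = dict(g1=1.0, g2=2.0, phi=0.5)
            return ModelSpec("A1", 4, structure="a1", state_names=A1_STATES,
                             core=core, variant_params=vp,
                             initial_overrides={"bp": 0.05},
                             enzyme_supplier=allocation.a1_enzyme_supplier,
                             free_params=("g1", "g2", "phi"),
                             param_boxes={"phi": (0.01, 0.99)},
                             description="static allocation: weighted enzyme budget from B'")
        if variant_id == "A2":
            # tight M cap + different pathway parameters break the symmetry
            vp = dict(u_max=0.5, M_max=0.5)
            return ModelSpec("A2", 4, structure="a2", core=core.copy(k_s1=2.0),
                             variant_params=vp,
                             initial_overrides={"bp": 0.05},
                             free_params=("M_max", "k_s1", "k_s2"),
                             description="dynamic allocation: maximise B(t_end) s.t. M <= M_max")
        if variant_id == "A3":
            return ModelSpec("A3", 4, core=core.copy(k_s1=2.0),
                             hooks=Hooks(f1=_a3_f1, f2=_a3_f2),
                             free_params=("k_s1", "k_s2"),
                             description="cybernetic: enzyme synthesis matches fractional uptake")
        if variant_id == "A4":
            vp = dict(K_M=0.1)
            return ModelSpec("A4", 4, structure="a4", core=core,
                             variant_params=vp,
                             hooks=Hooks(uptake1=_a4_uptake, uptake2=_a4_uptake),
                             initial_overrides={"m": 0.1},
                             free_params=("K_M", "k_s1", "k_s2"),
                             description="energy-coupled transport: M consumed per uptake event")
        if variant_id == "A5":
            vp = dict(k_p=10.0)
            return ModelSpec("A5", 4, structure="a5", state_names=A5_STATES,
                             core=core, variant_params=vp,
                             initial_overrides={"m": 0.1},
                             free_params=("k_p",),
                             description="PTS competition: phosphorylated E1 carries uptake of S1")
        # A6
        vp = dict(u_max=0.5, bp_min=0.02)
        return ModelSpec("A6", 4, structure="a6", core=core, variant_params=vp,
                         initial_overrides={"bp": 0.05},
                         free_params=("bp_min", "u_max"),
                         param_boxes={"u_max": (0.01, 1.0),
                                      "bp_min": (1e-3, 0.045)},
                         description="lifespan maximisation: free-time optimal control, B' >= B'_min")

    raise ConfigurationError(f"unknown variant id {variant_id!r}")


def make_variant(variant_id: str, overrides: dict = None) -> ModelSpec:
    """Construct a :class:`ModelSpec` for ``variant_id`` with overrides.

    Overrides may name core parameters, variant parameters, or initial
    conditions (``E1_0``/``E2_0``/``M_0``/``BP_0``).  ``induction=False``
    removes the induction hooks (N group and R1-R4).  An override that
    breaks a symmetry other than the variant's own is rejected: the point of
    the ensemble is that each variant differs in a single aspect.
    """
    spec = _build(variant_id)
    overrides = dict(overrides or {})

    if "induction" in overrides:
        if not overrides.pop("induction"):
            # keep R2's transcription-factor inhibition, drop only induction
            spec.hooks.f1 = None
            if variant_id == "R2":
                spec.variant_params["induction"] = False
            else:
                spec.hooks.f2 = None

    initial_map = {"e1_0": "e1", "e2_0": "e2", "m_0": "m", "bp_0": "bp",
                   "s1_0": "s1", "s2_0": "s2", "b_0": "b"}
    for key, value in overrides.items():
        lk = key.lower()
        if lk in initial_map:
            spec.initial_overrides[initial_map[lk]] = value
        elif hasattr(spec.core, key):
            spec.core = spec.core.copy(**{key: value})
        else:
            spec.variant_params[key] = value

    _validate_symmetry(spec, variant_id)
    spec.core.validate()
    return spec


def _validate_symmetry(spec: ModelSpec, variant_id: str) -> None:
    allowed = _ALLOWED_ASYMMETRY.get(variant_id)
    for a, b in _SYM_PAIRS["core"]:
        if getattr(spec.core, a) != getattr(spec.core, b):
            if allowed != ("core", (a, b)):
                raise ConfigurationError(
                    f"{variant_id}: asymmetric ({a}, {b}) breaks a symmetry "
                    "that is not this variant's own")
    for a, b in _SYM_PAIRS["vp"]:
        va, vb = spec.variant_params.get(a), spec.variant_params.get(b)
        if va is not None and vb is not None and va != vb:
            if allowed != ("vp", (a, b)):
                raise ConfigurationError(
                    f"{variant_id}: asymmetric ({a}, {b}) not permitted")
    ia = spec.initial_overrides.get("e1")
    ib = spec.initial_overrides.get("e2")
    if ia is not None and ib is not None and ia != ib and \
            allowed != ("initial", ("e1", "e2")):
        raise ConfigurationError(
            f"{variant_id}: asymmetric initial enzymes not permitted")
    if ia is not None and ib is None and ia != DEFAULT_E0 and \
            allowed != ("initial", ("e1", "e2")):
        raise ConfigurationError(
            f"{variant_id}: asymmetric initial enzymes not permitted")


DEFAULT_E0 = 0.01


def list_variants():
    """Machine-readable catalogue of the ensemble (id, group, free params)."""
    records = []
    for gid, members in GROUPS.items():
        for vid in members:
            spec = _build(vid)
            records.append({"id": vid, "group": gid, "kind": spec.kind,
                            "free_parameters": list(spec.free_params),
                            "description": spec.description})
    return records
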