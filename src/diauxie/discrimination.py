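"""Model discrimination by clustering predicted time-courses.

The ensemble's predictions for a discriminating experiment (glucose pulse
during growth on lactose, or a lactose-preculture batch with abundant E2)
are interpolated onto a common grid, clustered hierarchically (Ward
linkage, Euclidean distance) per measured channel, and each cluster is
summarised by its mean time-course.  Qualitative features of the
experiments are then checked against the cluster representatives - not the
raw trajectories - and the sets of variants passing the substrate and
enzyme channels are intersected.

Feature operationalisation (thresholds are committed choices):

* preculture: substrate OK iff S2 drops by < 5% before S1 depletion;
  enzyme OK iff the E2 activity proxy decreases during the glucose phase
  and increases again after S1 depletion.
* pulse: substrate OK iff the S2 consumption rate drops after the pulse
  and recovers to >= 80% of its pre-pulse value before S1 is re-depleted;
  enzyme OK iff E2-proxy growth halts after the pulse and later resumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .core import ConfigurationError, Trajectory
from .scenarios import _channel_series

__all__ = ["ClusterResult", "FeatureVerdict", "align_timecourses",
           "cluster_timecourses", "qualitative_features",
           "model_intersection", "s1_depletion_time"]

#: phase boundary: glucose-phase growth has effectively ceased below 1%
#: of the initial (rescaled) concentration
S1_DEPLETED = 1e-2


@dataclass
class ClusterResult:
    labels: dict                       # row id -> cluster id (1..k)
    k: int
    representatives: dict              # cluster id -> mean time-course
    linkage_record: list
    grid: np.ndarray = None

    def members(self, cid):
        return [rid for rid, c in self.labels.items() if c == cid]


@dataclass
class FeatureVerdict:
    variant_id: str
    substrate_ok: bool = None
    enzyme_ok: bool = None
    notes: list = field(default_factory=list)

    @property
    def both(self):
        return bool(self.substrate_ok) and bool(self.enzyme_ok)


def s1_depletion_time(traj: Trajectory, threshold: float = S1_DEPLETED) -> float:
    """First time at which S1 falls below the depletion threshold."""
    s1 = traj.states["s1"]
    below = np.nonzero(s1 < threshold)[0]
    return float(traj.t[below[0]]) if len(below) else float(traj.t[-1])


def align_timecourses(trajs: dict, channel: str, n_grid: int = 200,
                      pulse_align: bool = False, time_scales: dict = None,
                      window: tuple = None):
    """Interpolate one channel of each trajectory onto a common grid.

    For pulse scenarios the time axis of each trajectory is shifted so all
    pulses coincide at t = 0 before interpolation.  ``time_scales``
    optionally divides each (shifted) axis by a per-trajectory duration —
    e.g. the substrate-depletion time — so that models with different
    growth rates are compared at the same phase of the experiment rather
    than at the same clock time.  Without scales the common window is the
    overlap of the (shifted) supports; with scales, ``window`` fixes the
    grid and values beyond a trajectory's support hold its endpoints.
    Returns ``(grid, matrix, row_ids)``.
    """
    ids = list(trajs)
    if pulse_align:
        shifts = {}
        for vid in ids:
            tr = trajs[vid]
            t_p = tr.meta.get("t_pulse")
            if t_p is None:
                t_p = next((t for t, desc in tr.events if "pulse" in desc), 0.0)
            shifts[vid] = t_p
    else:
        shifts = {vid: 0.0 for vid in ids}
    scales = time_scales or {vid: 1.0 for vid in ids}
    if window is None:
        lo = max((tr.t[0] - shifts[vid]) / scales[vid]
                 for vid, tr in trajs.items())
        hi = min((tr.t[-1] - shifts[vid]) / scales[vid]
                 for vid, tr in trajs.items())
        if hi <= lo:
            raise ConfigurationError("trajectories have no common time window")
    else:
        lo, hi = window
    grid = np.linspace(lo, hi, n_grid)
    rows = np.vstack([
        np.interp(grid, (trajs[vid].t - shifts[vid]) / scales[vid],
                  _channel_series(trajs[vid], channel))
        for vid in ids])
    return grid, rows, ids


def cluster_timecourses(matrix: np.ndarray, k: int, row_ids=None) -> ClusterResult:
    """Agglomerative Ward/Euclidean clustering with mean representatives."""
    matrix = np.asarray(matrix, dtype=float)
    n = len(matrix)
    if not 1 <= k <= n:
        raise ConfigurationError(f"k={k} outside [1, {n}]")
    row_ids = list(row_ids) if row_ids is not None else list(range(n))
    if n == 1:
        return ClusterResult({row_ids[0]: 1}, 1, {1: matrix[0].copy()}, [])
    Z = linkage(matrix, method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber clusters by first appearance for determinism
    remap, labels = {}, {}
    for rid, c in zip(row_ids, raw):
        remap.setdefault(c, len(remap) + 1)
        labels[rid] = remap[c]
    reps = {}
    for cid in set(labels.values()):
        members = [i for i, rid in enumerate(row_ids) if labels[rid] == cid]
        reps[cid] = matrix[members].mean(axis=0)
    return ClusterResult(labels, len(reps), reps, Z.tolist())


# ---------------------------------------------------------------------------
# qualitative features
# ---------------------------------------------------------------------------

def _rate(series, grid):
    return -np.gradient(series, grid)


def _flag_with_margin(value, threshold, sense, notes, name, margin=0.1):
    """Compare value to threshold; flag near-threshold calls as ambiguous."""
    ok = value < threshold if sense == "lt" else value > threshold
    if threshold != 0 and abs(value - threshold) <= margin * abs(threshold):
        notes.append(f"ambiguous:{name} ({value:.3g} vs {threshold:.3g})")
    return bool(ok)


def qualitative_features(representative: dict, scenario_kind: str,
                         variant_id: str = "?") -> FeatureVerdict:
    """Check the retained experiment characteristics on a cluster mean.

    ``representative`` maps ``t`` to the common grid and optionally
    provides the channels ``S2`` and ``E2_activity`` plus the auxiliary
    time marks ``t_s1_depleted`` (both scenarios, on the same axis as
    ``t``).  For pulse scenarios the grid is pulse-aligned with the pulse
    at t = 0.
    """
    v = FeatureVerdict(variant_id)
    grid = np.asarray(representative["t"], dtype=float)
    t_dep = representative.get("t_s1_depleted", grid[-1])

    if scenario_kind == "preculture":
        if "S2" in representative:
            s2 = representative["S2"]
            phase1 = grid <= t_dep
            phase2 = grid > t_dep
            if not phase1.any() or not phase2.any() or s2[0] <= 0:
                v.substrate_ok = False
            else:
                drop = (s2[0] - s2[phase1].min()) / s2[0]
                untouched = _flag_with_margin(drop, 0.05, "lt",
                                              v.notes, "S2_drop")
                # and the substrate must actually be consumed afterwards
                after = (s2[phase1][-1] - s2[phase2].min()) / s2[0]
                v.substrate_ok = bool(untouched and after > 0.05)
        if "E2_activity" in representative:
            e2 = representative["E2_activity"]
            phase1 = grid <= t_dep
            phase2 = grid > t_dep
            if not phase1.any() or not phase2.any():
                v.enzyme_ok = False
            else:
                e_at_dep = e2[phase1][-1]
                decreased = e_at_dep < e2[0] * 0.98
                resumed = e2[phase2].max() > e_at_dep * 1.02
                v.enzyme_ok = bool(decreased and resumed)
                if not decreased:
                    v.notes.append("enzyme: no dilution during glucose phase")
                if not resumed:
                    v.notes.append("enzyme: no re-expression after depletion")
    elif scenario_kind == "pulse":
        pre = grid < 0.0
        post = grid >= 0.0
        if "S2" in representative:
            # specific (per-biomass) consumption rate: absolute rates keep
            # rising with the growing culture and would mask the slowdown
            b = representative.get("B", np.ones_like(grid))
            rate = _rate(representative["S2"], grid) / np.maximum(b, 1e-12)
            if not pre.any() or not post.any():
                v.substrate_ok = False
            else:
                pre_rate = max(float(np.median(rate[pre])), 0.0)
                if pre_rate <= 0:
                    v.substrate_ok = False
                else:
                    dropped = rate[post].min() < 0.95 * pre_rate
                    # uptake must resume after the slowdown; in variants
                    # whose glucose machinery re-induces slowly this
                    # happens only once the pulse is re-depleted
                    i_min = int(np.argmin(rate[post]))
                    recovered = (rate[post][i_min:] >= 0.8 * pre_rate).any()
                    v.substrate_ok = bool(dropped and recovered)
                    if dropped:
                        frac = rate[post][i_min:].max() / pre_rate
                        _flag_with_margin(frac, 0.8, "gt", v.notes,
                                          "S2_rate_recovery")
                    else:
                        v.notes.append("substrate: no slowdown after pulse")
        if "E2_activity" in representative:
            slope = np.gradient(representative["E2_activity"], grid)
            if not pre.any() or not post.any():
                v.enzyme_ok = False
            else:
                pre_slope = float(np.median(slope[pre]))
                if pre_slope <= 0:
                    v.enzyme_ok = False
                    v.notes.append("enzyme: not growing before pulse")
                else:
                    halted = slope[post].min() < 0.2 * pre_slope
                    i_min = int(np.argmin(slope[post]))
                    resumed = (slope[post][i_min:] > 0.5 * pre_slope).any()
                    v.enzyme_ok = bool(halted and resumed)
    else:
        raise ConfigurationError(f"unknown scenario kind {scenario_kind!r}")

    if v.substrate_ok is None and v.enzyme_ok is None:
        raise ConfigurationError("representative carries no known channel")
    return v


def model_intersection(verdicts: dict) -> dict:
    """Set algebra over per-experiment substrate/enzyme verdicts.

    ``verdicts`` maps experiment name -> list of :class:`FeatureVerdict`.
    Returns per-experiment sets (substrate, enzyme, both, ambiguous) and
    the across-experiment intersection of the ``both`` sets.
    """
    per = {}
    for exp, vs in verdicts.items():
        per[exp] = {
            "substrate": {v.variant_id for v in vs if v.substrate_ok},
            "enzyme": {v.variant_id for v in vs if v.enzyme_ok},
            "both": {v.variant_id for v in vs if v.both},
            "ambiguous": {v.variant_id for v in vs
                          if any(n.startswith("ambiguous") for n in v.notes)},
        }
    across = None
    for exp in per:
        across = per[exp]["both"] if across is None else across & per[exp]["both"]
    return {"per_experiment": per, "across": across or set()}


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def ensemble_predictions(scenario_kind: str, variants=None, params: dict = None,
                         settings=None) -> dict:
    """Simulate the ensemble under one discriminating experiment.

    ``params`` optionally maps variant id -> parameter overrides (e.g. the
    d-maximised sets).  Exclusions follow the experimental constraints:
    N2 cannot be run in the preculture design (its defining asymmetry *is*
    an initial enzyme condition) and A2's dynamic program admits no
    externally timed pulse.  The optimal-control variants are solved on
    the unperturbed medium and their allocation profile is then replayed
    in the scenario.
    """
    from .core import SolverSettings, simulate
    from .scenarios import (ScenarioInfeasibleError, make_batch,
                            make_preculture, make_pulse)
    from .variants import ENSEMBLE, make_variant

    settings = settings or SolverSettings(rtol=1e-7, atol=1e-9, n_out=1001)
    excluded = {"preculture": {"N2"}, "pulse": {"A2"}}[scenario_kind]
    variants = [v for v in (variants or ENSEMBLE) if v not in excluded]
    trajs = {}
    for vid in variants:
        spec = make_variant(vid, (params or {}).get(vid))
        try:
            if scenario_kind == "preculture":
                scen = make_preculture(spec)
            else:
                scen = make_pulse(spec)
        except ScenarioInfeasibleError:
            continue
        try:
            if vid == "A2":
                from .allocation import allocate_dynamic_A2

                res = allocate_dynamic_A2(spec, scen, n_starts=2, maxiter=25,
                                          seed=0)
                traj = res.trajectory
            elif vid == "A6":
                from .allocation import maximize_lifespan_A6

                plain = make_batch(t_end=scen.t_end)
                plain.initial = {k: v for k, v in scen.initial.items()}
                plain.initial.pop("pulses", None)
                res = maximize_lifespan_A6(spec, plain, n_starts=2,
                                           maxiter=25, seed=0)
                traj = simulate(spec, scen, settings, control=res.profile)
            else:
                traj = simulate(spec, scen, settings)
        except Exception:
            continue
        traj.meta["t_pulse"] = scen.meta.get("t_pulse")
        trajs[vid] = traj
    return trajs


def run_discrimination(k: int = 4, variants=None, params: dict = None,
                       settings=None, n_grid: int = 200) -> dict:
    """Cluster ensemble predictions and intersect the qualitative verdicts.

    Channels (S2 and the E2 activity proxy) are clustered separately with
    ``k`` clusters each; every variant inherits the verdict of the cluster
    representative it belongs to.
    """
    results = {"verdicts": {}, "clusters": {}, "trajectories": {}}
    for exp in ("preculture", "pulse"):
        trajs = ensemble_predictions(exp, variants, params, settings)
        results["trajectories"][exp] = trajs
        pulse_align = exp == "pulse"
        # per-variant duration of the glucose phase (time to S1 depletion,
        # measured from the pulse for pulse runs); the time axes are
        # normalised by it so models with different growth rates are
        # compared at the same phase of the experiment
        t_dep = {}
        for vid, tr in trajs.items():
            shift = (tr.meta.get("t_pulse") or 0.0) if pulse_align else 0.0
            after = tr.t >= shift
            s1 = tr.states["s1"][after]
            tt = tr.t[after]
            below = np.nonzero(s1 < S1_DEPLETED)[0]
            t_dep[vid] = float(tt[below[0]] - shift) if len(below) \
                else float(tr.t[-1] - shift)
            t_dep[vid] = max(t_dep[vid], 1e-6)
        window = (-0.3, 1.5) if pulse_align else (0.0, 1.5)

        flags = {}
        results["clusters"][exp] = {}
        for channel, attr in (("S2", "substrate_ok"),
                              ("E2_activity", "enzyme_ok")):
            grid, rows, ids = align_timecourses(trajs, channel, n_grid,
                                                pulse_align=pulse_align,
                                                time_scales=t_dep,
                                                window=window)
            kk = min(k, len(ids))
            cres = cluster_timecourses(rows, kk, ids)
            cres.grid = grid
            results["clusters"][exp][channel] = cres
            b_mean = {}
            if pulse_align and channel == "S2":
                _, b_rows, b_ids = align_timecourses(trajs, "B", n_grid,
                                                     pulse_align=True,
                                                     time_scales=t_dep,
                                                     window=window)
                b_of = dict(zip(b_ids, b_rows))
                for cid in cres.representatives:
                    b_mean[cid] = np.mean([b_of[m] for m in
                                           cres.members(cid)], axis=0)
            for vid in ids:
                cid = cres.labels[vid]
                # on the normalised axis S1 depletion sits at 1 by
                # construction for every member of the cluster
                rep = {"t": grid, channel: cres.representatives[cid],
                       "t_s1_depleted": 1.0}
                if cid in b_mean:
                    rep["B"] = b_mean[cid]
                verdict = qualitative_features(rep, exp, vid)
                flags.setdefault(vid, FeatureVerdict(vid))
                setattr(flags[vid], attr, getattr(verdict, attr))
                flags[vid].notes.extend(verdict.notes)
        results["verdicts"][exp] = list(flags.values())
    results["intersection"] = model_intersection(results["verdicts"])
    return results
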