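"""Time-course alignment, Ward clustering, feature verdicts, set algebra."""

import itertools

import numpy as np
import pytest

from diauxie import (Trajectory, align_timecourses, cluster_timecourses,
                     model_intersection, qualitative_features)
from diauxie.core import ConfigurationError
from diauxie.discrimination import FeatureVerdict


def traj_from(t, s2, pulse=None):
    states = {"s1": np.ones_like(t), "s2": s2, "b": np.ones_like(t)}
    meta = {"t_pulse": pulse} if pulse is not None else {}
    return Trajectory(t=t, states=states, rates={}, meta=meta)


class TestAlign:
    def test_identical_trajectories_identical_rows(self):
        t = np.linspace(0, 10, 101)
        trajs = {"a": traj_from(t, np.exp(-t)), "b": traj_from(t, np.exp(-t))}
        _, rows, ids = align_timecourses(trajs, "S2", 50)
        assert np.allclose(rows[0], rows[1])

    def test_pulse_markers_coincide_after_alignment(self):
        t = np.linspace(0, 10, 201)
        trajs = {"a": traj_from(t, np.where(t > 2, 0.5, 1.0), pulse=2.0),
                 "b": traj_from(t, np.where(t > 4, 0.5, 1.0), pulse=4.0)}
        grid, rows, ids = align_timecourses(trajs, "S2", 400,
                                            pulse_align=True)
        assert grid[0] < 0 < grid[-1]
        # both step changes sit at the common reference time 0
        for row in rows:
            drop = grid[np.argmax(np.abs(np.diff(row)))]
            assert abs(drop) < 0.1

    def test_grid_refinement_stable_for_smooth_input(self):
        t = np.linspace(0, 10, 400)
        trajs = {"a": traj_from(t, np.exp(-0.3 * t))}
        g1, r1, _ = align_timecourses(trajs, "S2", 100)
        g2, r2, _ = align_timecourses(trajs, "S2", 200)
        interp = np.interp(g1, g2, r2[0])
        assert np.max(np.abs(interp - r1[0])) < 1e-3


def brute_force_best_2partition(X):
    """Minimal within-cluster sum of squares over all 2-partitions."""
    n = len(X)
    best = np.inf
    for size in range(1, n // 2 + 1):
        for subset in itertools.combinations(range(n), size):
            a = np.array(subset)
            b = np.array([i for i in range(n) if i not in subset])
            wss = sum(((X[g] - X[g].mean(axis=0)) ** 2).sum()
                      for g in (a, b))
            best = min(best, wss)
    return best


class TestClustering:
    def test_two_far_groups_recovered_and_near_optimal(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(0.0, 0.01, size=(4, 20))
        g2 = rng.normal(5.0, 0.01, size=(4, 20))
        X = np.vstack([g1, g2])
        res = cluster_timecourses(X, 2)
        labels = [res.labels[i] for i in range(8)]
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        wss = sum(((X[[i for i in range(8) if res.labels[i] == c]]
                    - res.representatives[c]) ** 2).sum()
                  for c in res.representatives)
        assert wss <= 1.05 * brute_force_best_2partition(X) + 1e-12

    def test_singleton_clusters(self):
        X = np.arange(12.0).reshape(4, 3)
        res = cluster_timecourses(X, 4)
        assert res.k == 4
        for i in range(4):
            assert np.allclose(res.representatives[res.labels[i]], X[i])

    def test_duplicates_share_label(self):
        X = np.vstack([np.zeros(5), np.zeros(5), np.ones(5) * 9])
        res = cluster_timecourses(X, 2)
        assert res.labels[0] == res.labels[1] != res.labels[2]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 10))
        ids = list("abcdef")
        res1 = cluster_timecourses(X, 3, ids)
        perm = [3, 1, 5, 0, 2, 4]
        res2 = cluster_timecourses(X[perm], 3, [ids[i] for i in perm])
        part1 = {frozenset(k for k in ids if res1.labels[k] == c)
                 for c in set(res1.labels.values())}
        part2 = {frozenset(k for k in ids if res2.labels[k] == c)
                 for c in set(res2.labels.values())}
        assert part1 == part2

    def test_k_out_of_range(self):
        with pytest.raises(ConfigurationError):
            cluster_timecourses(np.zeros((3, 2)), 5)


class TestQualitativeFeatures:
    def test_ideal_preculture_representative_passes_both(self):
        t = np.linspace(0, 20, 400)
        t_dep = 8.0
        s2 = np.where(t < t_dep, 1.0, np.maximum(1.0 - 0.2 * (t - t_dep), 0))
        e2 = np.where(t < t_dep, 1.0 - 0.05 * t,
                      1.0 - 0.05 * t_dep + 0.1 * (t - t_dep))
        v = qualitative_features({"t": t, "S2": s2, "E2_activity": e2,
                                  "t_s1_depleted": t_dep}, "preculture")
        assert v.substrate_ok and v.enzyme_ok

    def test_flat_representative_fails(self):
        t = np.linspace(0, 20, 200)
        flat = np.ones_like(t)
        v = qualitative_features({"t": t, "S2": flat, "E2_activity": flat,
                                  "t_s1_depleted": 10.0}, "preculture")
        assert not v.substrate_ok and not v.enzyme_ok

    def test_early_s2_consumption_fails_substrate(self):
        t = np.linspace(0, 20, 400)
        s2 = 1.0 - 0.04 * t            # consumed from the start
        v = qualitative_features({"t": t, "S2": s2, "t_s1_depleted": 10.0},
                                 "preculture")
        assert v.substrate_ok is False

    def test_pulse_slowdown_and_recovery_passes(self):
        t = np.linspace(-5, 15, 800)
        rate = np.where(t < 0, 0.05,
                        np.where(t < 3, 0.005, 0.05))  # dip then recovery
        s2 = 2.0 - np.concatenate([[0], np.cumsum(np.diff(t) * rate[:-1])])
        e2 = np.where(t < 0, 1 + 0.02 * t,
                      np.where(t < 3, 1.0, 1.0 + 0.02 * (t - 3)))
        v = qualitative_features({"t": t, "S2": s2, "E2_activity": e2,
                                  "t_s1_depleted": 10.0}, "pulse")
        assert v.substrate_ok and v.enzyme_ok

    def test_unknown_scenario_kind(self):
        with pytest.raises(ConfigurationError):
            qualitative_features({"t": np.arange(3.0), "S2": np.ones(3)},
                                 "chemostat")


class TestIntersection:
    def test_set_algebra(self):
        va = [FeatureVerdict("R1", True, True),
              FeatureVerdict("R2", True, False),
              FeatureVerdict("C2", False, True)]
        vb = [FeatureVerdict("R1", True, True),
              FeatureVerdict("R2", True, True),
              FeatureVerdict("C2", False, False)]
        out = model_intersection({"e1": va, "e2": vb})
        assert out["per_experiment"]["e1"]["both"] == {"R1"}
        assert out["per_experiment"]["e2"]["both"] == {"R1", "R2"}
        assert out["across"] == {"R1"}
        for exp in ("e1", "e2"):
            per = out["per_experiment"][exp]
            assert per["both"] <= per["substrate"]
            assert per["both"] <= per["enzyme"]

    def test_empty_inputs(self):
        out = model_intersection({"e1": []})
        assert out["across"] == set()


class TestExclusions:
    def test_preculture_excludes_n2_and_pulse_excludes_a2(self):
        from diauxie.discrimination import ensemble_predictions

        pre = ensemble_predictions("preculture", variants=["N2", "R1"])
        assert "N2" not in pre and "R1" in pre
        pul = ensemble_predictions("pulse", variants=["A2", "R1"])
        assert "A2" not in pul and "R1" in pul
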