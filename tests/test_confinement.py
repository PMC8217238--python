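"""Confinement-index calibration, state segmentation, transition-probability
estimation and nanodomain-size recovery."""

import numpy as np
import pytest

from sptlock import confinement as cf
from sptlock import synthetic as syn
from sptlock import tracking as trk

DT = 0.032


def _long_trajectory(obs, pid=None):
    g = obs.sort_values("frame")
    if pid is not None:
        g = g[g.particle_id == pid]
    return trk.Trajectory(0, g.frame.to_numpy(), g.x_um.to_numpy(),
                          g.y_um.to_numpy())


class TestConfinementIndex:
    def test_static_trajectory_has_large_index_everywhere(self):
        rng = np.random.default_rng(1)
        n = 150
        tr = trk.Trajectory(
            0, np.arange(n), 5 + rng.normal(0, 0.02, n), 5 + rng.normal(0, 0.02, n)
        )
        prof = cf.confinement_index(tr, 10, 0.19, DT)
        l_star = cf.calibrate_threshold(n_sim=100_000, seed=3)
        vals = prof.l_index[~np.isnan(prof.l_index)]
        assert (vals > l_star).all()

    def test_free_trajectory_exceeds_threshold_at_nominal_rate(self):
        sc = syn.SimScenario(
            n_frames=5000, density=1 / 400, fov=(20, 20),
            boundary="reflecting", p_label=1.0, color_split=1.0, seed=6,
        )
        obs, _ = syn.simulate_trajectories(sc)
        tr = _long_trajectory(obs["A"])
        prof = cf.confinement_index(tr, 10, 0.19, DT)
        l_star = cf.calibrate_threshold(n_sim=200_000, alpha_conf=0.01, seed=3)
        vals = prof.l_index[~np.isnan(prof.l_index)]
        # overlapping windows are correlated; allow a loose factor
        assert (vals > l_star).mean() < 0.05

    def test_short_trajectory_rejected(self):
        tr = trk.Trajectory(0, np.arange(50), np.zeros(50), np.zeros(50))
        with pytest.raises(ValueError):
            cf.confinement_index(tr, 10, 0.19, DT)

    def test_edges_are_missing(self):
        rng = np.random.default_rng(2)
        n = 120
        tr = trk.Trajectory(0, np.arange(n), rng.normal(0, 0.1, n).cumsum(),
                            rng.normal(0, 0.1, n).cumsum())
        prof = cf.confinement_index(tr, 10, 0.19, DT)
        assert np.isnan(prof.l_index[:5]).all()
        assert np.isnan(prof.l_index[-4:]).all()


class TestCalibrateThreshold:
    def test_median_quantile_at_alpha_half(self):
        l_star = cf.calibrate_threshold(n_sim=50_000, alpha_conf=0.5, seed=9)
        rng = np.random.default_rng(10)
        sd = np.sqrt(2 * 0.19 * DT)
        steps = rng.normal(0, sd, (50_000, 9, 2))
        pos = np.concatenate([np.zeros((50_000, 1, 2)), steps.cumsum(axis=1)], axis=1)
        pos += rng.normal(0, 0.020, pos.shape)
        d = pos[:, 1:] - pos[:, :1]
        r2 = (d * d).sum(axis=2).max(axis=1)
        l_vals = np.maximum(0, 2.5117 * 0.19 * 0.32 / np.maximum(r2, 1e-12) - 0.2048)
        assert abs((l_vals > l_star).mean() - 0.5) < 0.02

    def test_quantile_stable_under_doubling(self):
        l1 = cf.calibrate_threshold(n_sim=150_000, seed=4)
        l2 = cf.calibrate_threshold(n_sim=300_000, seed=5)
        assert abs(l2 - l1) / l1 < 0.05

    def test_held_out_null_fpr_at_most_nominal(self):
        """The central calibration guarantee: a fresh null simulation
        exceeds L* at no more than the nominal rate (3-sigma binomial)."""
        alpha = 1e-3
        l_star = cf.calibrate_threshold(n_sim=200_000, alpha_conf=alpha, seed=1)
        rng = np.random.default_rng(999)
        n = 200_000
        sd = np.sqrt(2 * 0.19 * DT)
        steps = rng.normal(0, sd, (n, 9, 2))
        pos = np.concatenate([np.zeros((n, 1, 2)), steps.cumsum(axis=1)], axis=1)
        pos += rng.normal(0, 0.020, pos.shape)
        d = pos[:, 1:] - pos[:, :1]
        r2 = (d * d).sum(axis=2).max(axis=1)
        l_vals = np.maximum(0, 2.5117 * 0.19 * 0.32 / np.maximum(r2, 1e-12) - 0.2048)
        fpr = (l_vals > l_star).mean()
        assert fpr <= alpha + 3 * np.sqrt(alpha / n)

    def test_threshold_monotone_in_alpha(self):
        l_strict = cf.calibrate_threshold(n_sim=120_000, alpha_conf=1e-3, seed=2)
        l_loose = cf.calibrate_threshold(n_sim=120_000, alpha_conf=1e-2, seed=2)
        assert l_strict > l_loose

    def test_insufficient_n_sim_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            cf.calibrate_threshold(n_sim=1000, alpha_conf=1e-3)


class TestSegmentStates:
    def _profile(self, l_vals):
        return cf.ConfinementProfile(0, np.arange(len(l_vals)),
                                     np.asarray(l_vals, float), 10, 0.19)

    def test_all_zero_profile_all_mobile(self):
        s = cf.segment_states(self._profile(np.zeros(50)), l_star=3.0)
        assert s.sum() == 0

    def test_profile_above_threshold_throughout(self):
        s = cf.segment_states(self._profile(np.full(50, 9.0)), l_star=3.0)
        assert s.all()

    def test_short_runs_removed(self):
        l_vals = np.zeros(60)
        l_vals[10:15] = 9.0  # 5 frames < min_arrest_frames
        l_vals[30:45] = 9.0  # 15 frames
        s = cf.segment_states(self._profile(l_vals), 3.0, min_arrest_frames=10)
        assert s[10:15].sum() == 0
        assert s[30:45].all()

    def test_state_accuracy_on_simulated_two_state_trajectories(self):
        """Segmentation recovers the true mobile/arrested sequence with
        >= 90% per-frame accuracy when dwells are long vs the window."""
        trap = syn.TrapModel(p_arrest=0.02, p_release=0.05,
                             domain_diameter=0.035, d_trap=0.002)
        sc = syn.SimScenario(
            n_frames=1000, density=20 / 900, fov=(30, 30), trap=trap,
            p_label=1.0, color_split=1.0, loc_noise_sigma=0.020, seed=14,
        )
        obs, truth = syn.simulate_trajectories(sc)
        l_star = cf.calibrate_threshold(n_sim=150_000, seed=8)
        correct = 0
        total = 0
        for pid, g in obs["A"].groupby("particle_id"):
            g = g.sort_values("frame")
            tr = trk.Trajectory(int(pid), g.frame.to_numpy(),
                                g.x_um.to_numpy(), g.y_um.to_numpy())
            prof = cf.confinement_index(tr, 10, 0.19, DT)
            s = cf.segment_states(prof, l_star)
            true_s = truth.states[g.complex_id.iloc[0]]
            correct += (s == true_s).sum()
            total += len(s)
        assert total > 10_000
        assert correct / total >= 0.90


class TestEstimateTransitions:
    def test_hand_counted_example(self):
        est = cf.estimate_transitions([np.array([0, 0, 1, 1, 1, 0])])
        assert est.p_arrest == pytest.approx(0.5)
        assert est.p_release == pytest.approx(1 / 3)
        assert est.counts.tolist() == [[1, 1], [1, 2]]

    def test_all_mobile_release_undefined(self):
        est = cf.estimate_transitions([np.zeros(50, int)])
        assert est.p_arrest == 0.0
        assert np.isnan(est.p_release)

    def test_recovery_from_simulated_chain(self):
        p_a, p_r = 0.02, 0.05
        rng = np.random.default_rng(3)
        seqs = []
        n, T = 60, 500
        for _ in range(n):
            s = np.zeros(T, int)
            for t in range(1, T):
                p = p_a if s[t - 1] == 0 else p_r
                flip = rng.random() < p
                s[t] = 1 - s[t - 1] if flip else s[t - 1]
            seqs.append(s)
        est = cf.estimate_transitions(seqs)
        n0 = est.counts[0].sum()
        n1 = est.counts[1].sum()
        assert abs(est.p_arrest - p_a) < 3 * np.sqrt(p_a * (1 - p_a) / n0)
        assert abs(est.p_release - p_r) < 3 * np.sqrt(p_r * (1 - p_r) / n1)

    def test_order_invariance(self):
        seqs = [np.array([0, 1, 1, 0]), np.array([1, 1, 0, 0])]
        e1 = cf.estimate_transitions(seqs)
        e2 = cf.estimate_transitions(seqs[::-1])
        assert e1.counts.tolist() == e2.counts.tolist()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cf.estimate_transitions([np.array([0])])


class TestDomainSize:
    def test_exact_on_uniform_disc_points(self, rng):
        """Pair-displacement identity: E|x1-x2|^2 = R^2 for uniform points
        in a disc, so the estimator returns the diameter directly."""
        d_true = 0.040
        r = d_true / 2 * np.sqrt(rng.random(40_000))
        th = rng.uniform(0, 2 * np.pi, 40_000)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        res = cf.estimate_domain_size([pts], loc_noise_sigma=0.0)
        assert res["diameter_um"] == pytest.approx(d_true, rel=0.02)

    def test_noise_only_gives_near_zero_diameter(self, rng):
        pts = rng.normal(0, 0.020, (20_000, 2))
        res = cf.estimate_domain_size([pts], loc_noise_sigma=0.020)
        # plateau ~ 4 eps^2; the radicand is near zero (either sign)
        assert res["negative_radicand"] or res["diameter_um"] < 0.02

    def test_insufficient_data_missing(self):
        res = cf.estimate_domain_size([np.zeros((3, 2))], 0.02)
        assert np.isnan(res["diameter_um"])
        assert res["n_pairs"] == 0

    def test_recovery_from_trapped_simulation(self):
        """Ground-truth arrested segments from a 35 nm-domain simulation
        return the domain diameter within 20%."""
        trap = syn.TrapModel(p_arrest=0.05, p_release=0.02,
                             domain_diameter=0.035, d_trap=0.002)
        sc = syn.SimScenario(
            n_frames=1500, density=30 / 900, fov=(30, 30), trap=trap,
            p_label=1.0, color_split=1.0, loc_noise_sigma=0.020, seed=4,
        )
        obs, truth = syn.simulate_trajectories(sc)
        segs = []
        for pid, g in obs["A"].groupby("particle_id"):
            g = g.sort_values("frame")
            s = g.state.to_numpy()
            xy = g[["x_um", "y_um"]].to_numpy()
            edges = np.flatnonzero(np.diff(np.r_[0, s, 0]))
            for a, b in zip(edges[::2], edges[1::2]):
                segs.append(xy[a:b])
        res = cf.estimate_domain_size(segs, sc.loc_noise_sigma)
        assert res["n_pairs"] > 10_000
        assert res["diameter_um"] == pytest.approx(0.035, rel=0.20)
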