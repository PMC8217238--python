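"""Detection calibration, localization accuracy/precision, rendering mass
conservation and the density QC gate."""

import numpy as np
import pandas as pd
import pytest

from sptlock import detection as det
from sptlock import synthetic as syn

PX = 0.1067
SIGMA_PX = 0.139 / PX


def _spot_frame(x_px, y_px, photons=500.0, shape=(32, 32), background=0.0):
    """Noiseless frame with a single integrated-Gaussian spot."""
    rows, cols, stamp = syn._gaussian_stamp(x_px, y_px, SIGMA_PX, 8)
    frame = np.full(shape, background)
    rsel = (rows >= 0) & (rows < shape[0])
    csel = (cols >= 0) & (cols < shape[1])
    frame[np.ix_(rows[rsel], cols[csel])] += photons * stamp[np.ix_(rsel, csel)]
    return frame


class TestDetect:
    def test_zero_image_gives_no_candidates(self):
        assert len(det.detect_particles(np.zeros((64, 64)))) == 0

    def test_single_noiseless_spot_gives_one_candidate_at_peak(self):
        frame = _spot_frame(16.0, 12.0)
        cands = det.detect_particles(frame, 1e-6, 9, SIGMA_PX)
        assert len(cands) == 1
        assert (cands.row.iloc[0], cands.col.iloc[0]) == (12, 16)

    def test_false_positive_rate_on_pure_noise(self):
        """Empirical per-pixel FPR on Gaussian noise stays at or below the
        nominal rate (3-sigma Poisson tolerance)."""
        rng = np.random.default_rng(123)
        for alpha in (1e-3, 1e-2):
            n_hits = 0
            n_tests = 0
            for _ in range(6):
                frame = rng.normal(100.0, 5.0, (128, 128))
                cands = det.detect_particles(frame, alpha, 9, SIGMA_PX)
                n_hits += len(cands)
                n_tests += 124 * 124  # eligible pixels (border excluded)
            bound = alpha * n_tests + 3 * np.sqrt(alpha * n_tests)
            assert n_hits <= bound

    def test_frame_smaller_than_box_rejected(self):
        with pytest.raises(ValueError):
            det.detect_particles(np.zeros((5, 5)), box=9)

    def test_even_box_rejected(self):
        with pytest.raises(ValueError):
            det.detect_particles(np.zeros((32, 32)), box=8)


class TestLocalize:
    def test_subpixel_recovery_noiseless(self):
        """Center recovered to < 1e-3 px for off-center noiseless spots."""
        for x, y in [(16.3, 11.8), (15.72, 12.41)]:
            frame = _spot_frame(x, y)
            cands = det.detect_particles(frame, 1e-6, 9, SIGMA_PX)
            locs = det.localize(frame, cands, SIGMA_PX, 9, PX)
            assert len(locs) == 1
            assert abs(locs.x_um.iloc[0] / PX - x) < 1e-3
            assert abs(locs.y_um.iloc[0] / PX - y) < 1e-3

    def test_pixel_centered_spot_is_exact_by_symmetry(self):
        frame = _spot_frame(16.0, 12.0)
        cands = det.detect_particles(frame, 1e-6, 9, SIGMA_PX)
        locs = det.localize(frame, cands, SIGMA_PX, 9, PX)
        assert locs.x_um.iloc[0] == pytest.approx(16 * PX, abs=1e-9)
        assert locs.y_um.iloc[0] == pytest.approx(12 * PX, abs=1e-9)

    def test_reported_precision_matches_empirical_scatter(self):
        """Repeated noisy localizations of a static emitter: the empirical
        sd of fitted positions agrees with the reported precision and the
        mean position is unbiased."""
        rng = np.random.default_rng(5)
        x_true, y_true = 16.35, 12.6
        clean = _spot_frame(x_true, y_true, photons=500.0, background=10.0)
        xs, ys, precs = [], [], []
        for _ in range(250):
            noisy = rng.poisson(clean).astype(float)
            cands = det.detect_particles(noisy, 1e-6, 9, SIGMA_PX)
            locs = det.localize(noisy, cands, SIGMA_PX, 9, PX)
            if len(locs) == 1:
                xs.append(locs.x_um.iloc[0] / PX)
                ys.append(locs.y_um.iloc[0] / PX)
                precs.append(locs.precision_um.iloc[0] / PX)
        assert len(xs) > 200
        emp_sd = np.sqrt((np.var(xs) + np.var(ys)) / 2)
        rep = np.mean(precs)
        assert abs(emp_sd - rep) / rep < 0.25
        # unbiasedness: mean deviates from truth by much less than sd
        assert abs(np.mean(xs) - x_true) < 3 * emp_sd / np.sqrt(len(xs))
        assert abs(np.mean(ys) - y_true) < 3 * emp_sd / np.sqrt(len(ys))

    def test_flat_candidate_dropped(self):
        frame = np.full((32, 32), 7.0)
        cands = pd.DataFrame({"row": [16], "col": [16], "tstat": [99.0]})
        locs = det.localize(frame, cands, SIGMA_PX, 9, PX)
        assert len(locs) == 0
        assert locs.attrs["n_dropped"] == 1


class TestRenderSmlm:
    def test_mass_conservation_single_localization(self):
        locs = pd.DataFrame(
            {"frame": [0], "x_um": [1.0], "y_um": [1.5], "precision_um": [0.02]}
        )
        img = det.render_smlm_image(locs, PX, 10, fov_um=(3.0, 3.0))
        assert img.sum() == pytest.approx(1.0, abs=1e-6)

    def test_mass_conservation_many(self, rng):
        n = 500
        locs = pd.DataFrame(
            {
                "frame": np.zeros(n, int),
                "x_um": rng.uniform(1, 9, n),
                "y_um": rng.uniform(1, 9, n),
                "precision_um": np.full(n, 0.02),
            }
        )
        img = det.render_smlm_image(locs, PX, 10, fov_um=(10, 10))
        assert img.sum() == pytest.approx(n, rel=1e-6)

    def test_empty_input_gives_zero_image(self):
        img = det.render_smlm_image(
            pd.DataFrame(columns=["frame", "x_um", "y_um", "precision_um"]),
            PX, 10, fov_um=(2, 2),
        )
        assert img.sum() == 0.0

    def test_mobile_emitter_spreads_by_diffusion_length(self):
        """A static emitter renders as one tight speckle; a freely mobile
        one spreads over the diffusion length sqrt(4*D*T) ~ 3.5 um."""
        sc = syn.SimScenario(
            n_frames=500, density=1 / 225, fov=(15, 15), p_label=1.0,
            color_split=1.0, loc_noise_sigma=0.02, seed=21,
        )
        obs, _ = syn.simulate_trajectories(sc)
        mobile = obs["A"]
        static = mobile.copy()
        static["x_um"] = 7.5 + np.random.default_rng(1).normal(0, 0.02, len(static))
        static["y_um"] = 7.5 + np.random.default_rng(2).normal(0, 0.02, len(static))
        for locs, expected_extent in ((static, 0.2), (mobile, 2.0)):
            xy = locs[["x_um", "y_um"]].to_numpy()
            extent = np.sqrt(((xy - xy.mean(0)) ** 2).sum(1).mean())
            if expected_extent < 1:
                assert extent < 0.1
            else:
                assert extent > 1.0

    def test_two_close_emitters_resolved(self):
        locs = pd.DataFrame(
            {
                "frame": np.zeros(400, int),
                "x_um": np.r_[np.full(200, 1.0), np.full(200, 1.2)],
                "y_um": np.full(400, 1.0),
                "precision_um": np.full(400, 0.02),
            }
        )
        img = det.render_smlm_image(locs, PX, 10, fov_um=(2.2, 2.0))
        profile = img.sum(axis=0)
        peaks = np.flatnonzero(
            (profile > np.roll(profile, 1)) & (profile >= np.roll(profile, -1))
            & (profile > 0.2 * profile.max())
        )
        assert len(peaks) >= 2


class TestDensityQC:
    def test_below_threshold_accepted(self):
        locs = pd.DataFrame(
            {"frame": np.repeat(np.arange(10), 50),
             "x_um": 0.0, "y_um": 0.0}
        )
        qc = det.density_qc(locs, 100.0, 10)
        assert qc["density_um2"]["A"] == pytest.approx(0.5)
        assert qc["accepted"]

    def test_above_threshold_rejected(self):
        locs = pd.DataFrame(
            {"frame": np.repeat(np.arange(10), 150),
             "x_um": 0.0, "y_um": 0.0}
        )
        qc = det.density_qc(locs, 100.0, 10)
        assert qc["density_um2"]["A"] == pytest.approx(1.5)
        assert not qc["accepted"]

    def test_any_channel_over_limit_rejects(self):
        lo = pd.DataFrame({"frame": np.repeat(np.arange(5), 10),
                           "x_um": 0.0, "y_um": 0.0})
        hi = pd.DataFrame({"frame": np.repeat(np.arange(5), 200),
                           "x_um": 0.0, "y_um": 0.0})
        qc = det.density_qc({"A": lo, "B": hi}, 100.0, 5)
        assert not qc["accepted"]

    def test_simulated_density_measured_accurately(self):
        sc = syn.SimScenario(
            n_frames=50, density=0.8, fov=(20, 20), p_label=1.0,
            color_split=1.0, seed=13,
        )
        obs, _ = syn.simulate_trajectories(sc)
        qc = det.density_qc(obs["A"], sc.area, sc.n_frames)
        assert qc["density_um2"]["A"] == pytest.approx(0.8, abs=0.05)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            det.density_qc(pd.DataFrame({"frame": [0]}), 0.0, 1)
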