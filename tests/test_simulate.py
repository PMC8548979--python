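"""Synthetic cohort generator: events, determinism, planted structure."""

import numpy as np
import pytest

from nirspain.simulate import (
    SimulationConfig,
    planted_correlation_matrix,
    simulate_cohort,
    simulate_feature_table,
    simulate_subject,
    simulate_tqst_events,
)


class TestTqstEvents:
    def test_trial_duration_from_threshold(self):
        ev = simulate_tqst_events(np.array([46.0]))
        assert ev.durations[0] == pytest.approx(16.0)

    def test_paradigm_length_at_ceiling(self):
        """20 trials at 50 degC with 10 s rests span 20*20 + 19*10 s."""
        ev = simulate_tqst_events(np.full(20, 50.0))
        assert ev.end_time() == pytest.approx(20 * 20 + 19 * 10)

    def test_doubling_ramp_rate_halves_durations(self):
        thr = np.array([40.0, 46.0, 50.0])
        slow = simulate_tqst_events(thr, ramp_rate=1.0)
        fast = simulate_tqst_events(thr, ramp_rate=2.0)
        assert np.allclose(fast.durations, slow.durations / 2)

    def test_threshold_at_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            simulate_tqst_events(np.array([30.0]))

    def test_threshold_above_ceiling_rejected(self):
        with pytest.raises(ValueError, match="50"):
            simulate_tqst_events(np.array([51.0]))

    def test_rest_gap_between_trials(self):
        ev = simulate_tqst_events(np.array([40.0, 42.0]), rest_s=10.0)
        gap = ev.onsets[1] - (ev.onsets[0] + ev.durations[0])
        assert gap == pytest.approx(10.0)


class TestPlantedCorrelation:
    def test_psd_accepted(self):
        C = planted_correlation_matrix(5, [(1, 2, 0.6), (2, 3, 0.6)])
        assert np.all(np.linalg.eigvalsh(C) > -1e-12)

    def test_infeasible_triangle_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            planted_correlation_matrix(
                4, [(1, 2, 0.9), (2, 3, 0.9), (1, 3, -0.9)]
            )


class TestDeterminism:
    def test_same_seed_identical_cohort(self, tiny_cfg):
        r1, b1, _ = simulate_cohort(tiny_cfg)
        r2, b2, _ = simulate_cohort(tiny_cfg)
        assert np.array_equal(r1[0].intensities, r2[0].intensities)
        assert np.array_equal(r1[-1].intensities, r2[-1].intensities)
        assert b1.df.equals(b2.df)

    def test_different_seed_differs(self, tiny_cfg):
        r1, _, _ = simulate_cohort(tiny_cfg)
        r2, _, _ = simulate_cohort(tiny_cfg.with_(seed=tiny_cfg.seed + 1))
        assert not np.array_equal(r1[0].intensities, r2[0].intensities)


class TestCohortStructure:
    def test_default_group_sizes_give_40_subjects_80_recordings(self):
        cfg = SimulationConfig(
            rest_pre_s=4.0, breathing_s=4.0, rest_post_s=4.0, n_trials=2,
            cardiac_amp_um=0.0, mayer_amp_um=0.0, resp_amp_um=0.0,
            background_sd_um=0.0, seed=3,
        )
        recs, behavior, _ = simulate_cohort(cfg)
        assert len(recs) == 80
        assert behavior.df["subject"].nunique() == 40
        assert set(behavior.df["group"]) == {"TMB", "VRB"}

    def test_visit_effect_recovered_from_thresholds(self):
        """Planted +0.6 degC visit-2 offset shows up in paired means."""
        cfg = SimulationConfig(
            rest_pre_s=4.0, breathing_s=4.0, rest_post_s=4.0, n_trials=2,
            cardiac_amp_um=0.0, mayer_amp_um=0.0, resp_amp_um=0.0,
            background_sd_um=0.0, seed=11,
        )
        _, behavior, _ = simulate_cohort(cfg)
        df = behavior.df.pivot_table(
            index="subject", columns="visit", values="mean_threshold_c"
        )
        paired_diff = (df[2] - df[1]).mean()
        assert paired_diff == pytest.approx(0.6, abs=0.35)

    def test_thresholds_respect_thermode_range(self, tiny_cohort):
        _, behavior, _ = tiny_cohort
        thr = behavior.df["mean_threshold_c"]
        assert thr.between(30.0, 50.0).all()

    def test_null_coupling_gives_uncorrelated_threshold(self):
        cfg = SimulationConfig(
            rest_pre_s=4.0, breathing_s=4.0, rest_post_s=4.0, n_trials=2,
            cardiac_amp_um=0.0, mayer_amp_um=0.0, resp_amp_um=0.0,
            background_sd_um=0.0, coupling_slope_c_per_z=0.0, seed=5,
        )
        _, behavior, truth = simulate_cohort(cfg)
        z = truth.subject_edge_z.query("ch_a == 2 and ch_b == 5")
        merged = behavior.df.query("visit == 1").merge(z, on="subject")
        r = np.corrcoef(merged["z"], merged["mean_threshold_c"])[0, 1]
        assert abs(r) < 0.35  # null sampling band at n=40


class TestForwardModel:
    def test_noiseless_channel_is_scaled_hrf_convolution(self):
        """beta=1, no physiology: HbO equals the HRF-convolved boxcar."""
        from nirspain.activation import canonical_hrf

        cfg = SimulationConfig(
            active_channels={1: 1.0}, background_sd_um=0.0,
            cardiac_amp_um=0.0, mayer_amp_um=0.0, resp_amp_um=0.0,
            noise_sd_um=0.0, seed=0,
        )
        events = simulate_tqst_events(np.array([40.0, 42.0]))
        rec, truth = simulate_subject(cfg, events, 1)
        fs = cfg.sampling_rate
        n_t = truth["hbo_true"].shape[1]
        box = np.zeros(n_t)
        for onset, dur in zip(events.onsets, events.durations):
            i0 = int(np.ceil(onset * fs - 1e-9))
            i1 = int(np.ceil((onset + dur) * fs - 1e-9))
            box[i0:i1] = 1.0
        expected = np.convolve(box, canonical_hrf(fs))[:n_t] / fs
        expected -= expected.mean()
        assert np.max(np.abs(truth["hbo_true"][0] - expected)) < 1e-12
        assert np.allclose(truth["hbo_true"][5], 0.0)  # inactive channel

    def test_planted_edge_sample_correlation(self, tiny_cfg):
        """Planted r shows up in band-passed HbO, averaged over edges.

        Band-limited series carry roughly 2*bandwidth*T independent samples,
        so a single-edge sample correlation over 600 s has a standard error
        near 0.07; the mean over the three planted edges tightens this to
        ~0.04, making a +-0.1 check meaningful.
        """
        from nirspain.preprocess import (
            bandpass,
            intensity_to_od,
            od_to_hemoglobin,
            resample,
        )

        cfg = tiny_cfg.with_(breathing_s=600.0, rest_pre_s=10.0, seed=99)
        events = simulate_tqst_events(
            np.full(2, 40.0), start_s=cfg.rest_pre_s + cfg.breathing_s
        )
        phases = {
            "breathing": (cfg.rest_pre_s, cfg.rest_pre_s + cfg.breathing_s),
            "tqst": (cfg.rest_pre_s + cfg.breathing_s,
                     events.end_time() + 10.0),
        }
        target_z = np.array(
            [np.arctanh(r) for _, _, r in cfg.edge_set]
        )
        rec, _ = simulate_subject(cfg, events, 42, phases=phases,
                                  edge_z=target_z)
        hb = resample(
            od_to_hemoglobin(intensity_to_od(rec)).crop(*phases["breathing"]),
            4.0,
        )
        x = bandpass(hb.hbo, 4.0, 0.01, 0.08)
        sample = [
            np.corrcoef(x[a - 1], x[b - 1])[0, 1]
            for a, b, _ in cfg.edge_set
        ]
        planted = [r for _, _, r in cfg.edge_set]
        assert np.mean(sample) == pytest.approx(np.mean(planted), abs=0.1)

    def test_infeasible_edges_raise(self, tiny_cfg):
        cfg = tiny_cfg.with_(
            edge_set=[(1, 2, 0.9), (2, 3, 0.9), (1, 3, -0.9)]
        )
        events = simulate_tqst_events(np.array([40.0]))
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_subject(cfg, events, 1)


class TestFeatureTable:
    def test_shape_and_planted_columns(self):
        cfg = SimulationConfig()
        tbl, cols = simulate_feature_table(cfg, n_subjects=40, seed=1)
        assert tbl.features.shape == (40, 990)
        assert len(cols) == len(cfg.edge_set)
        assert np.allclose(tbl.features.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(tbl.features.std(axis=0), 1.0, atol=1e-12)

    def test_coupling_r2_realised(self):
        """Measured-feature R2 is the population 0.5 times the reliability.

        Edge features carry measurement noise (SD 0.1) on top of the trait
        (SD 0.3), so the regression on measured columns attenuates the
        population R2 by the reliability 0.09 / (0.09 + 0.01) = 0.9.
        """
        cfg = SimulationConfig()
        tbl, cols = simulate_feature_table(
            cfg, n_subjects=4000, r2=0.5, seed=2
        )
        from sklearn.linear_model import LinearRegression

        X = tbl.features[:, cols]
        fit = LinearRegression().fit(X, tbl.response)
        assert fit.score(X, tbl.response) == pytest.approx(0.45, abs=0.04)
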