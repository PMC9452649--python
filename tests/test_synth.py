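"""Synthetic cohort generator: determinism, conservation, plant-recover."""

import numpy as np
import pandas as pd
import pytest

from courtload import synth
from courtload.calibrate import estimate_vo2_for_speed, fit_calibration
from helpers import recover_band_minutes


class TestConfig:
    def test_occupancy_must_sum_to_one(self):
        with pytest.raises(ValueError, match="occupancy"):
            synth.SimConfig(band_occupancy_targets={
                r: (0.5, 0.2, 0.1, 0.1, 0.05) for r in synth.ROLES})

    def test_positive_counts_required(self):
        with pytest.raises(ValueError):
            synth.SimConfig(n_players_per_team={"women": 0, "men": 13},
                            role_mix={"women": {"starter": 0, "in_rotation": 0,
                                                "out_rotation": 0},
                                      "men": {"starter": 5, "in_rotation": 4,
                                              "out_rotation": 4}})


class TestRoster:
    def test_default_roster_has_23_players(self):
        roster, truth = synth.generate_roster(synth.SimConfig(seed=1))
        assert len(roster) == 23
        assert (roster.team == "women").sum() == 10
        assert (roster.team == "men").sum() == 13
        assert (roster.mass_kg > 0).all()
        assert set(truth) == set(roster.player_id)

    def test_same_seed_identical(self):
        r1, _ = synth.generate_roster(synth.SimConfig(seed=4))
        r2, _ = synth.generate_roster(synth.SimConfig(seed=4))
        pd.testing.assert_frame_equal(r1, r2)

    def test_degenerate_mass_distribution(self):
        cfg = synth.SimConfig(seed=1, mass_dist={"women": (76.5, 0.0),
                                                 "men": (96.2, 0.0)})
        roster, _ = synth.generate_roster(cfg)
        assert (roster.loc[roster.team == "women", "mass_kg"] == 76.5).all()


class TestYoyoStages:
    def test_noiseless_stages_on_planted_line_and_recovered(self):
        cfg = synth.SimConfig(seed=2, calib_noise_sd_n=0.0)
        _, truth = synth.generate_roster(cfg)
        pid, pt = next(iter(truth.items()))
        stages = synth.generate_yoyo_stages(pt, cfg,
                                            np.random.default_rng(0), pid)
        assert len(stages) >= 4
        assert np.all(np.diff(stages.speed_kmh) > 0)
        vo2 = np.array([estimate_vo2_for_speed(s) for s in stages.speed_kmh])
        expected = (vo2 - pt["intercept_vo2"]) / pt["slope_vo2_per_n"]
        np.testing.assert_allclose(stages.avf_net_n, expected, atol=1e-9)
        # downstream OLS refit recovers the planted coefficients
        m = fit_calibration(stages.avf_net_n.to_numpy(), vo2,
                            vo2_rest=3.5, vo2_max=pt["vo2max"])
        assert m.slope == pytest.approx(pt["slope_vo2_per_n"], abs=1e-6)
        assert m.intercept == pytest.approx(pt["intercept_vo2"], abs=1e-6)

    def test_too_few_stages_rejected(self):
        cfg = synth.SimConfig(seed=2)
        _, truth = synth.generate_roster(cfg)
        pt = dict(next(iter(truth.values())), stage_speeds=(10.0,))
        with pytest.raises(ValueError, match="stages"):
            synth.generate_yoyo_stages(pt, cfg, np.random.default_rng(0), "X")


class TestSessionTrace:
    def test_bad_occupancy_rejected(self):
        cfg = synth.SimConfig(seed=0)
        with pytest.raises(ValueError, match="sum to 1"):
            synth.generate_session_trace(80.0, 0.55,
                                         np.array([0.5, 0.2, 0.1, 0.1, 0.05]),
                                         120, cfg, np.random.default_rng(0))

    def test_all_inactive_session_recovered_as_inactive(self):
        cfg = synth.SimConfig(seed=0, noise_sd=0.0)
        occ = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        tr, truth = synth.generate_session_trace(
            80.0, 0.55, occ, 300, cfg, np.random.default_rng(3),
            player_id="P")
        rec = recover_band_minutes(tr, 80.0, 0.55)
        assert rec[0] == pytest.approx(5.0, abs=2 / 60)
        assert rec[1:].sum() <= 2 / 60

    def test_duration_and_truth_conservation(self):
        cfg = synth.SimConfig(seed=0)
        occ = np.asarray(cfg.band_occupancy_targets["starter"])
        tr, truth = synth.generate_session_trace(
            90.0, 0.5, occ, 600, cfg, np.random.default_rng(4), player_id="P")
        assert tr.duration_s == pytest.approx(600, abs=1)
        assert sum(truth["planted_band_minutes"]) == pytest.approx(10.0,
                                                                   abs=1 / 60)

    @pytest.mark.parametrize("noise", [0.0, 0.02])
    def test_plant_recover_full_session(self, noise):
        """Pipeline recovers planted band minutes: exactly (2-epoch slack)
        without noise, within 2 percentage points with realistic noise on
        a 90-minute session."""
        cfg = synth.SimConfig(seed=0, noise_sd=noise)
        occ = np.asarray(cfg.band_occupancy_targets["starter"])
        tr, truth = synth.generate_session_trace(
            85.0, 0.55, occ, 5400, cfg, np.random.default_rng(5),
            player_id="P")
        rec = recover_band_minutes(tr, 85.0, 0.55)
        planted = np.asarray(truth["planted_band_minutes"])
        if noise == 0.0:
            assert np.abs(rec - planted).max() <= 2 / 60 + 1e-9
        else:
            assert np.abs(rec - planted).max() / 90.0 * 100 <= 2.0


class TestCohort:
    def test_observation_counts_mirror_study(self, small_cohort):
        full = synth.generate_cohort(synth.SimConfig(seed=11))
        counts = full.manifest.groupby(
            ["session_type", "season_period"]).size()
        assert counts[("match", "regular")] == 387
        assert counts[("match", "finals")] == 75
        assert counts[("training", "regular")] == 445
        assert counts[("training", "finals")] == 113

    def test_every_observation_has_truth_and_trace_seed(self, small_cohort):
        c = small_cohort
        obs = c.ground_truth["observations"]
        keys = set(zip(c.manifest.session_id, c.manifest.player_id))
        assert set(zip(obs.session_id, obs.player_id)) == keys
        assert set(c._trace_seed) == keys

    def test_truth_band_minutes_sum_to_duration(self, small_cohort):
        obs = small_cohort.ground_truth["observations"]
        bands = [c for c in obs.columns
                 if c.startswith("planted_") and c.endswith("_min")
                 and c != "planted_duration_min"]
        total = obs[bands].sum(axis=1)
        assert np.abs(total - obs.planted_duration_min).max() <= 1 / 60 + 1e-9

    def test_null_minutes_shift_centers_md_on_zero(self):
        """With no planted finals shift the estimated MD is near zero."""
        from courtload import stats as st
        mds = []
        for rep in range(40):
            df = synth.simulate_minutes_cohort(shift=0.0, seed=900 + rep)
            reg = df[df.season_period == "regular"]
            fin = df[df.season_period == "finals"]
            mds.append(st.bootstrap_mean_difference(
                reg.minutes_played, fin.minutes_played, reps=200,
                seed=rep).md)
        assert abs(np.mean(mds)) < 0.6

    def test_trace_determinism_byte_identical(self, small_cohort, tmp_path):
        c2 = synth.generate_cohort(synth.SimConfig.scaled(seed=7, factor=0.25))
        key = sorted(small_cohort._trace_seed)[0]
        t1 = small_cohort.trace(*key)
        t2 = c2.trace(*key)
        assert np.array_equal(t1.samples, t2.samples)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        small_cohort.write_trace_csv(*key, p1)
        c2.write_trace_csv(*key, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_cohort_tables_written(self, small_cohort, tmp_path):
        small_cohort.write(tmp_path)
        for name in ("roster.csv", "calibration.csv", "manifest.csv",
                     "sessions.csv", "ground_truth.json"):
            assert (tmp_path / name).exists()
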