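"""Force-to-VO2 calibration and personalized intensity banding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from courtload import calibrate as cal
from courtload.signal import ForceSeries


def _model(slope=0.1, intercept=3.5, vo2_rest=3.5, vo2_max=53.5):
    return cal.CalibrationModel(player_id="P", slope=slope,
                                intercept=intercept, r_squared=1.0,
                                vo2_rest=vo2_rest, vo2_max=vo2_max)


class TestVo2Estimation:
    def test_rest_and_running_values(self):
        assert cal.estimate_vo2_for_speed(0.0) == pytest.approx(3.5)
        # 12 km/h is 200 m/min: 0.2*200 + 3.5
        assert cal.estimate_vo2_for_speed(12.0) == pytest.approx(43.5)

    def test_monotone_in_speed(self):
        speeds = np.linspace(0, 20, 50)
        vo2 = [cal.estimate_vo2_for_speed(s) for s in speeds]
        assert np.all(np.diff(vo2) > 0)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            cal.estimate_vo2_for_speed(-1.0)


class TestCalibrationFit:
    def test_exact_line_recovered(self):
        x = np.array([50.0, 100.0, 150.0, 200.0])
        m = cal.fit_calibration(x, 0.1 * x + 2.0, vo2_rest=3.5, vo2_max=53.5)
        assert m.slope == pytest.approx(0.1, abs=1e-12)
        assert m.intercept == pytest.approx(2.0, abs=1e-10)
        assert m.r_squared == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable|equal"):
            cal.fit_calibration([100.0, 100.0], [40.0, 45.0], 3.5, 53.5)
        with pytest.raises(ValueError):
            cal.fit_calibration([100.0], [40.0], 3.5, 53.5)

    def test_negative_slope_warns(self):
        x = np.array([50.0, 100.0, 150.0])
        with pytest.warns(UserWarning, match="slope"):
            cal.fit_calibration(x, -0.05 * x + 50.0, 3.5, 53.5)

    def test_noise_shrinks_with_more_stages(self):
        """Slope error decreases as calibration stages accumulate."""
        errs = {}
        for n in (4, 40):
            reps = []
            for seed in range(40):
                r = np.random.default_rng(seed)
                x = np.linspace(50, 450, n)
                y = 0.12 * x + 3.5 + r.normal(0, 2.0, n)
                reps.append(abs(cal.fit_calibration(x, y, 3.5, 53.5).slope
                                - 0.12))
            errs[n] = np.mean(reps)
        assert errs[40] < errs[4]


class TestReservePercent:
    def test_anchors_and_boundary(self):
        assert cal.vo2r_percent(3.5, 3.5, 53.5) == 0.0
        assert cal.vo2r_percent(53.5, 3.5, 53.5) == 100.0
        assert cal.vo2r_percent(8.5, 3.5, 53.5) == pytest.approx(10.0)

    def test_invalid_reserve_rejected(self):
        with pytest.raises(ValueError):
            cal.vo2r_percent(10.0, 50.0, 40.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(pct=hst.floats(0.0, 150.0))
    def test_round_trip(self, pct):
        vo2 = cal.vo2_at_reserve_pct(pct, 3.5, 53.5)
        assert cal.vo2r_percent(vo2, 3.5, 53.5) == pytest.approx(pct,
                                                                 abs=1e-9)


class TestBands:
    def test_algebraic_inversion_of_edges(self):
        bands = cal.bands_for_player(_model())
        # 10% edge: VO2 8.5 -> F = (8.5 - 3.5)/0.1 = 50 N
        assert bands.thresholds_n == pytest.approx([50.0, 200.0, 450.0, 500.0])
        assert len(bands.thresholds_n) == 4
        assert np.all(np.diff(bands.thresholds_n) > 0)

    def test_doubling_slope_halves_threshold_spacing(self):
        b1 = cal.bands_for_player(_model(slope=0.1))
        b2 = cal.bands_for_player(_model(slope=0.2))
        np.testing.assert_allclose(np.diff(b2.thresholds_n),
                                   np.diff(b1.thresholds_n) / 2)

    def test_nonpositive_slope_rejected(self):
        m = _model()
        m.slope = -0.1
        with pytest.raises(ValueError):
            cal.bands_for_player(m)


class TestClassification:
    def test_boundary_belongs_to_lower_band(self):
        bands = cal.bands_for_player(_model())
        fs = ForceSeries("P", "S", 1.0,
                         [50.0, 50.0001, 500.0, 500.1, 0.0, 200.0])
        labels = cal.classify_epochs(fs, bands)
        # exactly at the 10% edge -> inactive; just above -> light;
        # at 100% -> maximal; above -> supramaximal
        assert labels.tolist() == [0, 1, 3, 4, 0, 1]

    def test_all_zero_series_fully_inactive(self):
        bands = cal.bands_for_player(_model())
        fs = ForceSeries("P", "S", 1.0, np.zeros(120))
        mins = cal.band_minutes(cal.classify_epochs(fs, bands), 1.0)
        assert mins.tolist() == [2.0, 0.0, 0.0, 0.0, 0.0]

    def test_player_mismatch_rejected(self):
        bands = cal.bands_for_player(_model())
        fs = ForceSeries("Q", "S", 1.0, np.zeros(10))
        with pytest.raises(ValueError, match="player"):
            cal.classify_epochs(fs, bands)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=hst.integers(0, 10 ** 6))
    def test_partition_exhaustive_and_exclusive(self, seed):
        """Every non-negative force lands in exactly one of the 5 bands."""
        bands = cal.bands_for_player(_model())
        vals = np.random.default_rng(seed).uniform(0, 700, 200)
        labels = cal.classify_epochs(ForceSeries("P", "S", 1.0, vals), bands)
        assert labels.min() >= 0 and labels.max() <= 4
        assert cal.band_minutes(labels, 1.0).sum() * 60 == pytest.approx(
            len(vals))
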