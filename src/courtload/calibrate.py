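"""Individualized force-to-oxygen-uptake calibration and intensity bands.

Each player completes an incremental shuttle-run (Yo-Yo IR1 style) wearing
the accelerometer.  Per stage speed we know an estimated VO2 (ACSM running
equation by default) and measure the net-force intensity AvF_NET, giving an
ordinary-least-squares linear mapping VO2 = slope * AvF_NET + intercept per
player.  Percent VO2-reserve band edges (10/40/90/100 %VO2R) are inverted
through this line into newton thresholds, so every epoch of a session can
be classified as inactive, light, moderate-vigorous, maximal, or
supramaximal with player-specific cut-points.

Boundary semantics follow the band definitions: a value exactly at an edge
belongs to the lower band (inactive is <=10 %VO2R; higher bands open with a
strict ">").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .signal import ForceSeries

BAND_LABELS = ("inactive", "light", "moderate_vigorous", "maximal", "supramaximal")
DEFAULT_BAND_EDGES_PCT = (10.0, 40.0, 90.0, 100.0)
VO2_REST_DEFAULT = 3.5  # ml/kg/min, 1 MET


@dataclass
class CalibrationModel:
    """Per-player linear AvF_NET <-> VO2 relationship plus VO2 rest/max."""

    player_id: str
    slope: float          # ml/kg/min per newton
    intercept: float      # ml/kg/min
    r_squared: float
    vo2_rest: float       # ml/kg/min
    vo2_max: float        # ml/kg/min

    def __post_init__(self) -> None:
        if self.vo2_rest <= 0 or self.vo2_max <= self.vo2_rest:
            raise ValueError("require vo2_max > vo2_rest > 0")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def vo2_at_force(self, force_n: float) -> float:
        return self.slope * force_n + self.intercept

    def force_at_vo2(self, vo2: float) -> float:
        return (vo2 - self.intercept) / self.slope


@dataclass
class IntensityBands:
    """Personalized newton thresholds for the five %VO2R bands."""

    player_id: str
    edges_pct: tuple      # %VO2R band edges, e.g. (10, 40, 90, 100)
    thresholds_n: np.ndarray  # same length, strictly increasing newtons

    def __post_init__(self) -> None:
        self.thresholds_n = np.asarray(self.thresholds_n, dtype=float)
        if self.thresholds_n.size != len(self.edges_pct):
            raise ValueError("one newton threshold per %VO2R edge")
        if np.any(np.diff(self.thresholds_n) <= 0):
            raise ValueError("newton thresholds must be strictly increasing")

    @property
    def labels(self) -> tuple:
        return BAND_LABELS


def estimate_vo2_for_speed(speed_kmh: float, vo2_rest: float = VO2_REST_DEFAULT) -> float:
    """Estimated running VO2 (ml/kg/min) at a given speed.

    ACSM running equation: VO2 = 0.2 * speed(m/min) + vo2_rest.  Any other
    speed->VO2 mapping can be injected where calibrations are built.
    """
    if speed_kmh < 0:
        raise ValueError("speed must be non-negative")
    speed_m_min = speed_kmh * 1000.0 / 60.0
    return 0.2 * speed_m_min + vo2_rest


def fit_calibration(avf_net: np.ndarray, vo2: np.ndarray, vo2_rest: float,
                    vo2_max: float, player_id: str = "") -> CalibrationModel:
    """OLS fit of VO2 on AvF_NET over the calibration stages."""
    avf_net = np.asarray(avf_net, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    if avf_net.size < 2 or vo2.size != avf_net.size:
        raise ValueError("need >=2 paired (AvF_NET, VO2) stages")
    if np.ptp(avf_net) == 0:
        raise ValueError("calibration unidentifiable: all AvF_NET values equal")
    res = spstats.linregress(avf_net, vo2)
    if res.slope <= 0:
        warnings.warn(
            f"non-positive calibration slope ({res.slope:.4g}) for "
            f"player {player_id!r}", stacklevel=2)
    return CalibrationModel(player_id=player_id, slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            vo2_rest=vo2_rest, vo2_max=vo2_max)


def vo2r_percent(vo2: float, vo2_rest: float, vo2_max: float) -> float:
    """Percent of oxygen-uptake reserve; may exceed 100 (supramaximal)."""
    if vo2_max <= vo2_rest:
        raise ValueError("vo2_max must exceed vo2_rest")
    return 100.0 * (vo2 - vo2_rest) / (vo2_max - vo2_rest)


def vo2_at_reserve_pct(pct: float, vo2_rest: float, vo2_max: float) -> float:
    """Inverse of :func:`vo2r_percent`."""
    return vo2_rest + pct / 100.0 * (vo2_max - vo2_rest)


def bands_for_player(model: CalibrationModel,
                     edges_pct: tuple = DEFAULT_BAND_EDGES_PCT) -> IntensityBands:
    """Convert %VO2R band edges into personalized newton thresholds.

    Each edge percentage maps to a VO2 via the player's reserve, then
    inverts through the calibration line: F_edge = (VO2_edge - b) / a.
    Negative inversions clamp to 0 (force is non-negative by construction).
    """
    if model.slope <= 0:
        raise ValueError("cannot invert a non-positive calibration slope")
    vo2_edges = [vo2_at_reserve_pct(p, model.vo2_rest, model.vo2_max)
                 for p in edges_pct]
    thresholds = np.maximum(0.0, [model.force_at_vo2(v) for v in vo2_edges])
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("band thresholds not strictly increasing after inversion")
    return IntensityBands(player_id=model.player_id, edges_pct=tuple(edges_pct),
                          thresholds_n=thresholds)


def classify_epochs(force: ForceSeries, bands: IntensityBands) -> np.ndarray:
    """Label every epoch with one of the five intensity bands.

    Returns an integer array (0=inactive ... 4=supramaximal).  A value
    exactly at a threshold belongs to the band below it.
    """
    if bands.player_id and force.player_id and bands.player_id != force.player_id:
        raise ValueError(
            f"bands for player {bands.player_id!r} applied to force series of "
            f"{force.player_id!r}")
    # side='left': index = number of thresholds strictly below the value,
    # so a value equal to a threshold stays in the lower band.
    return np.searchsorted(bands.thresholds_n, force.values, side="left")


def band_minutes(labels: np.ndarray, epoch_length: float) -> np.ndarray:
    """Minutes spent in each of the five bands."""
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=len(BAND_LABELS))
    return counts * epoch_length / 60.0
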