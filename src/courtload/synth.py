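"""Synthetic cohort generator with known ground truth.

Real player recordings behind this kind of study are not publicly
deposited, so every downstream stage is exercised against simulated data
with planted truth: a two-team roster (10 women, 13 men), per-player
incremental shuttle-run calibration stages lying on a known linear
force-to-VO2 relationship, and 100 Hz triaxial traces built from
piecewise-stationary bouts whose epoch-level intensity occupies each
%VO2R band for planted fractions of the session.

Key design points:

* Within a bout the two horizontal axes carry a quadrature sinusoid pair
  (A sin, A cos) at a passband carrier frequency, so the filtered
  resultant magnitude is exactly constant at A; the vertical axis carries
  the 1 g gravity component that the band-pass must remove.  Amplitudes
  are pre-divided by the known zero-phase filter gain at the carrier, so
  the planted intensity survives filtering exactly.
* Bout lengths are truncated log-normal (minimum 2 s), drawn from
  separate active/recovery distributions, mirroring the highly
  intermittent structure of basketball without claiming biomechanical
  realism.
* Role and season-period effects are planted additively on minutes
  played and band occupancy, with signs mirroring starters gaining and
  out-rotation bench players losing involvement in finals.
* Everything is deterministic under the config seed; traces are produced
  on demand from per-observation child seeds so a full cohort does not
  require holding ~1000 raw traces in memory.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .signal import AccelTrace, G_TO_MS2, bandpass_gain
from .calibrate import BAND_LABELS, estimate_vo2_for_speed, VO2_REST_DEFAULT

ROLES = ("starter", "in_rotation", "out_rotation")


def _stringify_keys(obj):
    """Make nested dicts JSON-safe (tuple keys -> '|'-joined strings)."""
    if isinstance(obj, dict):
        return {("|".join(map(str, k)) if isinstance(k, tuple) else str(k)):
                _stringify_keys(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_stringify_keys(v) for v in obj]
    return obj

# Yo-Yo IR1 style incremental speed ladder (km/h)
YOYO_SPEED_LADDER = (10.0, 12.0, 13.0, 13.5, 14.0, 14.5, 15.0, 15.5, 16.0)

def _norm(fracs) -> tuple:
    a = np.asarray(fracs, dtype=float)
    return tuple(a / a.sum())


# Band occupancy fractions per match role (normalized to exact unit sum;
# columns follow BAND_LABELS: inactive, light, moderate-vigorous,
# maximal, supramaximal).
_MATCH_OCCUPANCY = {
    "starter": _norm((0.6056, 0.1572, 0.1611, 0.0320, 0.0440)),
    "in_rotation": _norm((0.7657, 0.0859, 0.0990, 0.0212, 0.0283)),
    "out_rotation": _norm((0.8513, 0.0941, 0.0416, 0.0059, 0.0069)),
}
_TRAINING_OCCUPANCY = _norm((0.6071, 0.1665, 0.1716, 0.0264, 0.0284))

# Additive finals shifts on occupancy fractions (sum to zero per role) and
# on minutes played, mirroring the direction of role-dependent changes:
# starters gain playing time and high-intensity work in finals,
# out-rotation bench players lose both.
_MATCH_PERIOD_OCCUPANCY_SHIFT = {
    "starter": (-0.049, 0.007, 0.025, 0.012, 0.005),
    "in_rotation": (0.0, 0.0, 0.0, 0.0, 0.0),
    "out_rotation": (0.012, -0.002, -0.003, -0.003, -0.004),
}
_TRAINING_PERIOD_OCCUPANCY_SHIFT = (-0.027, 0.002, 0.015, 0.007, 0.003)
_MINUTES_SHIFT = {"starter": 4.4, "in_rotation": 0.0, "out_rotation": -2.1}

# Minutes-played sampling per role: mean, sd, lower, upper (truncation
# bounds keep the drawn minutes consistent with the role definition).
_MINUTES_DIST = {
    "starter": (30.0, 4.0, 12.0, 44.0),
    "in_rotation": (17.5, 3.5, 10.0, 30.0),
    "out_rotation": (4.5, 2.2, 0.2, 9.5),
}

# Session counts per (team, type, period), mirroring a two-team season.
_SESSION_COUNTS = {
    ("women", "training", "regular"): 26,
    ("women", "match", "regular"): 20,
    ("women", "training", "finals"): 4,
    ("women", "match", "finals"): 3,
    ("men", "training", "regular"): 24,
    ("men", "match", "regular"): 20,
    ("men", "training", "finals"): 8,
    ("men", "match", "finals"): 4,
}

# Player-session observation totals per (type, period) after attendance.
_OBSERVATION_TARGETS = {
    ("match", "regular"): 387,
    ("match", "finals"): 75,
    ("training", "regular"): 445,
    ("training", "finals"): 113,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study."""

    seed: int = 0
    n_players_per_team: dict = field(
        default_factory=lambda: {"women": 10, "men": 13})
    sample_rate: float = 100.0
    match_duration_min: float = 94.0
    training_duration_min: float = 90.0
    epoch_length: float = 1.0
    role_mix: dict = field(default_factory=lambda: {
        "women": {"starter": 5, "in_rotation": 3, "out_rotation": 2},
        "men": {"starter": 5, "in_rotation": 4, "out_rotation": 4},
    })
    mass_dist: dict = field(default_factory=lambda: {
        "women": (76.5, 19.5), "men": (96.2, 16.4)})
    max_speed_dist: dict = field(default_factory=lambda: {
        "women": (14.0, 1.0), "men": (15.0, 1.0)})
    vo2_rest: float = VO2_REST_DEFAULT
    yoyo_speed_ladder: tuple = YOYO_SPEED_LADDER
    calib_noise_sd_n: float = 5.0
    band_occupancy_targets: dict = field(
        default_factory=lambda: {r: _MATCH_OCCUPANCY[r] for r in ROLES})
    training_occupancy: tuple = _TRAINING_OCCUPANCY
    period_effects: dict = field(default_factory=lambda: {
        "match_occupancy_shift": dict(_MATCH_PERIOD_OCCUPANCY_SHIFT),
        "training_occupancy_shift": _TRAINING_PERIOD_OCCUPANCY_SHIFT,
        "minutes_shift": dict(_MINUTES_SHIFT),
    })
    minutes_dist: dict = field(default_factory=lambda: dict(_MINUTES_DIST))
    session_counts: dict = field(default_factory=lambda: dict(_SESSION_COUNTS))
    observation_targets: dict = field(
        default_factory=lambda: dict(_OBSERVATION_TARGETS))
    bout_length_dist: dict = field(default_factory=lambda: {
        "active": (6.0, 4.0), "recovery": (12.0, 8.0)})
    bout_min_s: float = 2.0
    # Dirichlet precision for per-session occupancy draws around the role
    # target (higher = less session-to-session spread; 0 disables).  At 60
    # the inactive fraction varies by ~6 percentage points SD, matching
    # the wide interquartile ranges seen in real match data.
    occupancy_concentration: float = 60.0
    noise_sd: float = 0.02  # g, per axis
    carrier_band_hz: tuple = (1.0, 4.0)
    filter_low: float = 0.1
    filter_high: float = 15.0
    filter_order: int = 4

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for role, occ in self.band_occupancy_targets.items():
            if abs(sum(occ) - 1.0) > 1e-9:
                raise ValueError(
                    f"band occupancy for role {role!r} sums to {sum(occ)}, not 1")
        if abs(sum(self.training_occupancy) - 1.0) > 1e-9:
            raise ValueError("training occupancy must sum to 1")
        for team, n in self.n_players_per_team.items():
            if n <= 0:
                raise ValueError(f"non-positive player count for team {team!r}")
            if sum(self.role_mix[team].values()) != n:
                raise ValueError(f"role mix for {team!r} must sum to {n}")
        for val, name in [(self.sample_rate, "sample_rate"),
                          (self.match_duration_min, "match_duration_min"),
                          (self.training_duration_min, "training_duration_min"),
                          (self.epoch_length, "epoch_length"),
                          (self.bout_min_s, "bout_min_s")]:
            if val <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def scaled(cls, seed: int = 0, factor: float = 0.1, **overrides) -> "SimConfig":
        """A reduced-scale config for fast end-to-end runs.

        Session durations and counts shrink by ``factor``; attendance
        targets shrink proportionally.  The occupancy targets, role
        structure and planted effects are untouched.
        """
        counts = {k: max(1, int(round(v * factor)))
                  for k, v in _SESSION_COUNTS.items()}
        caps = {}
        base = cls(seed=seed)
        for (team, stype, period), n in counts.items():
            caps[(stype, period)] = caps.get((stype, period), 0) \
                + n * base.n_players_per_team[team]
        targets = {k: max(1, min(caps[k], int(round(v * factor))))
                   for k, v in _OBSERVATION_TARGETS.items()}
        kw = dict(seed=seed, session_counts=counts, observation_targets=targets,
                  match_duration_min=10.0, training_duration_min=10.0)
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# roster and calibration stages


def generate_roster(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Sample the two-team roster.

    Returns the roster table (player_id, team, sex, mass_kg,
    vo2max_mlkgmin) and per-player planted truth: role, the linear
    force-to-VO2 coefficients, and the acceleration intensity (in g) at
    which the player reaches VO2max.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows, truth = [], {}
    for team, n in config.n_players_per_team.items():
        mu, sd = config.mass_dist[team]
        roles = [r for r in ROLES for _ in range(config.role_mix[team][r])]
        for i in range(n):
            pid = f"{team[0].upper()}{i + 1:02d}"
            mass = float(np.clip(rng.normal(mu, sd), 45.0, 140.0))
            s_mu, s_sd = config.max_speed_dist[team]
            max_speed = float(rng.normal(s_mu, s_sd))
            ladder = [s for s in config.yoyo_speed_ladder if s <= max_speed]
            if len(ladder) < 4:
                ladder = list(config.yoyo_speed_ladder[:4])
            vo2max = estimate_vo2_for_speed(ladder[-1], config.vo2_rest)
            # acceleration (g) at which this player works at VO2max
            g_max = float(np.clip(rng.normal(0.55, 0.05), 0.40, 0.70))
            slope = (vo2max - config.vo2_rest) / (mass * G_TO_MS2 * g_max)
            rows.append(dict(player_id=pid, team=team,
                             sex="F" if team == "women" else "M",
                             mass_kg=round(mass, 1),
                             vo2max_mlkgmin=round(vo2max, 2)))
            truth[pid] = dict(role=roles[i], mass_kg=round(mass, 1),
                              vo2max=vo2max, g_at_vo2max=g_max,
                              slope_vo2_per_n=slope,
                              intercept_vo2=config.vo2_rest,
                              stage_speeds=tuple(ladder))
    return pd.DataFrame(rows), truth


def generate_yoyo_stages(player_truth: dict, config: SimConfig,
                         rng: np.random.Generator,
                         player_id: str) -> pd.DataFrame:
    """Calibration stage records for one player.

    Stage AvF_NET is a noisy linear function of the stage's estimated VO2
    through the planted per-player coefficients, so an OLS refit recovers
    them exactly when ``calib_noise_sd_n`` is zero.
    """
    speeds = player_truth["stage_speeds"]
    if len(speeds) < 2:
        raise ValueError("need at least 2 calibration stages")
    slope, b = player_truth["slope_vo2_per_n"], player_truth["intercept_vo2"]
    rows = []
    for k, s in enumerate(speeds, start=1):
        vo2 = estimate_vo2_for_speed(s, config.vo2_rest)
        avf = (vo2 - b) / slope + rng.normal(0.0, config.calib_noise_sd_n)
        rows.append(dict(player_id=player_id, stage=k, speed_kmh=s,
                         avf_net_n=max(avf, 1e-6)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-session bout plan and trace synthesis

# Band mid-points and supramaximal target as fractions of the reserve
_BAND_MID_FRACTION = (0.05, 0.25, 0.65, 0.95, 1.15)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _draw_bout_length(rng: np.random.Generator, dist: tuple, min_s: float) -> int:
    mu, sig = _lognormal_params(*dist)
    return int(round(max(min_s, rng.lognormal(mu, sig))))


def plan_session(occupancy: np.ndarray, duration_s: int,
                 config: SimConfig, rng: np.random.Generator) -> list:
    """Schedule alternating bouts hitting the target band occupancy.

    Returns a list of (band_index, length_s) whose lengths sum exactly to
    ``duration_s`` and whose per-band totals match ``occupancy *
    duration_s`` to within bout-rounding (a few seconds).
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if abs(occupancy.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy fractions must sum to 1")
    remaining = occupancy * duration_s
    bouts, total = [], 0
    while total < duration_s:
        probs = np.clip(remaining, 0.0, None)
        if probs.sum() <= 0:
            band = 0
        else:
            band = int(rng.choice(len(occupancy), p=probs / probs.sum()))
        dist = config.bout_length_dist["recovery" if band == 0 else "active"]
        length = _draw_bout_length(rng, dist, config.bout_min_s)
        length = int(min(length, max(remaining[band], 1), duration_s - total))
        length = max(length, 1)
        bouts.append((band, length))
        remaining[band] -= length
        total += length
    # Sessions open and close in recovery: swap a recovery bout to each
    # edge (totals unchanged).  This also keeps the zero-phase filter's
    # pad-edge transient (slow tail of the 0.1 Hz high-pass) from
    # contaminating high-intensity epochs at the trace boundaries.
    rec = [i for i, (b, _) in enumerate(bouts) if b == 0]
    if rec and bouts[0][0] != 0:
        bouts[0], bouts[rec[0]] = bouts[rec[0]], bouts[0]
        rec = [i for i, (b, _) in enumerate(bouts) if b == 0]
    if rec and bouts[-1][0] != 0:
        bouts[-1], bouts[rec[-1]] = bouts[rec[-1]], bouts[-1]
    return bouts


def planted_band_seconds(bouts: list, n_bands: int = len(BAND_LABELS)) -> np.ndarray:
    out = np.zeros(n_bands)
    for band, length in bouts:
        out[band] += length
    return out


def generate_session_trace(mass_kg: float, g_at_vo2max: float,
                           occupancy: np.ndarray, duration_s: int,
                           config: SimConfig, rng: np.random.Generator, *,
                           player_id: str = "", session_id: str = "",
                           ) -> tuple[AccelTrace, dict]:
    """Synthesize one session trace plus its ground truth.

    Band thresholds in acceleration units are fractions (0.1, 0.4, 0.9,
    1.0) of the player's ``g_at_vo2max``; each bout targets its band's
    mid-point, pre-compensated for the zero-phase filter gain at the
    bout's carrier frequency so the recovered epoch intensity lands
    mid-band after filtering.
    """
    fs = config.sample_rate
    bouts = plan_session(occupancy, int(duration_s), config, rng)
    n_total = int(round(duration_s * fs))
    ax = np.empty(n_total)
    ay = np.empty(n_total)
    phase = 0.0
    pos = 0
    for band, length in bouts:
        n = int(round(length * fs))
        n = min(n, n_total - pos)
        f_c = rng.uniform(*config.carrier_band_hz)
        gain = bandpass_gain(f_c, fs, config.filter_low, config.filter_high,
                             config.filter_order)
        amp = _BAND_MID_FRACTION[band] * g_at_vo2max / gain
        ph = phase + 2 * np.pi * f_c * np.arange(n) / fs
        ax[pos:pos + n] = amp * np.sin(ph)
        ay[pos:pos + n] = amp * np.cos(ph)
        phase = (ph[-1] + 2 * np.pi * f_c / fs) if n else phase
        pos += n
    ax, ay = ax[:pos], ay[:pos]
    az = np.ones(pos)  # gravity on the vertical axis
    samples = np.column_stack([ax, ay, az])
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, samples.shape)
    trace = AccelTrace(player_id=player_id, session_id=session_id,
                       sample_rate=fs, samples=samples)
    seconds = planted_band_seconds(bouts)
    truth = dict(player_id=player_id, session_id=session_id,
                 planted_band_minutes=(seconds / 60.0).tolist(),
                 planted_duration_min=duration_s / 60.0,
                 occupancy=np.asarray(occupancy, float).tolist())
    return trace, truth


# ---------------------------------------------------------------------------
# cohort assembly


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def _season_dates(team: str, config: SimConfig) -> list:
    """(session_id, type, period, date, duration_min) for one team."""
    base = _dt.date(2019, 4, 2)  # a Tuesday
    out = []
    for period in ("regular", "finals"):
        week0 = 0 if period == "regular" else 20
        n_tr = config.session_counts[(team, "training", period)]
        n_ma = config.session_counts[(team, "match", period)]
        n_weeks = max(n_ma, int(np.ceil(n_tr / 2)), 1)
        for i in range(n_tr):
            week = week0 + (i * n_weeks) // n_tr
            day = 0 if i % 2 == 0 else 2  # Tue / Thu
            out.append((f"{team[0].upper()}-T-{period[0]}{i + 1:02d}",
                        "training", period,
                        base + _dt.timedelta(weeks=week, days=day)))
        for i in range(n_ma):
            week = week0 + (i * n_weeks) // n_ma
            out.append((f"{team[0].upper()}-M-{period[0]}{i + 1:02d}",
                        "match", period,
                        base + _dt.timedelta(weeks=week, days=4)))
    return out


@dataclass
class Cohort:
    """A generated synthetic study: tables, ground truth, trace factory."""

    config: SimConfig
    roster: pd.DataFrame
    calibration: pd.DataFrame
    sessions: pd.DataFrame
    manifest: pd.DataFrame
    ground_truth: dict
    _trace_seed: dict = field(repr=False, default_factory=dict)

    def trace(self, session_id: str, player_id: str) -> AccelTrace:
        """Deterministically (re)generate the raw trace for one observation."""
        key = (session_id, player_id)
        if key not in self._trace_seed:
            raise KeyError(f"no observation for {key}")
        seed_list, occupancy, duration_s = self._trace_seed[key]
        pt = self.ground_truth["players"][player_id]
        rng = np.random.default_rng(np.random.SeedSequence(seed_list))
        trace, _ = generate_session_trace(
            pt["mass_kg"], pt["g_at_vo2max"], occupancy, duration_s,
            self.config, rng, player_id=player_id, session_id=session_id)
        return trace

    def write(self, outdir) -> None:
        """Write roster/calibration/sessions/manifest CSVs + truth JSON."""
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.roster.to_csv(outdir / "roster.csv", index=False)
        self.calibration.to_csv(outdir / "calibration.csv", index=False)
        self.sessions.to_csv(outdir / "sessions.csv", index=False)
        self.manifest.to_csv(outdir / "manifest.csv", index=False)
        truth = dict(self.ground_truth)
        truth["observations"] = self.ground_truth["observations"].to_dict(
            orient="records")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(_stringify_keys(truth), fh, indent=1, default=str)

    def write_trace_csv(self, session_id: str, player_id: str, path) -> None:
        tr = self.trace(session_id, player_id)
        t = np.arange(tr.n_samples) / tr.sample_rate
        pd.DataFrame({"timestamp_s": t, "ax_g": tr.samples[:, 0],
                      "ay_g": tr.samples[:, 1], "az_g": tr.samples[:, 2]}
                     ).to_csv(path, index=False, float_format="%.5f")


def _occupancy_for(role: str, stype: str, period: str, config: SimConfig
                   ) -> np.ndarray:
    if stype == "match":
        occ = np.array(config.band_occupancy_targets[role], float)
        if period == "finals":
            occ = occ + np.array(
                config.period_effects["match_occupancy_shift"][role], float)
    else:
        occ = np.array(config.training_occupancy, float)
        if period == "finals":
            occ = occ + np.array(
                config.period_effects["training_occupancy_shift"], float)
    occ = np.clip(occ, 0.0, None)
    return occ / occ.sum()


def generate_cohort(config: SimConfig | None = None) -> Cohort:
    """Generate the full synthetic study.

    Produces the roster, per-player calibration stages, the season session
    calendar for both teams, an attendance manifest hitting the configured
    observation totals per (session type, period), and per-observation
    ground truth (role, planted minutes played, planted band minutes).
    Traces are generated on demand via :meth:`Cohort.trace`.
    """
    config = config or SimConfig()
    roster, player_truth = generate_roster(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    calib = pd.concat(
        [generate_yoyo_stages(player_truth[pid], config, rng, pid)
         for pid in roster.player_id], ignore_index=True)

    srows = []
    for team in config.n_players_per_team:
        for sid, stype, period, date in _season_dates(team, config):
            if stype == "match":
                dur = config.match_duration_min
            else:
                dur = float(np.round(rng.triangular(
                    0.93 * config.training_duration_min,
                    config.training_duration_min,
                    1.11 * config.training_duration_min)))
            srows.append(dict(session_id=sid, team=team, session_type=stype,
                              season_period=period, date=date.isoformat(),
                              duration_min=dur))
    sessions = pd.DataFrame(srows)

    # attendance: draw player-session slots per stratum to hit the targets
    players_by_team = {t: roster.loc[roster.team == t, "player_id"].tolist()
                       for t in config.n_players_per_team}
    mrows, trace_seeds, obs_truth = [], {}, []
    for (stype, period), target in config.observation_targets.items():
        strat = sessions[(sessions.session_type == stype)
                         & (sessions.season_period == period)]
        slots = [(s.session_id, pid, s.duration_min)
                 for s in strat.itertuples()
                 for pid in players_by_team[s.team]]
        if target > len(slots):
            raise ValueError(
                f"observation target {target} exceeds capacity {len(slots)} "
                f"for {(stype, period)}")
        chosen = rng.choice(len(slots), size=target, replace=False)
        for j in sorted(chosen):
            sid, pid, dur = slots[j]
            role = player_truth[pid]["role"]
            if stype == "match":
                mean, sd, lo, hi = config.minutes_dist[role]
                shift = (config.period_effects["minutes_shift"][role]
                         if period == "finals" else 0.0)
                minutes = round(_truncnorm(rng, mean + shift, sd, lo, hi), 1)
                started = role == "starter"
            else:
                minutes, started = dur, None
            date = strat.loc[strat.session_id == sid, "date"].iloc[0]
            mrows.append(dict(session_id=sid, session_type=stype,
                              season_period=period, date=date, player_id=pid,
                              started=started, minutes_played=minutes))
            occ = _occupancy_for(role, stype, period, config)
            if config.occupancy_concentration > 0:
                # session-level realization around the role/period target
                occ = rng.dirichlet(np.maximum(occ, 1e-6)
                                    * config.occupancy_concentration)
                occ = occ / occ.sum()
            child = int(rng.integers(0, 2 ** 31))
            trace_seeds[(sid, pid)] = ([config.seed, 3, child], occ, int(dur * 60))
            plan_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 3, child]))
            bouts = plan_session(occ, int(dur * 60), config, plan_rng)
            secs = planted_band_seconds(bouts)
            obs_truth.append(dict(
                session_id=sid, player_id=pid, session_type=stype,
                season_period=period, role=role,
                planted_minutes_played=minutes,
                planted_duration_min=dur,
                **{f"planted_{b}_min": s / 60.0
                   for b, s in zip(BAND_LABELS, secs)},
                planted_minutes_shift=(
                    config.period_effects["minutes_shift"][role]
                    if stype == "match" and period == "finals" else 0.0)))

    manifest = pd.DataFrame(mrows)
    truth = dict(players=player_truth,
                 observations=pd.DataFrame(obs_truth),
                 config=asdict(config))
    return Cohort(config=config, roster=roster, calibration=calib,
                  sessions=sessions, manifest=manifest, ground_truth=truth,
                  _trace_seed=trace_seeds)


# ---------------------------------------------------------------------------
# summary-level simulators for statistical calibration studies
#
# The heavy Monte Carlo work (type-I error, power, bootstrap coverage)
# operates on the statistical unit — the per player-session summary — so
# these generators plant effects directly at that level instead of paying
# for raw 100 Hz synthesis inside every replicate.


def simulate_lmm_dataset(n_subjects: int = 23, obs_per_subject: int = 15,
                         icc: float = 0.05, effect: float = 0.0,
                         seed: int = 0) -> pd.DataFrame:
    """Balanced within-subject two-condition dataset with unit total SD.

    ``effect`` is the condition difference in total-SD units; the subject
    random intercept carries ``icc`` of the total variance.
    """
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n_subjects), obs_per_subject)
    half = obs_per_subject // 2
    cond = np.tile(np.r_[np.zeros(obs_per_subject - half), np.ones(half)],
                   n_subjects)
    b = rng.normal(0.0, np.sqrt(icc), n_subjects)[subj]
    y = b + effect * cond + rng.normal(0.0, np.sqrt(1.0 - icc), subj.size)
    return pd.DataFrame(dict(player_id=[f"P{s:02d}" for s in subj],
                             condition=cond.astype(int), y=y))


def simulate_minutes_cohort(shift: float = 4.4, seed: int = 0,
                            n_subjects: int = 10, n_regular: int = 189,
                            n_finals: int = 35, sd_total: float = 6.6,
                            icc: float = 0.05) -> pd.DataFrame:
    """Starter playing-time observations with a planted finals shift.

    Observation counts and spread mirror the starter stratum of a two-team
    season (about 19 regular and 3-4 finals match observations per
    starter; total SD from the reported interquartile range of starter
    minutes).  The finals mean is the regular mean plus ``shift`` exactly.
    """
    rng = np.random.default_rng(seed)
    sd_b = sd_total * np.sqrt(icc)
    sd_w = sd_total * np.sqrt(1.0 - icc)
    b = rng.normal(0.0, sd_b, n_subjects)
    rows = []
    for period, n, mu in (("regular", n_regular, 30.0),
                          ("finals", n_finals, 30.0 + shift)):
        subj = np.arange(n) % n_subjects
        y = mu + b[subj] + rng.normal(0.0, sd_w, n)
        for s, v in zip(subj, y):
            rows.append(dict(player_id=f"S{s:02d}", season_period=period,
                             minutes_played=v))
    return pd.DataFrame(rows)


def simulate_factorial_cohort(seed: int = 0, obs_per_cell: int = 8,
                              finals_frac: float = 0.2, icc: float = 0.1,
                              sd_total: float = 1.0,
                              period_effect=None) -> pd.DataFrame:
    """Role x team x period summaries for decision-tree simulations.

    ``period_effect(role, team)`` gives the finals-minus-regular shift for
    that cell (in ``sd_total`` units); a callable varying with role only
    plants a period x role interaction, varying with both factors plants
    the full 3-way interaction, and a constant plants a pure main effect.
    """
    rng = np.random.default_rng(seed)
    if period_effect is None:
        period_effect = lambda role, team: 0.0
    sd_b = sd_total * np.sqrt(icc)
    sd_w = sd_total * np.sqrt(1.0 - icc)
    role_mix = {"women": {"starter": 5, "in_rotation": 3, "out_rotation": 2},
                "men": {"starter": 5, "in_rotation": 4, "out_rotation": 4}}
    rows = []
    pid = 0
    for team, mix in role_mix.items():
        for role, n in mix.items():
            for _ in range(n):
                pid += 1
                b = rng.normal(0.0, sd_b)
                n_fin = max(1, int(round(obs_per_cell * finals_frac)))
                for period, m in (("regular", obs_per_cell), ("finals", n_fin)):
                    eff = period_effect(role, team) if period == "finals" else 0.0
                    y = b + eff + rng.normal(0.0, sd_w, m)
                    rows.extend(dict(player_id=f"P{pid:02d}", team=team,
                                     role=role, season_period=period, y=v)
                                for v in y)
    return pd.DataFrame(rows)
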