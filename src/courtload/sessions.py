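"""Per player-session demand summaries and player-role assignment.

A session summary — the unit of statistical analysis — carries the mean
net-force intensity (AvF_NET), impulse, absolute minutes and percentage of
monitored time in each of the five %VO2R bands, plus the player's role
and the season period.  Match roles follow the conventional split into
starters (on court at tip-off), in-rotation bench (>=10 min played) and
out-rotation bench; a player's training role is the role they most often
played across the season's matches.

The percentage denominator is the full monitored duration (first-quarter
start to final-quarter end for matches, whole session for training), so
band percentages always total 100.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .signal import AccelTrace, ForceSeries, session_intensity, session_impulse
from .calibrate import BAND_LABELS, band_minutes

ROLE_PRIORITY = ("starter", "in_rotation", "out_rotation")


def parse_started(value) -> bool:
    """Coerce a manifest 'started' entry (bool or CSV string) to bool."""
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("true", "1", "yes"):
            return True
        if v in ("false", "0", "no", ""):
            return False
        raise ValueError(f"unrecognized started flag {value!r}")
    if pd.isna(value):
        return False
    return bool(value)


@dataclass
class SessionSummary:
    session_id: str
    player_id: str
    team: str
    session_type: str
    season_period: str
    date: str
    role: str
    minutes_played: float
    monitored_duration_min: float
    avf_net_n: float
    impulse_kns: float
    inactive_min: float = 0.0
    light_min: float = 0.0
    moderate_vigorous_min: float = 0.0
    maximal_min: float = 0.0
    supramaximal_min: float = 0.0
    inactive_pct: float = 0.0
    light_pct: float = 0.0
    moderate_vigorous_pct: float = 0.0
    maximal_pct: float = 0.0
    supramaximal_pct: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def match_window(trace: AccelTrace, start_s: float, end_s: float) -> AccelTrace:
    """Trim a match trace to first-quarter start .. final-quarter end."""
    if not (0 <= start_s < end_s <= trace.duration_s + 1e-9):
        raise ValueError(
            f"window [{start_s}, {end_s}] s outside trace extent "
            f"[0, {trace.duration_s:.1f}] s")
    i0 = int(round(start_s * trace.sample_rate))
    i1 = int(round(end_s * trace.sample_rate))
    if i1 <= i0:
        raise ValueError("empty match window")
    from dataclasses import replace
    return replace(trace, samples=trace.samples[i0:i1])


def assign_match_role(started: bool, minutes_played: float) -> str:
    """starter if on court at tip-off; bench split at 10 minutes played."""
    if minutes_played < 0:
        raise ValueError("minutes_played must be non-negative")
    if started:
        return "starter"
    return "in_rotation" if minutes_played >= 10.0 else "out_rotation"


def assign_training_role(match_roles) -> str:
    """Modal match role; ties break toward the higher-involvement role."""
    roles = list(match_roles)
    if not roles:
        raise ValueError("no match roles observed for player")
    counts = Counter(roles)
    best = max(counts.values())
    for role in ROLE_PRIORITY:
        if counts.get(role, 0) == best:
            return role
    raise ValueError(f"unknown roles {sorted(counts)}")  # pragma: no cover


def summarize_session(record: dict, labels: np.ndarray, force: ForceSeries
                      ) -> SessionSummary:
    """Assemble one SessionSummary from classified epochs and force series."""
    for key in ("session_id", "player_id"):
        rv = record.get(key)
        fv = getattr(force, key)
        if rv and fv and rv != fv:
            raise ValueError(f"{key} mismatch: record {rv!r} vs series {fv!r}")
    labels = np.asarray(labels, dtype=int)
    if labels.size != force.n_epochs:
        raise ValueError("label/epoch length mismatch")
    mins = band_minutes(labels, force.epoch_length)
    monitored = force.duration_s / 60.0
    pct = 100.0 * mins / monitored
    kwargs = {f"{b}_min": float(m) for b, m in zip(BAND_LABELS, mins)}
    kwargs.update({f"{b}_pct": float(p) for b, p in zip(BAND_LABELS, pct)})
    return SessionSummary(
        session_id=record["session_id"], player_id=record["player_id"],
        team=record.get("team", ""), session_type=record.get("session_type", ""),
        season_period=record.get("season_period", ""),
        date=str(record.get("date", "")), role=record.get("role", ""),
        minutes_played=float(record.get("minutes_played", monitored)),
        monitored_duration_min=monitored,
        avf_net_n=session_intensity(force),
        impulse_kns=session_impulse(force), **kwargs)


def season_roles(manifest: pd.DataFrame) -> pd.Series:
    """Per-player match role per observation plus modal training role.

    Returns a Series mapping player_id -> training role, derived from the
    manifest's match rows (started flag + minutes played).
    """
    matches = manifest[manifest.session_type == "match"]
    if matches.empty:
        raise ValueError("manifest contains no matches to derive roles from")
    per_obs = matches.apply(
        lambda r: assign_match_role(parse_started(r.started),
                                    float(r.minutes_played)),
        axis=1)
    return per_obs.groupby(matches.player_id).agg(
        lambda roles: assign_training_role(roles))


def weekly_training_load(summaries: pd.DataFrame) -> dict:
    """Median (Q1-Q3) training-session duration and weekly total per period.

    ``summaries`` needs columns season_period, date, monitored_duration_min
    restricted (or restrictable) to training sessions.
    """
    df = summaries
    if "session_type" in df.columns:
        df = df[df.session_type == "training"]
    if "session_id" in df.columns:
        # schedule-level quantity: one row per session, not per player
        df = df.drop_duplicates("session_id")
    out = {}
    for period, grp in df.groupby("season_period"):
        if grp.empty:
            continue
        dur = grp.monitored_duration_min.to_numpy(float)
        dates = pd.to_datetime(grp.date)
        weekly = grp.assign(week=dates.dt.isocalendar().week.values) \
                    .groupby(["week"]).monitored_duration_min.sum().to_numpy(float)
        out[period] = dict(
            session_median=float(np.median(dur)),
            session_q1=float(np.percentile(dur, 25)),
            session_q3=float(np.percentile(dur, 75)),
            weekly_median=float(np.median(weekly)),
            weekly_q1=float(np.percentile(weekly, 25)),
            weekly_q3=float(np.percentile(weekly, 75)),
            n_sessions=int(len(grp)))
    return out
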