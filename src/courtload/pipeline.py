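"""End-to-end orchestration: raw inputs -> summaries -> statistics.

Two entry points:

* :func:`process_cohort` runs the full chain in memory on a synthetic
  :class:`~courtload.synth.Cohort` (traces generated on demand).
* :func:`run_pipeline` runs from files on disk (trace CSVs, roster,
  calibration, manifest) driven by a :class:`PipelineConfig`, writing
  ``summaries.csv``, ``stats.json`` and markdown tables — the layout the
  command-line interface exposes.

All outputs are plain CSV/JSON so external re-analysis can consume them
unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate as cal
from . import sessions as ses
from . import signal as sig
from . import stats as st
from .calibrate import BAND_LABELS

log = logging.getLogger("courtload")

#: Table-style analysis variables; (column, has_zeros) pairs.  Variables
#: containing zeros (playing time, maximal and supramaximal activity in
#: both absolute and relative terms) receive the +1 offset before the log.
MATCH_VARIABLES = [
    ("minutes_played", True), ("avf_net_n", False), ("impulse_kns", False),
    ("inactive_min", False), ("inactive_pct", False),
    ("light_min", False), ("light_pct", False),
    ("moderate_vigorous_min", False), ("moderate_vigorous_pct", False),
    ("maximal_min", True), ("maximal_pct", True),
    ("supramaximal_min", True), ("supramaximal_pct", True),
]
TRAINING_VARIABLES = [v for v in MATCH_VARIABLES if v[0] != "minutes_played"]


@dataclass
class PipelineConfig:
    """File locations and processing settings for a disk-based run."""

    traces_dir: str
    roster: str
    calibration: str
    manifest: str
    output_dir: str
    filter_low: float = 0.1
    filter_high: float = 15.0
    filter_order: int = 4
    epoch_length: float = 1.0
    vo2_rest: float = cal.VO2_REST_DEFAULT
    band_edges_pct: tuple = cal.DEFAULT_BAND_EDGES_PCT
    bootstrap_reps: int = 1000
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(roster: pd.DataFrame, calibration: pd.DataFrame,
                    manifest: pd.DataFrame, sample_rate: float = 100.0,
                    filter_high: float = 15.0) -> ValidationReport:
    """Schema and consistency checks; errors are fatal, warnings are not."""
    rep = ValidationReport()
    for df, name, cols in [
            (roster, "roster", {"player_id", "team", "mass_kg"}),
            (calibration, "calibration", {"player_id", "speed_kmh", "avf_net_n"}),
            (manifest, "manifest", {"session_id", "session_type",
                                    "season_period", "player_id",
                                    "minutes_played"})]:
        missing = cols - set(df.columns)
        if missing:
            rep.errors.append(f"{name} missing columns: {sorted(missing)}")
    if rep.errors:
        return rep
    if (roster.mass_kg <= 0).any():
        rep.errors.append("roster contains non-positive body mass")
    if roster.player_id.duplicated().any():
        rep.errors.append("duplicate player_id in roster")
    dup = manifest.duplicated(["session_id", "player_id"])
    if dup.any():
        rep.errors.append(
            f"duplicate (session_id, player_id) rows in manifest: "
            f"{manifest.loc[dup, ['session_id', 'player_id']].values.tolist()}")
    unknown = set(manifest.player_id) - set(roster.player_id)
    if unknown:
        rep.errors.append(f"manifest references unknown players: {sorted(unknown)}")
    uncal = set(manifest.player_id) - set(calibration.player_id)
    if uncal:
        rep.errors.append(
            f"players with sessions but no calibration: {sorted(uncal)}")
    if sample_rate <= 2 * filter_high:
        rep.errors.append(
            f"sample rate {sample_rate} Hz below Nyquist for "
            f"{filter_high} Hz cutoff")
    elif sample_rate < 4 * filter_high:
        rep.warnings.append(
            f"sample rate {sample_rate} Hz leaves a thin margin above the "
            f"{filter_high} Hz cutoff")
    return rep


def build_calibrations(roster: pd.DataFrame, calibration: pd.DataFrame,
                       vo2_rest: float = cal.VO2_REST_DEFAULT,
                       band_edges_pct: tuple = cal.DEFAULT_BAND_EDGES_PCT,
                       ) -> dict:
    """Per-player calibration model + newton band thresholds.

    VO2 per stage comes from the ACSM running equation at the stage speed;
    VO2max defaults to the estimated VO2 of the final completed stage.
    """
    out = {}
    for pid, stages in calibration.groupby("player_id"):
        stages = stages.sort_values("speed_kmh")
        vo2 = np.array([cal.estimate_vo2_for_speed(s, vo2_rest)
                        for s in stages.speed_kmh])
        model = cal.fit_calibration(stages.avf_net_n.to_numpy(), vo2,
                                    vo2_rest=vo2_rest, vo2_max=float(vo2[-1]),
                                    player_id=str(pid))
        out[pid] = (model, cal.bands_for_player(model, band_edges_pct))
    return out


def summarize_trace(trace: sig.AccelTrace, record: dict, mass_kg: float,
                    bands: cal.IntensityBands, *, filter_low: float = 0.1,
                    filter_high: float = 15.0, filter_order: int = 4,
                    epoch_length: float = 1.0) -> ses.SessionSummary:
    """Filter -> resultant -> force epochs -> band labels -> summary."""
    filt = sig.bandpass_filter(trace, filter_low, filter_high, filter_order)
    mag = sig.resultant_acceleration(filt)
    force = sig.compute_force_series(mag, mass_kg, trace.sample_rate,
                                     epoch_length, player_id=trace.player_id,
                                     session_id=trace.session_id)
    labels = cal.classify_epochs(force, bands)
    return ses.summarize_session(record, labels, force)


def process_cohort(cohort, *, filter_low: float = 0.1,
                   filter_high: float = 15.0, filter_order: int = 4,
                   epoch_length: float = 1.0) -> pd.DataFrame:
    """Process every manifest observation of a synthetic cohort.

    Returns one SessionSummary row per player-session, with match roles
    from the started flag and minutes played, and training roles as each
    player's modal match role.
    """
    rep = validate_inputs(cohort.roster, cohort.calibration, cohort.manifest,
                          cohort.config.sample_rate, filter_high)
    if not rep.ok:
        raise ValueError("invalid cohort inputs: " + "; ".join(rep.errors))
    calibs = build_calibrations(cohort.roster, cohort.calibration,
                                cohort.config.vo2_rest)
    mass = cohort.roster.set_index("player_id").mass_kg
    team = cohort.roster.set_index("player_id").team
    training_roles = ses.season_roles(cohort.manifest)
    rows = []
    for r in cohort.manifest.itertuples():
        if r.session_type == "match":
            role = ses.assign_match_role(ses.parse_started(r.started),
                                         float(r.minutes_played))
        else:
            role = training_roles[r.player_id]
        record = dict(session_id=r.session_id, player_id=r.player_id,
                      team=team[r.player_id], session_type=r.session_type,
                      season_period=r.season_period, date=r.date, role=role,
                      minutes_played=float(r.minutes_played))
        trace = cohort.trace(r.session_id, r.player_id)
        summary = summarize_trace(
            trace, record, float(mass[r.player_id]),
            calibs[r.player_id][1], filter_low=filter_low,
            filter_high=filter_high, filter_order=filter_order,
            epoch_length=epoch_length)
        rows.append(summary.to_dict())
    return pd.DataFrame(rows)


def analyze_summaries(summaries: pd.DataFrame, seed: int = 0,
                      alpha: float = 0.05) -> dict:
    """Run the statistical pipeline on processed summaries.

    Per session type and response variable: Shapiro-Wilk screen, log
    transform (offset 1 where zeros occur), the interaction decision tree
    with participant-random-intercept models, and the post-hoc
    bootstrap/Bonferroni/effect-size comparisons the chosen branch calls
    for.
    """
    results = {}
    for stype, variables in (("match", MATCH_VARIABLES),
                             ("training", TRAINING_VARIABLES)):
        sub = summaries[summaries.session_type == stype]
        if sub.empty:
            continue
        var_names = [v for v, _ in variables]
        # the offset rule is "variables containing zero values": the
        # declared list covers the full-scale study (playing time,
        # maximal/supramaximal activity); any further zero-containing
        # variable in this dataset joins it
        offset_vars = set(v for v, z in variables if z)
        offset_vars |= {v for v in var_names if (sub[v] == 0).any()}
        normality = {}
        for v in var_names:
            try:
                w, p, fails = st.normality_check(sub[v])
                normality[v] = dict(W=w, p=p, non_normal=fails)
            except ValueError as exc:
                normality[v] = dict(error=str(exc))
        logged, offsets = st.log_transform(sub, var_names, offset_vars)
        for v in var_names:
            logged[f"raw__{v}"] = sub[v].to_numpy()
        out_vars = {}
        for v in var_names:
            try:
                tree = st.interaction_decision_tree(
                    logged, v, response_raw=f"raw__{v}", alpha=alpha,
                    seed=seed)
            except ValueError as exc:
                out_vars[v] = dict(error=str(exc))
                continue
            out_vars[v] = dict(
                branch=tree.branch,
                offset=offsets[v],
                full_model=tree.full_model.terms.to_dict(orient="records"),
                reduced_model=(tree.reduced_model.terms.to_dict(orient="records")
                               if tree.reduced_model is not None else None),
                comparisons=[dataclasses.asdict(c) for c in tree.comparisons],
                log=tree.log,
            )
            for entry in tree.log:
                log.info("%s/%s: %s", stype, v, entry)
        results[stype] = dict(normality=normality, variables=out_vars,
                              n_obs=int(len(sub)))
    return results


# ---------------------------------------------------------------------------
# disk-based run


def load_trace_csv(path, player_id: str = "", session_id: str = "",
                   sample_rate: float | None = None) -> sig.AccelTrace:
    """Read a trace CSV (timestamp_s, ax_g, ay_g, az_g)."""
    df = pd.read_csv(path)
    need = {"timestamp_s", "ax_g", "ay_g", "az_g"}
    if not need <= set(df.columns):
        raise ValueError(f"trace {path} missing columns {need - set(df.columns)}")
    if sample_rate is None:
        dt = np.diff(df.timestamp_s.to_numpy())
        if dt.size == 0 or np.ptp(dt) > 1e-6 * dt.mean() + 1e-9:
            raise ValueError(f"trace {path} is not uniformly sampled")
        sample_rate = 1.0 / float(dt.mean())
    return sig.AccelTrace(player_id=player_id, session_id=session_id,
                          sample_rate=float(sample_rate),
                          samples=df[["ax_g", "ay_g", "az_g"]].to_numpy())


def run_pipeline(config: PipelineConfig) -> dict:
    """Disk-to-disk run: read inputs, process every observation, analyze,
    and write summaries.csv / stats.json / tables/*.md.

    Trace files are expected as ``<traces_dir>/<session_id>__<player_id>.csv``.
    Deterministic given identical inputs and seed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    roster = pd.read_csv(config.roster)
    calibration = pd.read_csv(config.calibration)
    manifest = pd.read_csv(config.manifest)
    rep = validate_inputs(roster, calibration, manifest,
                          filter_high=config.filter_high)
    for w in rep.warnings:
        log.warning(w)
    if not rep.ok:
        raise ValueError("invalid inputs: " + "; ".join(rep.errors))
    calibs = build_calibrations(roster, calibration, config.vo2_rest,
                                config.band_edges_pct)
    mass = roster.set_index("player_id").mass_kg
    team = roster.set_index("player_id").team
    training_roles = ses.season_roles(manifest)
    rows = []
    for r in manifest.itertuples():
        path = Path(config.traces_dir) / f"{r.session_id}__{r.player_id}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing trace file {path}")
        trace = load_trace_csv(path, r.player_id, r.session_id)
        role = (ses.assign_match_role(ses.parse_started(r.started),
                                      float(r.minutes_played))
                if r.session_type == "match" else training_roles[r.player_id])
        record = dict(session_id=r.session_id, player_id=r.player_id,
                      team=team[r.player_id], session_type=r.session_type,
                      season_period=r.season_period, date=r.date, role=role,
                      minutes_played=float(r.minutes_played))
        rows.append(summarize_trace(
            trace, record, float(mass[r.player_id]), calibs[r.player_id][1],
            filter_low=config.filter_low, filter_high=config.filter_high,
            filter_order=config.filter_order,
            epoch_length=config.epoch_length).to_dict())
    summaries = pd.DataFrame(rows)
    summaries.to_csv(outdir / "summaries.csv", index=False)
    stats_out = analyze_summaries(summaries, seed=config.seed,
                                  alpha=config.alpha)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=1, default=_json_default)
    write_report_tables(summaries, outdir / "tables")
    return dict(summaries=summaries, stats=stats_out,
                validation=dataclasses.asdict(rep))


def write_report_tables(summaries: pd.DataFrame, outdir) -> None:
    """Median (Q1-Q3) descriptive tables per session type, markdown."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stype, variables in (("match", MATCH_VARIABLES),
                             ("training", TRAINING_VARIABLES)):
        sub = summaries[summaries.session_type == stype]
        if sub.empty:
            continue
        tab = st.report_table(sub, [v for v, _ in variables],
                              group_cols=("role", "season_period"))
        (outdir / f"{stype}_demands.md").write_text(
            tab.to_markdown(index=False) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
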