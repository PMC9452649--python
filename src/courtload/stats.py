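"""Statistical pipeline for regular-season vs finals demand comparisons.

The analysis chain mirrors standard repeated-measures practice in athlete
monitoring: Shapiro-Wilk normality screening, natural-log transformation
(offset of 1 for variables containing zeros), participant-random-intercept
linear mixed models with season period, player role and team as fixed
factors, an interaction decision tree that decides whether follow-up runs
per role (and team), Bonferroni-adjusted post-hocs, percentile-bootstrap
mean differences (1,000 resamples, cluster-aware), Cohen's d on the log
scale, partial eta squared for the mixed-model fixed effects, and the
design-effect sample-size calculation for clustered observations.

Mixed models are estimated by REML through statsmodels' ``MixedLM``;
fixed-effect F statistics use sum-to-zero factor coding (Type-III style
marginal tests) with a residual denominator-degrees-of-freedom
approximation (n_obs - rank(X)).  The simulation-based calibration
checks in the test-suite validate this approximation empirically rather
than asserting software-exact degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.formula.api as smf
from statsmodels.stats.power import TTestIndPower
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LmmResult", "Comparison", "PowerDesign",
    "normality_check", "log_transform", "fit_lmm", "partial_eta_squared",
    "eta_category", "cohens_d_log", "d_category", "bonferroni",
    "bootstrap_mean_difference", "interaction_decision_tree",
    "sample_size_lmm", "format_median_iqr", "report_table",
    "lmm_condition_pvalue", "empirical_power",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class LmmResult:
    """Fixed-effect test table from a participant-random-intercept model."""

    response: str
    terms: pd.DataFrame  # term, F, df_num, df_den, p, eta_p2, eta_category
    loglik: float
    converged: bool
    n_obs: int

    def term(self, name: str) -> pd.Series:
        hit = self.terms[self.terms.term == name]
        if hit.empty:
            raise KeyError(f"no fixed-effect term {name!r}; "
                           f"have {list(self.terms.term)}")
        return hit.iloc[0]

    def p(self, name: str) -> float:
        return float(self.term(name).p)


@dataclass
class Comparison:
    """Pairwise regular-vs-finals contrast."""

    label: str
    md: float
    ci_low: float
    ci_high: float
    p_adjusted: float | None = None
    d: float | None = None
    d_category: str | None = None
    n_a: int = 0
    n_b: int = 0


@dataclass
class PowerDesign:
    """Design-effect sample-size solution for clustered observations."""

    effect_size: float
    power: float
    alpha: float
    k_subjects: int
    icc: float
    base_total_n: float
    obs_per_subject: int
    total_n: int


# ---------------------------------------------------------------------------
# screening and transformation


def normality_check(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk W, p, and whether the variable fails normality."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no distribution to test")
    w, p = spstats.shapiro(x)
    return float(w), float(p), bool(p < alpha)


def log_transform(frame: pd.DataFrame, variables, offset_variables=()
                  ) -> tuple[pd.DataFrame, dict]:
    """Natural-log transform analysis variables.

    Variables listed in ``offset_variables`` (those containing zeros, such
    as minutes played and the maximal/supramaximal band times) get an
    offset of 1 before the log; all others are logged directly.  Returns
    the transformed copy and the applied offset per variable (invertible
    via exp(y) - offset).
    """
    out = frame.copy()
    offsets = {}
    offset_variables = set(offset_variables)
    for var in variables:
        x = out[var].to_numpy(dtype=float)
        if np.any(x < 0):
            raise ValueError(f"variable {var!r} contains negative values")
        off = 1.0 if var in offset_variables else 0.0
        if off == 0.0 and np.any(x == 0):
            raise ValueError(
                f"variable {var!r} contains zeros; list it in "
                f"offset_variables to apply the +1 offset")
        out[var] = np.log(x + off)
        offsets[var] = off
    return out, offsets


# ---------------------------------------------------------------------------
# effect sizes


def partial_eta_squared(f_stat: float, df_num: float, df_den: float,
                        reported: float | None = None) -> tuple[float, str]:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2).

    If ``reported`` is given (a previously published value for the same
    test), a mismatch at 2-decimal rounding is warned about rather than
    silently adopted.
    """
    if f_stat < 0 or df_num <= 0 or df_den <= 0:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    eta = (f_stat * df_num) / (f_stat * df_num + df_den)
    if reported is not None and round(eta, 2) != round(reported, 2):
        warnings.warn(
            f"partial eta squared {eta:.4f} (rounds to {round(eta, 2)}) "
            f"disagrees with reported {reported}", stacklevel=2)
    return float(eta), eta_category(eta)


def eta_category(eta: float) -> str:
    """Bins: 0.01-0.04 small, >0.04-0.14 medium, >0.14 large."""
    if eta < 0.01:
        return "negligible"
    if eta <= 0.04:
        return "small"
    if eta <= 0.14:
        return "medium"
    return "large"


def d_category(d: float) -> str:
    """Bins: <0.2 trivial, 0.2-0.6 small, >0.6-1.2 moderate,
    >1.2-2.0 large, >2.0 very large."""
    d = abs(d)
    if d < 0.2:
        return "trivial"
    if d <= 0.6:
        return "small"
    if d <= 1.2:
        return "moderate"
    if d <= 2.0:
        return "large"
    return "very large"


def cohens_d_log(group_a_log, group_b_log) -> tuple[float, str]:
    """|mean difference| / pooled SD on log-transformed values."""
    a = np.asarray(group_a_log, dtype=float)
    b = np.asarray(group_b_log, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = math.sqrt(((a.size - 1) * a.var(ddof=1)
                        + (b.size - 1) * b.var(ddof=1))
                       / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    d = abs(b.mean() - a.mean()) / pooled
    return float(d), d_category(d)


def bonferroni(p: float, m: int) -> float:
    """Adjusted p = min(1, p*m); never smaller than the raw p."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, p * m)


# ---------------------------------------------------------------------------
# mixed models


def _term_label(raw: str) -> str:
    """'C(season_period, Sum):C(role, Sum)' -> 'season_period:role'."""
    parts = []
    for piece in raw.split(":"):
        piece = piece.strip()
        if piece.startswith("C("):
            piece = piece[2:].split(",")[0].strip()
        parts.append(piece)
    return ":".join(parts)


def fit_lmm(frame: pd.DataFrame, response: str, fixed=("season_period",),
            subject: str = "player_id", interactions: bool = True) -> LmmResult:
    """Participant-random-intercept linear mixed model (REML).

    Factors are sum-to-zero coded so the per-term Wald tests are
    Type-III-style marginal tests; chi-square statistics are converted to
    F with denominator df approximated by n_obs - rank(X).
    """
    fixed = list(fixed)
    for f in fixed:
        if frame[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 observed levels")
    op = " * " if interactions else " + "
    formula = f"{response} ~ " + op.join(f"C({f}, Sum)" for f in fixed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, frame, groups=frame[subject])
        res, converged = _robust_mixedlm_fit(model)
        if res is not None:
            wt = res.wald_test_terms(scalar=True).table
            loglik = float(res.llf)
        else:
            # degenerate random-effects solution: fall back to the fixed
            # part only and flag the result as non-converged
            ols = smf.ols(formula, frame).fit()
            owt = ols.wald_test_terms(scalar=True).table
            wt = pd.DataFrame(
                {"statistic": owt.iloc[:, 0].to_numpy(float)
                 * owt["df_constraint"].to_numpy(float),
                 "df_constraint": owt["df_constraint"]}, index=owt.index)
            loglik = float(ols.llf)
    n_obs = int(model.nobs)
    df_den = n_obs - int(np.linalg.matrix_rank(model.exog))
    rows = []
    for raw, r in wt.iterrows():
        if raw == "Intercept":
            continue
        df_num = int(r["df_constraint"])
        f_stat = max(float(r["statistic"]), 0.0) / df_num
        p = float(spstats.f.sf(f_stat, df_num, df_den))
        eta, cat = partial_eta_squared(f_stat, df_num, df_den)
        rows.append(dict(term=_term_label(raw), F=f_stat, df_num=df_num,
                         df_den=df_den, p=p, eta_p2=eta, eta_category=cat))
    return LmmResult(response=response, terms=pd.DataFrame(rows),
                     loglik=loglik, converged=converged, n_obs=n_obs)


def _robust_mixedlm_fit(model):
    """REML fit with optimizer fallbacks.

    Returns (results, converged); (None, False) if every optimizer hits a
    singular profile (degenerate random-intercept variance).
    """
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            res = model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if np.all(np.isfinite(res.fe_params)):
            return res, bool(res.converged)
    return None, False


def lmm_condition_pvalue(frame: pd.DataFrame, response: str = "y",
                         condition: str = "condition",
                         subject: str = "player_id") -> float:
    """p-value of a single two-level condition effect (fast path for
    simulation studies): random-intercept model, Wald test."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(f"{response} ~ {condition}", frame,
                            groups=frame[subject])
        res, _ = _robust_mixedlm_fit(model)
        if res is None:  # variance collapsed to the boundary
            res = smf.ols(f"{response} ~ {condition}", frame).fit()
    return float(res.pvalues[condition])


def empirical_power(effect: float, n_reps: int = 500, seed: int = 0,
                    n_subjects: int = 23, obs_per_subject: int = 15,
                    icc: float = 0.05, alpha: float = 0.05) -> float:
    """Monte-Carlo rejection rate of the mixed-model condition test.

    With ``effect=0`` this estimates the type-I error rate; otherwise the
    power against a standardized (total-SD units) condition difference.
    """
    from .synth import simulate_lmm_dataset
    ss = np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        df = simulate_lmm_dataset(n_subjects=n_subjects,
                                  obs_per_subject=obs_per_subject,
                                  icc=icc, effect=effect, seed=rep_seed)
        if lmm_condition_pvalue(df) <= alpha:
            rejections += 1
    return rejections / n_reps


# ---------------------------------------------------------------------------
# bootstrap mean differences


def _cluster_indices(subjects: np.ndarray) -> dict:
    idx = {}
    for i, s in enumerate(subjects):
        idx.setdefault(s, []).append(i)
    return {k: np.asarray(v) for k, v in idx.items()}


def bootstrap_mean_difference(group_a, group_b, reps: int = 1000,
                              seed: int = 0, subjects_a=None, subjects_b=None,
                              label: str = "") -> Comparison:
    """Percentile-bootstrap mean difference, MD = mean(B) - mean(A).

    When subject labels are supplied, observations are resampled within
    each group stratified by subject: every subject keeps its observation
    count and is resampled internally with replacement.  For the
    within-subject regular-vs-finals contrast this respects the clustered
    design — subject intercepts enter both period means with (nearly)
    fixed weights and cancel from the difference, so the dominant
    within-subject sampling variance is what the interval must capture.
    Without labels, observations are resampled iid within each group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if reps < 100:
        warnings.warn(f"only {reps} bootstrap resamples; interval will be "
                      "unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    md = float(b.mean() - a.mean())

    def _group_means(x: np.ndarray, subjects) -> np.ndarray:
        if subjects is None:
            idx = rng.integers(0, x.size, (reps, x.size))
            return x[idx].mean(axis=1)
        sums = np.zeros(reps)
        for obs_idx in _cluster_indices(np.asarray(subjects)).values():
            vals = x[obs_idx]
            n_s = vals.size
            pick = rng.integers(0, n_s, (reps, n_s))
            draws = vals[pick]
            if n_s > 1:
                # rescale within-stratum deviations so the stratum's
                # resampling variance is unbiased (ML variance carries a
                # (n_s-1)/n_s shrinkage that matters for small strata)
                m_s = vals.mean()
                draws = m_s + (draws - m_s) * np.sqrt(n_s / (n_s - 1.0))
            sums += draws.sum(axis=1)
        return sums / x.size

    boots = _group_means(b, subjects_b) - _group_means(a, subjects_a)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return Comparison(label=label, md=md, ci_low=float(lo), ci_high=float(hi),
                      n_a=a.size, n_b=b.size)


# ---------------------------------------------------------------------------
# interaction decision tree


@dataclass
class DecisionTreeResult:
    """Outcome of the interaction decision procedure for one response."""

    response: str
    branch: str           # per_role_team | per_role | team_interaction_only
    #                       | main_effect
    full_model: LmmResult
    reduced_model: LmmResult | None
    subgroup_models: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)
    log: list = field(default_factory=list)


def _period_comparison(frame, response, response_raw, label, seed, n_family,
                       raw_p, subject="player_id", period="season_period"):
    """Bootstrap MD on original units; Cohen's d on the inference (log)
    scale; Bonferroni adjustment over the post-hoc family."""
    reg = frame[frame[period] == "regular"]
    fin = frame[frame[period] == "finals"]
    comp = bootstrap_mean_difference(
        reg[response_raw], fin[response_raw], reps=1000, seed=seed,
        subjects_a=reg[subject].to_numpy(), subjects_b=fin[subject].to_numpy(),
        label=label)
    comp.p_adjusted = bonferroni(raw_p, n_family)
    try:
        comp.d, comp.d_category = cohens_d_log(
            reg[response].to_numpy(float), fin[response].to_numpy(float))
    except ValueError:
        comp.d, comp.d_category = float("nan"), "undefined"
    return comp


def interaction_decision_tree(frame: pd.DataFrame, response: str,
                              response_raw: str | None = None,
                              alpha: float = 0.05, seed: int = 0,
                              subject: str = "player_id",
                              period: str = "season_period",
                              role: str = "role", team: str = "team"
                              ) -> DecisionTreeResult:
    """Decide how the period effect is analyzed, following the factorial
    interaction hierarchy.

    (a) significant period x role x team -> separate models per role and
    team; (b) team does not interact with period (neither 3-way nor
    2-way) -> drop team, re-run with period x role, and if that
    interaction is significant, per-role models; (c) period x team
    significant without the 3-way -> report the interaction only (no
    simple effects; inter-team contrasts are out of scope); (d) no
    interactions -> interpret the period main effect.  Every branch
    decision is logged.

    Models are fit on ``response`` (typically the log-transformed
    variable); bootstrap mean differences use ``response_raw`` (the
    original-units column), defaulting to ``response``.
    """
    response_raw = response_raw or response
    if frame.empty:
        raise ValueError("empty analysis frame")
    for fac in (role, team):
        counts = frame.groupby([period, fac]).size().unstack(fill_value=0)
        empty = counts.stack()[counts.stack() == 0]
        if not empty.empty:
            cells = [f"{period}={p}, {fac}={v}" for p, v in empty.index]
            raise ValueError(f"empty design cell(s): {'; '.join(cells)}")
    log = []
    full = fit_lmm(frame, response, fixed=(period, role, team), subject=subject)
    t3 = f"{period}:{role}:{team}"
    p3 = full.p(t3)
    log.append(dict(step="3-way interaction", term=t3,
                    F=full.term(t3).F, p=p3, significant=p3 <= alpha))
    res = DecisionTreeResult(response=response, branch="", full_model=full,
                             reduced_model=None, log=log)
    if p3 <= alpha:
        res.branch = "per_role_team"
        cells = frame.groupby([role, team])
        for (r, t), sub in cells:
            if sub[period].nunique() < 2:
                raise ValueError(f"cell role={r}, team={t} lacks both periods")
            m = fit_lmm(sub, response, fixed=(period,), subject=subject)
            res.subgroup_models[(r, t)] = m
            res.comparisons.append(_period_comparison(
                sub, response, response_raw, f"{r}/{t}", seed, cells.ngroups,
                m.p(period), subject, period))
        log.append(dict(step="branch", decision="per role x team"))
        return res

    p_pt = full.p(f"{period}:{team}")
    log.append(dict(step="2-way period x team", term=f"{period}:{team}",
                    F=full.term(f"{period}:{team}").F, p=p_pt,
                    significant=p_pt <= alpha))
    if p_pt > alpha:
        # team does not interact with period: drop it and re-run
        reduced = fit_lmm(frame, response, fixed=(period, role),
                          subject=subject)
        res.reduced_model = reduced
        pr = reduced.p(f"{period}:{role}")
        log.append(dict(step="2-way period x role (team dropped)",
                        term=f"{period}:{role}",
                        F=reduced.term(f"{period}:{role}").F, p=pr,
                        significant=pr <= alpha))
        if pr <= alpha:
            res.branch = "per_role"
            groups = frame.groupby(role)
            for r, sub in groups:
                if sub[period].nunique() < 2:
                    raise ValueError(f"role {r!r} lacks both periods")
                m = fit_lmm(sub, response, fixed=(period,), subject=subject)
                res.subgroup_models[r] = m
                res.comparisons.append(_period_comparison(
                    sub, response, response_raw, str(r), seed, groups.ngroups,
                    m.p(period), subject, period))
            log.append(dict(step="branch", decision="per role"))
        else:
            res.branch = "main_effect"
            pm = reduced.p(period)
            log.append(dict(step="period main effect", term=period,
                            F=reduced.term(period).F, p=pm,
                            significant=pm <= alpha))
            res.comparisons.append(_period_comparison(
                frame, response, response_raw, "all", seed, 1, pm,
                subject, period))
            log.append(dict(step="branch", decision="period main effect"))
    else:
        res.branch = "team_interaction_only"
        log.append(dict(
            step="branch",
            decision="period x team interaction reported without simple "
                     "effects (inter-team contrasts out of scope)"))
    return res


# ---------------------------------------------------------------------------
# sample size


def sample_size_lmm(effect_size: float = 0.40, power: float = 0.80,
                    alpha: float = 0.05, k_subjects: int = 23,
                    icc: float = 0.05) -> PowerDesign:
    """Design-effect sample size for a clustered two-group comparison.

    The base total N comes from the standard two-sample t power
    computation at (d, two-sided alpha, power); repeated observations per
    subject inflate the required N by the design effect 1 + (m-1)*ICC,
    giving k*m = N_base * (1 + (m-1)*ICC), solved for m.  Total sample
    size is ceil(k*m), per-subject observations round(m).
    """
    if not (0 < alpha < 1 and 0 < power < 1 and 0 <= icc < 1
            and effect_size > 0 and k_subjects > 0):
        raise ValueError("parameters out of range")
    n_per_group = TTestIndPower().solve_power(
        effect_size=effect_size, alpha=alpha, power=power, ratio=1.0,
        alternative="two-sided")
    n_base = 2.0 * n_per_group
    if k_subjects <= n_base * icc:
        raise ValueError(
            f"{k_subjects} subjects cannot satisfy the design effect with "
            f"ICC={icc} (need more than {n_base * icc:.1f})")
    m = n_base * (1.0 - icc) / (k_subjects - n_base * icc)
    total = math.ceil(k_subjects * m - 1e-9)
    return PowerDesign(effect_size=effect_size, power=power, alpha=alpha,
                       k_subjects=k_subjects, icc=icc, base_total_n=n_base,
                       obs_per_subject=round(m), total_n=total)


# ---------------------------------------------------------------------------
# descriptive reporting


def format_median_iqr(values, fmt: str = "{:.1f}") -> str:
    """'median (Q1-Q3)' with linear-interpolation quartiles."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return ""
    med, q1, q3 = np.percentile(x, [50, 25, 75])
    return f"{fmt.format(med)} ({fmt.format(q1)}–{fmt.format(q3)})"


def report_table(summaries: pd.DataFrame, variables,
                 group_cols=("role", "season_period"),
                 fmt: str = "{:.1f}") -> pd.DataFrame:
    """Descriptive median (Q1-Q3) table per variable and group cell.

    Descriptives stay on the original units; the log transform is for
    inference only.  Empty cells render as missing, not zero.
    """
    groups = summaries.groupby(list(group_cols), observed=True)
    rows = []
    for var in variables:
        row = {"variable": var}
        for key, sub in groups:
            key = key if isinstance(key, tuple) else (key,)
            row["/".join(map(str, key))] = format_median_iqr(sub[var], fmt)
        rows.append(row)
    return pd.DataFrame(rows)
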