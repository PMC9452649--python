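# Methods

`courtload` implements an accelerometry-based time-motion analysis for
basketball: raw 100 Hz triaxial traces become per-session demand
summaries banded by individualized physiological thresholds, and
regular-season vs finals differences are tested with
participant-random-intercept mixed models. Because the player
recordings behind studies of this kind are not publicly deposited, the
package ships a synthetic cohort generator with planted ground truth;
every claim the test-suite makes is a claim about recovering known
truth, not about any real team.

## Signal chain

Each axis is filtered with a band-pass Butterworth, 0.1–15 Hz, overall
order 4 (two poles per band edge — `filter_order` is the overall pole
count and is configurable). Filtering is zero-phase
(forward–backward, `sosfiltfilt`), chosen so that banding epochs are
not phase-shifted relative to the underlying movement; the magnitude
response is therefore the square of the single-pass response. The DC
(gravity) component lies below the 0.1 Hz edge and is removed by
construction. The per-sample resultant magnitude √(ax²+ay²+az²) is
converted to net force with F = m·a·9.81 (raw data in g; the standard
gravity constant is our choice, the method literature does not fix
one). Epoch length for banding is 1 s by default — the finest common
epoch consistent with reporting minutes; it is configurable.

Session intensity AvF_NET is the mean epoch force (N); session volume
is the impulse AvF_NET × duration, reported in kN·s. The first/last
seconds of a session carry filter edge transients; traces in the
generator start and end in recovery bouts, where the transient is
negligible (see below).

## Calibration and intensity bands

Per player, incremental shuttle-run (Yo-Yo IR1 style) stages provide
paired (AvF_NET, V̇O₂) observations: V̇O₂ per stage speed uses the ACSM
running equation V̇O₂ = 0.2·v(m·min⁻¹) + 3.5 by default (the mapping is
injectable), V̇O₂max defaults to the estimated V̇O₂ of the final
completed stage, and an OLS line V̇O₂ = a·AvF_NET + b is fit per
player. Band edges at 10/40/90/100 %V̇O₂R (oxygen-uptake reserve)
invert through this line to newton thresholds; negative inversions
clamp to zero. Boundary semantics: a value exactly at an edge belongs
to the lower band (inactive is ≤10 %V̇O₂R; higher bands open with a
strict ">").

A known fragility of the method, reproduced faithfully here: the
10 %V̇O₂R threshold lies below the calibration stage range, so it is an
extrapolation. With noisy stages the fitted intercept can drag this
threshold far from truth and systematically re-label near-rest epochs.
The exact plant-recover guarantees below therefore presume noise-free
calibration stages; with the default stage noise (5 N) the descriptive
outputs show realistic calibration scatter instead.

## Session summaries and roles

A summary (the unit of statistical analysis) carries AvF_NET, impulse,
minutes and percent of monitored time per band, minutes played, role,
period, and team. The percentage denominator is the full monitored
duration — first-quarter start to final-quarter end for matches
(stoppages included), the whole session for training — under which
band percentages total 100 by construction. Match roles: starter (on
court at tip-off), in-rotation bench (≥10 min played), out-rotation
bench (the rest); the boundary value 10.0 is in-rotation. Training
role is the player's modal match role across the season, ties broken
toward the higher-involvement role (starter > in-rotation >
out-rotation) — the tie-break is our choice. Minutes played come from
the manifest (as league records would provide them), not from the
trace.

## Statistics

Variables are screened with Shapiro-Wilk and natural-log transformed
for inference; variables containing zeros get a +1 offset first (at
full scale these are playing time and maximal/supramaximal activity;
the rule is applied to whatever variables contain zeros in the data at
hand). Descriptives stay on original units as median (Q1–Q3), with
linear-interpolation quartiles (the convention is our choice).

Mixed models are REML fits via statsmodels `MixedLM` with a random
intercept per participant and season period × player role × team as
sum-to-zero-coded fixed factors, giving Type-III-style marginal Wald
tests. Chi-square statistics convert to F with denominator df
approximated as n_obs − rank(X) — a residual approximation we document
rather than reimplementing any particular software's Satterthwaite
variant; the simulation suite calibrates the resulting test
empirically (type-I error 0.054–0.056 at nominal 0.05 over 500
replicates of the designed study). When the random-intercept variance
profile is degenerate the fit falls back through optimizers and,
failing that, to the fixed-effects OLS solution flagged
`converged=False`.

The interaction decision tree follows the standard factorial
hierarchy: (a) significant 3-way period×role×team → separate period
models per role×team cell; (b) team interacts with period in neither
the 3-way nor the 2-way term → team is dropped, the model re-run with
period×role, and a significant period×role interaction → per-role
models; (c) period×team significant without the 3-way → the
interaction is reported without simple effects (inter-team contrasts
are out of scope); (d) otherwise the period main effect is
interpreted. Every branch decision is logged. Follow-up p-values are
Bonferroni-adjusted over the subgroup family of the chosen branch.

Pairwise period contrasts report a bootstrap mean difference (MD,
original units, 1,000 resamples, percentile 95% CI) and Cohen's d on
the log scale (pooled-SD; bins: <0.2 trivial, 0.2–0.6 small, >0.6–1.2
moderate, >1.2–2.0 large, >2.0 very large, with 0.2 and the other
lower bounds closed). The bootstrap resamples observations within
group, stratified by subject: each subject keeps its observation count
and is resampled internally, with within-stratum deviations rescaled
by √(n_s/(n_s−1)) so each stratum contributes an unbiased variance
(without the rescale, subjects contributing 3–4 observations shrink
the interval noticeably). For the within-subject period contrast this
captures the dominant sampling variance, because subject intercepts
enter both period means with nearly fixed weights and cancel from the
difference; for contrasts between disjoint groups of subjects with
substantial intraclass correlation it would understate between-subject
variance — a documented limitation, not our use case. Partial eta
squared for fixed effects is F·df₁/(F·df₁+df₂) (bins 0.01–0.04 small,
>0.04–0.14 medium, >0.14 large); when a caller supplies a previously
published value that disagrees at 2-decimal rounding, the function
warns rather than adopting it.

The sample-size operation solves the clustered design: the base total
N for a two-sample t test at (d, two-sided α, power) is inflated by
the design effect 1+(m−1)·ICC, i.e. k·m = N_base·(1+(m−1)·ICC) solved
for per-subject observations m; total = ⌈k·m⌉. At d = 0.40,
power = 0.80, α = 0.05, k = 23, ICC = 0.05 this gives m → 14 and a
total of 331. The t-based (not normal-approximation) base computation
is required for these figures.

## Synthetic cohort generator

The generator emulates a two-team season: 10 women and 13 men with
masses drawn from team-specific normals (76.5 ± 19.5 and
96.2 ± 16.4 kg), roles fixed per player (5/3/2 and 5/4/4
starter/in-rotation/out-rotation), a season calendar of 26/4 and 24/8
regular/finals training sessions and 20/3 and 20/4 matches per team,
and attendance drawn so the per-stratum observation totals are exactly
387/75 (matches, regular/finals) and 445/113 (training). Minutes
played are truncated normals per role (starters 30 ± 4, in-rotation
17.5 ± 3.5 bounded below at 10, out-rotation 4.5 ± 2.2 bounded below
10); planted finals shifts are +4.4 (starters), 0 (in-rotation) and
−2.1 min (out-rotation).

Traces are piecewise-stationary bouts: lengths are truncated
log-normal (minimum 2 s; active bouts 6 ± 4 s, recovery 12 ± 8 s),
each bout is assigned an intensity band by sampling proportional to
the session's remaining per-band time budget, and sessions open and
close with a recovery bout. Within a bout the two horizontal axes
carry a quadrature pair (A·sin, A·cos) at a carrier drawn from
1–4 Hz — inside the filter passband — so the filtered resultant is
exactly constant at A; the vertical axis carries the 1 g gravity
component the band-pass must remove. A targets the band midpoint
(5/25/65/95/115% of the reserve, mapped through the player's planted
force–V̇O₂ line) and is pre-divided by the known zero-phase filter
gain at the carrier, so planted intensities survive filtering exactly.
White measurement noise (0.02 g per axis by default) is added last.
Per-session band occupancy is drawn from a Dirichlet around the
role/period target (precision 60, giving the several-percentage-point
session-to-session spread real match data shows); planted truth
records the realized bout schedule, so recovery tests compare against
what was actually planted. Occupancy targets per role come from
published match-demand profiles (starters ≈61% inactive down to
≈4.4% supramaximal; bench roles progressively more inactive), with
finals shifts whose signs mirror the role-dependent findings the
statistics must detect.

Everything derives from `numpy` `SeedSequence` children of the single
config seed: identical configs produce byte-identical cohorts, and
traces are regenerated on demand from stored per-observation child
seeds rather than held in memory (a full season is ~10⁹ samples).

What the generator does **not** emulate: biomechanical realism of
basketball movement (impacts, jumps, orientation changes),
physiological drift or fatigue, positional/GPS structure, and
non-stationarity within bouts. Passing tests therefore demonstrate
that the pipeline recovers what its own model plants — filter
correctness, banding arithmetic, statistical calibration — not that it
would reproduce any particular team's empirical tables.

## Problem sizes and numerical choices

The analysis scripts and test-suite run the full observation counts at
reduced session duration (10-minute monitored windows, quarter-scale
session counts) — our chosen desk scale; the generator accepts the
full 90/94-minute design unchanged. Monte-Carlo calibration uses 500
replicates for type-I error, power and CI coverage. Exact
plant-recover (within 2 epochs per band) presumes noise-free
calibration stages and bouts ≥5 s; with measurement noise the
guarantee is ±2 percentage points on a 90-minute session. Bootstrap
and simulation seeds are explicit everywhere; epoch classification at
thresholds is closed-below; trailing partial epochs are dropped (at
most one per session).

## Known limitations

* Denominator df is a residual approximation; software-exact F/df
  agreement with any particular mixed-model implementation is not a
  goal (the calibration simulations are).
* The Wald z→F conversion is mildly liberal in very small subgroups.
* The stratified bootstrap understates between-subject variance for
  unpaired contrasts at high ICC.
* The 10 %V̇O₂R threshold is an extrapolation below the calibration
  range and inherits its noise — visible in the synthetic descriptives
  as occasional players whose inactive time is systematically
  re-labelled.
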