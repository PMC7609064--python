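# Methods

This note documents the models, scoring rules, statistical procedures and
numerical choices implemented in `flysleep`, and what the synthetic-data
generators do and do not emulate.

## Sleep scoring from activity monitors

Activity is recorded as beam-break counts in 1-minute bins.  Sleep is the
field's standard operational definition: a maximal run of zero-count
minutes lasting **at least 5 minutes**.  Runs shorter than 5 minutes
contribute nothing; runs truncated by the start or end of the recording
count if their *observed* length reaches 5 minutes (their true extent is
unknowable; this matches common practice).  `score_sleep` is a run-length
scan; an independently written brute-force scanner is kept in the test
suite as its oracle.

Summaries use Zeitgeber time (ZT; minutes since lights-on) with the
half-open phase convention day = ZT [0, 720), night = ZT [720, 1440) under
a 12:12 light:dark cycle — the minute at exactly ZT 720 is night, so no
minute is double-counted.  A bout spanning the day/night boundary
contributes its minutes to each phase by membership (whether the original
analyses split boundary bouts this way or assigned them to the bout-onset
phase is not documented; minute-membership splitting is our assumption).
The 30-minute sleep profile counts asleep-minutes per ZT bin
[30b, 30(b+1)); conservation identities (day + night = total; profile bins
sum to the window total; bout durations sum to total sleep) hold exactly
and are asserted on random inputs.

For multi-beam monitors, `moves` (adjacent-beam transitions) index
locomotion while `counts` additionally include within-beam twitches and
grooming; because counts ≥ moves minute-by-minute, sleep scored from
counts is a subset of sleep scored from moves — the counts analysis can
only *underestimate* sleep.  This inequality is structural and is verified
per fly on simulated data.

**Thermogenetic sleep change.**  For warmth-activation experiments
(baseline ≈1.5 days at 22 °C, 1 day at 28–30 °C, 1 day recovery), the
sleep change is activation-phase sleep minus baseline-phase sleep:
baseline = the **last** full phase instance (e.g. night) inside the
baseline epoch; activation = a configurable ordinal instance inside the
activation epoch, defaulting to the second when two or more exist, else
the first (matching designs that quantify the second activation night).

**Dead flies.**  A fly whose final zero-count run is ≥ 12 h (configurable)
and reaches the recording end is flagged dead with its death minute and
excluded from group summaries.  This is an artifact-level convention; the
threshold has no biological calibration.

**Tukey boxplots.**  Quartiles use linear interpolation between order
statistics (NumPy's default); whiskers sit on the most extreme data values
within 1.5 IQR of the quartiles; values outside are reported as outliers.
Tukey's method admits variants — this one is declared and the test oracle
uses the same rule.

## Video ethogram scoring (ZT 18–24)

Per-second labels (`immobile`, `courting`, `other_active`) are scored for
the first 5 minutes of each hour between ZT 18 and ZT 24.  An in-window
immobile second counts as sleep only if its maximal immobile run, followed
into context **beyond the window edges**, reaches 300 s; shorter
immobility is "wake but not courting" (brief inactivity).  The context
horizon is 300 s per side — exactly enough to decide the 300-s criterion
for any run touching a window edge — and runs straddling the window start
are treated symmetrically to window-end runs.  The three percentages
partition 100 by construction.  Nightly scores are the unweighted mean of
the six hourly windows.

## Courtship and latency analysis

The courtship index (CI) is the fraction of time courting within
min(10 min, time to copulation) after courtship initiation.  Males that
never initiate have **no** CI (undefined, not zero) and are excluded from
CI group statistics; they still contribute censored latency samples.
Latencies to initiation and copulation are measured from introduction and
right-censored at the 2-h observation end.

The two-group log-rank test is implemented from its risk-table formula: at
each distinct event time, observed events in group A are compared with the
expectation under a common hazard, with the hypergeometric variance for
tied events; the statistic (ΣO−ΣE)²/ΣV is referred to χ²(1).  Censorings
tied with an event time remain in the risk set at that time (events
precede censorings).  The implementation is validated against an
independent survival-analysis package on random censored samples, against
a hand-worked risk table, and by Monte-Carlo type-I/power calibration.

## Calcium-trace ΔF/F0

The imaging protocol samples a region-of-interest intensity every 5 s for
5 min; ATP is perfused for 1 min after a 1-min baseline.  Photobleaching
is corrected by fitting F(t) = A·e^(−kt) + C to two transient-free
windows — 30–60 s before ATP onset and 150–180 s after ATP offset — and
subtracting **only the decaying component** A·e^(−kt).  Subtracting the
full fitted curve would drive the baseline to ≈0 and make the subsequent
normalization unstable; a `full_subtraction` switch implements that
literal alternative.  F0 is the mean detrended intensity over the 30 s
before ATP onset (the window cannot contain the transient); ΔF/F0 =
(F − F0)/F0.  The pipeline is scale-invariant: multiplying the raw trace
by any positive constant leaves ΔF/F0 unchanged.

**Peak response.**  "Peak" is not uniquely defined in the field; we use
the maximum of a 5-frame (25 s) moving average of ΔF/F0 over
[ATP onset, ATP offset + 60 s].  A pointwise maximum over a response
plateau of ~13 frames is biased upward by ~1.7 noise SDs, which at
realistic noise (σ = 1% of baseline) exceeds a 10% tolerance on small
transients; the short moving average suppresses single-frame noise while
leaving any plateau wider than 25 s unattenuated.  The window and
smoothing width are configurable.

**Identifiability limitation.**  The two 30-s fit windows pin down the
bleach-curve *levels* at their midpoints (and weak within-window slopes)
but contain almost no curvature information when the decay is slow.  The
(A, k, C) decomposition then lies on a near-flat likelihood ridge, and the
offset estimate Ĉ — which sets F0 and hence the ΔF/F0 scale — has large
variance: at k ≲ 0.004 s⁻¹ over a 5-min trace, no estimator restricted to
those windows can pin the absolute ΔF/F0 scale to within ~10% at σ = 1%
of baseline (two independent estimators, a bounded Levenberg–Marquardt
fit and an exact profile least squares over a rate grid, give
indistinguishable recovery rates).  With fast bleaching
(k ≈ 0.01 s⁻¹) the split is well identified and transients of amplitude
≥ 0.3 are recovered within 10% in ≥95% of noisy traces; noiseless
recovery is exact everywhere.  Detrended *curves* (and therefore relative
comparisons across conditions under a common protocol) are much more
stable than the absolute scale.  If the offset cannot be resolved at all
(F0 ≤ 0), the pipeline raises rather than emitting a meaningless
normalization.

## Statistical decision procedures

Two-group comparisons follow an explicit gate chain: D'Agostino–Pearson
normality on each group (validity floor n = 8; smaller groups go
nonparametric with a warning); if either group fails at α = 0.05 →
Mann-Whitney; else a Brown–Forsythe variance-equality gate (Levene on
deviations from medians, α = 0.05, a choice the original "when
appropriate" wording leaves open) routes to Welch's t or Student's t.
Note the gates themselves consume error probability: with two normality
tests at 5%, ~10% of perfectly Gaussian datasets go nonparametric, so the
expected rate of reaching the variance gate is ~90%, not 100%.  The
type-I error of the full chain is calibrated (asserted within the
binomial CI of α on null Gaussian data).

Two-factor designs use a two-way ANOVA (type-II) for the interaction,
followed by a selectable post-hoc family — Sidak-adjusted planned pairs
(factor-A levels within each level of factor B), Tukey HSD over all
cells, or Dunnett against a named control cell — since different
experiments call for different families.  ANOVA and Tukey numerics
delegate to statsmodels; Dunnett to SciPy.

**Screen-hit rule.**  In a thermogenetic screen each driver line has an
experimental group, a line-specific driver (GAL4) control and a shared
effector (UAS) control.  A line is a hit only if the experimental group
differs from **both** controls at α with the same direction of effect
(Welch's t per comparison); a line sitting between its controls is never
a hit.  The reported effect size is the difference versus the shared
effector control.

## Synthetic data

The fly model is a two-state Markov chain on the 1-minute grid: from wake
a fly falls asleep with probability p_fall, from sleep it wakes with
probability p_wake, each phase-dependent (day/night, switched at ZT 0/720
with no dawn/dusk ramps — sufficient for every tested surface).  Sleep
runs are therefore geometric with mean 1/p_wake.  Awake minutes emit
zero-truncated Poisson counts (≥ 1 break; the configured rate is the
truncated mean), asleep minutes emit zero, so the scorer can never invent
sleep during wake.  Each fly draws from its own RNG stream seeded from
(experiment seed, CRC32(fly id)), making every dataset bit-reproducible
and order-independent.

Because run lengths are geometric, the scored-sleep observable has closed
forms.  At stationarity the expected scored fraction is
π · q^(L−1) (L(1−q) + q) with π = p_fall/(p_fall+p_wake), q = 1−p_wake,
L = 5.  For finite, inhomogeneous recordings (phase switches, activation
epochs, edge truncation) `expected_scored_sleep` computes the exact
expectation: P(asleep at minute m) from the forward recursion minus the
probability that m lies in a maximal run shorter than 5 minutes (a finite
sum over run placements).  This exact form is validated against complete
enumeration of all hidden-state sequences at small n and is the oracle
for the thermogenetic sleep-change check (the stationary formula is ~1–2%
off at realistic parameters because nights are finite and the chain is
not stationary at phase boundaries — more than Monte-Carlo error at the
sample sizes used).

Default condition presets mirror the structure of pairing-by-nutrition
experiments: male–male pairs sleep ~600 min/night regardless of diet;
male–female pairs sleep ~200 min/night when protein-fed and ~480 when
yeast-deprived.  Cohort generators map per-fly target means to p_wake at
fixed p_fall = 0.1 by inverting the stationary formula; per-fly targets
are drawn N(cell mean, 110 min) because the chain's intrinsic SD of
nightly scored sleep is only ~36–49 min and real per-fly variability in
such experiments is ~120 min — the 2×2 power analyses use that total SD.
The 2×2 scenario places the interaction as a difference-of-differences of
240 min (the pairing deficit is 120 min larger than average under fed and
120 min smaller under deprived conditions), detectable with ≥90% power at
p < 0.01 with n = 32/cell.

Multi-beam simulation adds, while awake, adjacent-beam pacing (Poisson)
and within-beam micro-movements, and while asleep occasional twitches
that register in counts only, guaranteeing counts ≥ moves by
construction.  Courtship trials draw exponential initiation and
copulation latencies censored at 2 h, with courting intervals filling a
target CI fraction.  Fluorescence traces are
raw(t) = A·e^(−kt) + C·(1 + a·s(t)) + ε with s(t) a smooth
ramp–plateau–decay confined to [ATP onset, ATP offset + 60 s] and ε
Gaussian: the evoked transient rides on the stable component, so the
pipeline's noiseless peak equals the amplitude `a` exactly.

What the generators do **not** emulate: locomotor microstructure (bout
clustering, anticipation ramps), circadian period differences, female
behavior beyond pairing labels, non-exponential latency shapes, and
indicator saturation or motion artifacts in imaging.  Passing tests
therefore demonstrate correctness of the scoring/statistics machinery
under the stated generative assumptions, not robustness to every feature
of real recordings.

## Problem sizes

The repository's test suite and acceptance script size their simulations
to keep full runs in the minutes range on one CPU: 10,000 vectors for the
scorer-oracle check; 200 multi-beam flies; 100 replicates of the 2×2
design (n = 32/cell, 1 day); 60 flies × 20 replicates for the
thermogenetic check (3.5 days); 1,000 traces per calcium bound; 1,000
null and 500 alternative log-rank replicates (n = 40/group); one 20-line
screen at n = 30.
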