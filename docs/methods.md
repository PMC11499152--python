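# Methods

This note documents the statistical procedure, the generative model behind
the synthetic datasets, the numerical conventions, and the choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Divergence-point analysis

**Data model.** The unit of analysis is the role-labelled gaze sample:
per trial, each sample at time *t* (ms since trial onset) is *factual*,
*illusory* or *elsewhere*, depending on whether it falls inside the
remembered rectangle of the picture matching the sentence meaning, inside
the competitor's rectangle, or neither. Rectangle membership is half-open
(`[x0, x0+w) × [y0, y0+h)`) so touching rectangles can never double-count a
sample; coordinates use the web convention (origin top-left, y downward).
Samples are used directly as looks — no fixation-event parsing (dispersion
or velocity filtering) is applied, a deliberate simplification appropriate
when the downstream statistics are proportions of looks rather than
fixation events.

**Windows and bins.** The trial timeline is preview `[0, 4000)`,
anticipation `[4000, 7000)`, integration `[7000, 8000]` ms (configurable;
boundaries belong to the later window, the trial end to integration). The
DPA operates on the span `[4000, 8000)` — anticipation plus integration,
since fixation curves keep evolving after the pictures reappear — in 200 ms
bins anchored at the audio onset (4,000 ms), so every reportable onset and
CI endpoint sits on the 200 ms grid from 4,000.

**Per-bin test.** For participant *i* and bin *b*, let *y* be the factual
looks out of *N* = factual + illusory looks (the *aoi-only* denominator;
*all-samples* is available for sensitivity analyses). The empirical logit
and its variance term are

    elog = ln((y + 0.5) / (N − y + 0.5)),   w = 1/(y + 0.5) + 1/(N − y + 0.5),

finite for all counts including 0 and N. Each bin is fit by weighted least
squares of elog on the two-level fixation-target indicator — one elog per
participant × target, regression weights 1/w — and the target coefficient
is tested one-sided for factual > illusory at α = .05 (two-sided is a
config switch). Because the predictor is binary the WLS solution is
computed in closed form (the test suite verifies it against a generic WLS
routine); this keeps the bootstrap inexpensive. Cells with *N* = 0 are
flagged missing rather than raising; bins with fewer than two contributing
participants are untestable and break significance runs.

One structural property deserves note: under the aoi-only denominator the
illusory elog is exactly the negative of the factual elog with the same
weight, so the two per-participant observations are mirrored copies and the
WLS t-statistic runs ~√2 hot relative to a nominal t reference (measured
null one-sided rejection ≈ 12% at α = .05 rather than 5%). The
sustained-run criterion below is the error control for the onset decision,
and the bootstrap quantifies its sampling variability; single-bin p-values
should not be interpreted in isolation.

**Onset rule.** The divergence point is the left edge of the first bin of
the first run of ≥ 3 consecutive significant bins — a factual preference
sustained for 600 ms at the defaults. No multiple-comparison correction is
applied across bins; the run criterion is the error control. A series with
no qualifying run has a *missing* onset, which is a valid outcome, not an
error.

**Bootstrap.** The onset's sampling distribution is estimated by
nonparametric resampling: trials are drawn with replacement within
participant × condition strata, per-trial bin counts are re-aggregated, the
per-bin tests and onset rule re-run, 2,000 times by default. The
distribution is summarised by the mean over non-missing onsets and the
2.5/97.5 percentile interval; the missing fraction is always reported, and
a distribution with only missing onsets carries no mean/CI. Alternative
resampling units are selectable but non-default: whole participants, or
parametric redraws of the AOI looks within each participant × bin cell (the
most literal reading of reshuffling within participants, conditions and
time bins). The stratified trial bootstrap is the default because it
preserves each participant's trial count and per-bin structure while
treating trials as the exchangeable unit.

**Contrasts.** Differences between conditions, or between language groups,
are element-wise differences of two onset distributions paired by resample
index (each generated with independent draws); pairs where either member is
missing are dropped and counted. An effect is declared when the percentile
CI of the differences excludes zero. Between-language contrasts are
computed as L1 − L2, so a positive mean means the L1 group diverged later
(was slower). Onset distributions can be multimodal (e.g. an early and a
late cluster in an affirmative condition); they are summarised by the
overall mean and percentile CI, and the difference histograms the pipeline
emits make any bimodality visible.

## Synthetic-data generator

The generator emulates a two-picture blank-screen experiment at the design
scale of a typical webcam study: 32 participants, three sentence conditions
(affirmative control *positive*, sentential negation *negative*,
negative-concord *nobody*), 20 items per condition, 8,000 ms trials
(preview to 4,000 ms, 3,000 ms audio over a blank screen, pictures restored
at 7,000 ms), samples every 33 ms (~30 Hz webcam rate), button-press
accuracy 99.8%, and bounded-normal proficiency scores matching an
upper-intermediate placement-test profile (mean 43/50, range 36–47).
Factual side is counterbalanced left/right within participant × condition.

**Fixation ramp.** Each condition carries a ground-truth onset τ_c. A
trial's onset is τ_c plus additive Gaussian participant and item offsets
(truncated to the trial). Before the trial onset, looks are at baseline
(P(factual) = P(illusory) = 0.40, remainder elsewhere; during preview the
two picture probabilities are exactly equal). From the onset, P(factual)
rises along the upper half of a logistic anchored at the onset —
`r(t) = 2/(1 + e^{−k(t−τ)}) − 1` for t ≥ τ, zero before — toward an
asymptote (0.75 by default), while P(illusory) declines complementarily in
proportion to the realised fraction of the factual gain. The slope default
makes the 10–90% rise span ~600 ms. Anchoring the ramp at zero rather than
centring a logistic on τ keeps the pre-onset period exactly signal-free, so
τ is by construction the first moment of factual preference — the
generative analogue of the divergence point the bootstrap estimates. A flat
ramp (asymptote = baseline) produces no divergence signal anywhere and is
the null configuration used in the validation suite.

**Onset heterogeneity defaults (40 ms participant, 25 ms item).** The
generator draws each sample's role independently, so a 200 ms bin holds ~6
independent looks per trial and the group-level per-bin test resolves far
smaller effects than real, strongly autocorrelated gaze data would. With
symmetric onset jitter, half the trials ramp before τ_c, and jitter SDs
comparable to the bin width make the detected *group* onset systematically
earlier than τ_c — at which point τ_c no longer means what a recovered
divergence point estimates. The default SDs are therefore kept below the
bin width so that τ_c remains the group-level divergence onset; larger
values are available via config, and shift recovered onsets earlier exactly
as that analysis predicts.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: gaze autocorrelation and saccade/dwell dynamics
(independent per-sample draws make per-bin counts far less dispersed than
real data), pixel-level gaze noise and calibration drift, realistic
onset heterogeneity across participants (deliberately sub-bin, see above),
track loss (an optional uniform dropout rate exists but no default rate is
claimed faithful), audio-landmark alignment beyond a single onset
timestamp, and a separate integration-window verification process (the
anticipation ramp simply continues, which drives integration-window factual
proportions near 100%, higher than real studies report). Recovery results
on synthetic data validate the *estimator machinery*, not webcam data
quality.

**Proficiency coupling.** Optionally, the standard-normal participant
effect that generates proficiency also perturbs that participant's
asymptote (`proficiency_coupling`, an SD in probability units; 0 by
default), producing a positive proficiency × anticipatory-looking
correlation for exercising the correlation stage.

## Surrounding statistics

**Descriptives.** Per-trial fixation percentages per window are aggregated
two ways — across trials, and across participant means — and both are
emitted with an `aggregation` label, since reported descriptives in this
literature can follow either convention and the choice is rarely stated.

**Mixed model.** Total fixation length per trial × target (in-window
sample count × sample period) is modelled as
`fixtotal ~ target * condition` with treatment coding (references:
*factual*, *positive*), so a factual preference appears as a negative
coefficient for the illusory level. Fitting is delegated to statsmodels'
MixedLM (REML); re-deriving a mixed-model optimiser would add risk without
fidelity gain. Crossed participant and item effects are expressed as
variance components within a single grouping constant: by-participant
intercepts, target slopes and condition slopes, and by-item intercepts and
target slopes. This estimates independent variance components —
random-effect correlations, which a fully maximal formulation would
include, are not available in this framework; that simplification is the
package's own. A structure ladder (drop condition slopes → drop target
slopes → intercepts only → participant-only grouping) is descended on
failed fits, with the simplification logged. The optimizer's convergence
flag is recorded but advisory: L-BFGS flags variance-component fits
liberally even when fixed effects are stable across structures (the
fallback `participant_only` tier reproduces the same fixed-effect estimates
where this was checked).

**Correlations, accuracy, power.** Proficiency correlations are Pearson r
(scipy) between each participant's score and their mean anticipation-window
factual percentage, per condition. Accuracy is percent correct per
condition to two decimals. The paired-means sample size iterates the exact
noncentral-t power function (df = n − 1, noncentrality d·√n) over n and
returns the smallest n reaching the target power — d = 0.5, α = .05,
power = .80 two-tailed gives N = 34 — and is cross-checked in the tests
against statsmodels' power solver.

## Numerical conventions and degenerate inputs

- Onsets are reported at bin left edges; boundary times belong to the later
  window/bin (half-open), the trial end to integration.
- Degenerate bins with zero residual variance get t = ±∞ (p = 0 or 1) for a
  nonzero estimate and t = 0 (one-sided p = 0.5) for a zero estimate.
- Zero-denominator trials/cells are excluded with a logged count; empty
  descriptive cells are omitted with a warning; zero-variance correlation
  inputs raise.
- Bin width must divide the analysis span; onsets must lie inside the
  trial; probabilities are validated to [0, 1] with baselines summing ≤ 1.
- All randomness flows through numpy Generators; pipeline runs spawn
  per-condition child streams from the run seed in a fixed order, making
  end-to-end output byte-reproducible under a fixed seed.

## Problem sizes used in the validation suite

The test suite validates at the full design scale where the property needs
it (parameter recovery: 32 × 20 per condition, 200 bootstrap resamples;
CI coverage: 200 moderate-effect datasets at full scale, 200 resamples
each) and at reduced scale elsewhere (onset-detector and elog oracles are
exhaustive; pipeline determinism and CLI checks use 6–8 participants and
25–50 resamples). `scripts/acceptance.py` runs the full design with the
default 2,000 resamples.

## Known limitations

- The per-bin test's √2 t-inflation under the aoi-only denominator (see
  above) means single-bin significance is liberal; onset decisions rely on
  the sustained-run criterion and bootstrap, not on any single bin.
- Onset estimates are discretised to the bin grid; a mid-bin true onset is
  recovered at the containing bin's left edge, an inherent ≤ one-bin
  downward bias.
- The mixed model omits random-effect correlations (see above).
- The generator's independent per-sample draws understate real binomial
  overdispersion; quantitative power/coverage results on synthetic data
  will be optimistic relative to real gaze data.
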