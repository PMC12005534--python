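# Methods

`intentchain` re-implements, as a tested pipeline, the analysis chain of a
clock-based intentional-binding experiment performed through an M1
brain-machine interface (BMI) whose output drives real hand closing via
neuromuscular electrical stimulation (NMES).  This note documents the
models, the synthetic-data generator that stands in for the experiment,
the numerical choices, and the known limits of what the tests show.

## The experiment being modeled

A participant watches a Libet clock (full cycle 2,560 ms, 60 ticks,
random initial phase per trial) and, after each trial, reports the clock
position at which one element of the *intentional chain* occurred: the
intention to move (I), the hand closing itself (A), or an auditory tone
played 300 ms after the action (E).  Six conditions enable or bypass
chain elements: the full chain IAE; AE (NMES-evoked movement, no
intention); IE (decoded intention, NMES disabled, tone at the fixed
delay after decoder threshold); IA (no tone); A-only; E-only.  Reports
come in mini-runs of five trials per query type, ~50 trials per
condition.  Neural data are 96-channel multi-unit activity (MUA),
sorted single units, LFP, and the online movement decoder's output — a
score in [-1, 1] per 100 ms bin whose zero-crossing triggers NMES.

## Time and clock conventions

All times are milliseconds, trial-relative (0 = trial start); aligned
windows use 0 = alignment event with negative = before; bins are
half-open `[t, t + bin)`.  A clock report recurs once per cycle; the
occurrence nearest the objective event is selected, so event-relative
offsets are guaranteed to lie in `(-cycle/2, +cycle/2]`.  This
nearest-occurrence rule is safe because reports cluster well within one
second of their events.

Each trial occupies a fixed 10 s slot on the session timeline (action
drawn uniformly in 4-6 s, snapped to the decoder grid; the slot leaves
>= 2 s of pre-trial rest and ~3 s post-action).  Spike times are stored
session-relative; the uniform slot makes trial slicing reproducible
from the trial order alone.

## Circular statistics

The circular median is the *in-sample* minimizer of summed geodesic
(shorter-arc) distances on the cycle, ties broken toward the smallest
value.  The in-sample definition is chosen over a continuous minimizer
so that a brute-force oracle can verify it exactly (the test suite does
this on 1,000 random inputs).  Condition contrasts use two-sided
Wilcoxon rank-sum tests on the unwrapped offsets — a deliberate,
swappable choice for unpaired trial-level data in a single-subject
design, since the original "targeted non-parametric statistics" are not
further specified.  The action-effect interval is the median over all
cross pairs of (effect estimate - action estimate) on a common
action-relative axis.

## Synthetic sessions: what the generator emulates

The generator (`intentchain.synthetic_data`) is first-class, tested
code; its defaults are the study conditions.

**Reports.**  Report time = event + per-query bias + binding shift +
truncated-Gaussian noise, wrapped onto the clock at the trial's phase.
Default biases are the experiment's values (intention -597 ms, action
-455 ms, effect -512 ms); per-trial SDs are the reported standard
errors scaled by sqrt(50) (37.2/21.4/17.2 ms at n = 50 -> SDs of
263/151/122 ms), since only S.E.M.s are reported.  Noise is truncated
at 45% of the clock cycle: subjective reports cannot express an offset
beyond the half-cycle, and untruncated tails would occasionally wrap to
the far side of the clock, poisoning Pearson correlations with single
extreme outliers that the real data do not show.

**The latent intention time.**  The subjective intention time of a
trial is a latent variable: action + intention bias + binding shift +
noise carrying 90% of the intention-report variance; the clock report
is a noisy reading of it (the remaining 10%).  Neural intention
responses lock to the latent time, not the report — this produces the
report-alignment structure (evoked MUA near the report, trial-by-trial
spike-count correlations) that the analyses exploit, while keeping the
report an imperfect observer of the neural event.

**Binding.**  Each trial draws a decoder-quality factor q ~ N(0, 1)
that scales the decoder trace's plateau and shifts reports: intention
later (+80 ms per unit q) and action earlier (-50 ms per unit q) on
high-quality trials.  This reproduces the sign pattern of the
AUC-tertile analysis (intention reported later, action earlier on
high-AUC trials) without hard-coding its outcome.

**Spikes.**  Every unit is an inhomogeneous Poisson process realized by
thinning (chosen over time-rescaling because the thinning construction
is its own oracle: a bounded rate and a uniform acceptance test).
Rates combine a gamma-distributed baseline (mean 5 Hz sorted units,
12 Hz channel MUA), a logistic intention step
`f_I * expit((t - t0)/alpha)` locked to the latent intention time with
t0 offset -108 ms, per-trial jitter SD 50 ms and alpha ~ 23 ms, and a
Gaussian movement transient peaking 373 ms after action (width 150 ms,
mean amplitude 20 Hz on MUA channels).  30% of sorted units carry the
step; a disjoint 12% instead carry a pre-action rate gain proportional
to the trial's latent-intention deviation, calibrated
(`gain = r / sqrt(lambda (1 - r^2))` for window count lambda) to yield
a target spike-count/report correlation of r = 0.5.  The populations
are disjoint because a step whose *timing* co-varies with the report
adds its own (negative) count-report covariance inside a fixed count
window, which would confound the calibrated gain.

**Decoder traces.**  100 ms bins over the slot, rest level -0.6 with
SD 0.05 noise, clipped to [-1, 1].  Intended trials ramp linearly from
rest starting 1,100 ms before threshold and cross zero exactly at the
action bin (the crossing bin is noise-free and pre-crossing bins are
clamped strictly negative, so the crossing time is exact by
construction).  NMES-only trials rise abruptly at movement; the
no-action chain collapses ~100 ms after crossing; the no-effect chain
holds its plateau longer.  E-only trials are rest noise throughout.

**LFP.**  1/f background (FFT-shaped) plus band-limited oscillations:
a delta (2 Hz) envelope sustained from 1,000 ms before action when
intention is present but only switching on at movement without
intention, and alpha/beta (10/20 Hz) bursts for 500 ms after movement.
3 channels at 500 Hz by default.

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real data: spike-sorting errors and unit
drift across sessions, non-Poisson firing (bursting, refractoriness),
correlated noise across channels, NMES artifact waveforms beyond
threshold-triggering deflections, decoder failures (every intended
synthetic trial crosses threshold), spontaneous (unrequested) movement
intentions, and any vascular/behavioral nonstationarity.  Tests
establish that the *procedures* are correct and calibrated, not that
the biological effects exist.

## Spiking analyses

Rates: 1 ms binning, Gaussian kernel SD 50 ms truncated at +/-4 SD and
normalized to unit area, scaled to Hz — so the rate integral equals the
spike count for interior spikes (checked to 1e-6).  Evoked onset: first
bin where the trial-averaged rate exceeds baseline mean + 5 x baseline
SD, *sustained for >= 10 ms* — the sustain requirement suppresses
single-bin noise, since the source rule specifies only the 5 x SD
threshold.  Baseline defaults to -2,000..-1,500 ms pre-event.

Report-perturbation robustness follows the published procedure:
for widths 10..1,000 ms (step 10), re-align to uniformly jittered
reports and call the response *degraded* once >= 10 bins differ from
the unperturbed average at p < 0.01 (per-bin unpaired t); the tolerated
width is the largest non-degraded width.  Note the direction of its
SNR dependence: a stronger, sharper report-locked response is
significantly altered by *smaller* jitter, so tolerated width shrinks
as response SNR grows (the acceptance suite asserts exactly this
monotonicity).

Sliding spike-count correlations use a 1,000 ms window (the default
pre-action window is the second before movement), Pearson r per unit
against report times, p < 0.05 two-sided; windows with zero count
variance are undefined and counted not-significant.  Type-I behavior is
calibrated in the acceptance suite (1,000 null units, 15 trials ->
flagged fraction within [2%, 8%]).

### Single-trial sigmoid fits

Model: `f(t) = f_I / (1 + exp(-(t - t0)/alpha)) + f_b`, fit by least
squares with bounds f_b >= 0, alpha > 0, t0 inside the window
(default -2,000..+200 ms around the reported intention).  Multi-start:
a coarse grid over t0 (100 ms steps) x alpha (5/20/60/150 ms) with the
linear pair (f_b, f_I) solved in closed form at each node, then bounded
local refinement from the best three nodes; if refinement ever lands
above the best grid node the grid solution is returned, so the output
residual never exceeds any grid start's (a tested invariant).  r^2 may
be negative for a nonlinear fit; retention uses r^2 > 0.5 (strict), so
this is benign and negative values are reported as-is.

Session-level fitting is two-stage, mirroring the published selection
(34 units -> 177 trials): a unit's trials enter only if the fit of the
unit's *average* report-aligned response has r^2 > 0.5 with a positive
step.  Without the screen, trial fits from unresponsive units pass the
retention threshold on smooth autocorrelated noise and scatter their
change-points across the window, dominating the t0 distribution.
Session fits run on a 10 ms grid (well below the 50 ms kernel SD) to
keep the full-session fit under a minute.

Parameter-recovery testing fits the *average* of 200 Poisson trials:
at the stated rates (5 -> 20 Hz) a single trial contains ~6 spikes in
the 300 ms after the step, so single-trial estimates are not
identifiable to the tested precision and the retention rule would add
selection bias; the averaged-fit route recovers t0 to ~10 ms and alpha
to ~20% and is the standard PSTH practice.

## Decoder pipeline

Artifact blanking: an artifact is a sample exceeding 500 uV on >= 4 of
12 monitored channels (drawn once per session); each detection blanks
3.5 ms (105 samples at 30 kHz) on all channels by linear interpolation
across the gap.

MWP features: per channel, an 11-level DWT (db4 by default — the
wavelet order is an undocumented dialect knob, so it is configurable);
mean squared detail coefficients of levels 3-6 (234.375 Hz-3.75 kHz at
30 kHz, `fs/2^(l+1)..fs/2^l`) per 100 ms bin, z-scored per channel
against a trailing 10 s baseline (global statistics while the history
is short).  Near a band edge the DWT's soft roll-off can place a tone's
maximum in the neighboring level; the mapping test therefore uses
band-central tones.

Classifier: per movement (HC, HO), an L1 linear-SVM ranking keeps the
most valuable half of the MWP features (the "sparsity optimization"),
then an RBF SVM is fit on the retained features; decision scores are
scaled by the largest training margin and clipped to [-1, 1], so the
zero threshold sits at the decision boundary.  Both stages are seeded.
The estimator follows scikit-learn conventions (get_params/set_params,
fitted attributes with trailing underscores) and composes with sklearn
model selection.

Trace measures: threshold crossing = first bin >= 0 after a sub-zero
bin; objective intention time = first bin above rest-noise mean + 5 SD
(rest noise pooled from >= 5 s of pre-trial segments); AUC = trapezoidal
time-average over -2,000..+2,000 ms around action (signed, since the
trace is already normalized to [-1, 1]); divergence = per-bin unpaired
t-tests, Bonferroni-corrected over bins, earliest corrected p < 0.01.

## Population analyses

PCA is fit on time-concatenated condition-average channel rates
(channels as variables), per the published procedure; the bootstrap
(1,000 draws by default) resamples trials with replacement, recomputes
condition means, *refits PCA per draw*, and takes percentile 95% CIs of
the per-bin 2-D Euclidean distance.  Channel-rate stacks for these
analyses use 20 ms bins — far below the 50 ms smoothing kernel, so no
information is lost, while keeping the memory of a 96-channel,
300-trial session modest.

LFP band power: complex-Morlet CWT (cmor1.5-1.0), 0.5-30 Hz, after
anti-aliased decimation to ~125 Hz; power normalized per frequency to a
baseline window.  Band classification compares baseline power
(-2,200..-2,000 ms) against each 100 ms step in -2,000..+2,000 ms with
a 10-fold cross-validated RBF SVM and a one-sided binomial test
against chance at p < 0.01.  CV folds are grouped by trial: each trial
contributes one baseline and one induced sample, and ungrouped splits
would place a sample's near-identical twin in the opposite class of
the test fold, biasing accuracy below chance under the null (a
measured effect, ~0.31 instead of 0.50).  Band edges: delta 0.5-4,
theta 4-8, alpha 8-13, beta 13-30 Hz (the upper beta edge is a
documented choice).  Note the temporal resolution limit: at 2 Hz the
Morlet support is several hundred ms, so a power envelope switching on
at -1,000 ms becomes separable earlier than its true onset.

The AUC-tertile report analysis standardizes AUC within condition
before pooling: decoder AUC differs systematically between conditions
(the no-action chain collapses early, the no-effect chain holds
longer), and pooling raw AUCs would sort trials by condition rather
than by per-trial decoding quality.

## Problem sizes

The default synthetic session is full-size (6 x 50 trials, 96
channels, 66 sorted units, 3 LFP channels) and is what
`scripts/acceptance.py` analyzes end-to-end (~1 min).  Unit tests use
reduced sessions (10 trials/condition, 16 channels, 12 units) where
only structural realism matters; simulation-based calibrations use the
counts stated in their docstrings (e.g. 1,000 null units, 500 null
divergence simulations, 100 binding seeds, 1,000 circular-median
inputs).  Bootstrap defaults stay at 1,000 draws in the library; tests
and the acceptance script use 40-200 draws, which is ample for a mean
curve and 95% band at test tolerances.

## Known limitations

* The generator's report-noise truncation slightly narrows the
  intention-report SD relative to the nominal value (~7% at the default
  bias), and pooled SEMs are reported at the pooled n, so they are not
  numerically identical to the per-condition values that inspired the
  defaults.
* Responsive units whose step *timing* tracks the latent intention also
  produce genuine (negative) count-report correlations; the measured
  fraction of significantly correlated units therefore exceeds the 12%
  injected-gain fraction.  Both mechanisms are real consequences of the
  generative model.
* `alpha` estimates from smoothed single-trial rates are biased upward
  by the smoothing kernel (the mean more than the median, because the
  retention rule keeps some ramp-like noise fits); the recovery test
  works on averaged rates where the bias is negligible.
* The IE condition's decoder collapse and the no-effect hold are
  piecewise-linear stylizations; only their ordering relations (earlier
  fall, longer hold) are treated as meaningful.
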