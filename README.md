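# intentchain

Analysis pipeline for clock-based intentional-chain experiments run
through a brain-machine interface (BMI): subjective-timing (Libet
clock) statistics, M1 spiking analyses including single-trial logistic
change-point fits, the wavelet-power movement decoder and its derived
measures, and population-level (PCA / LFP band-power) analyses — plus a
synthetic-session generator that emulates the experiment's statistical
structure so every stage is testable without any data download.

It is written for electrophysiologists and BMI researchers analyzing
paradigms in which elements of the *intentional chain* — the intention
to move (I), the action itself (A), and its environmental effect (E) —
are selectively enabled or bypassed while a participant timestamps one
of them on a rotating clock (2,560 ms cycle, 60 ticks) and neural
activity (96-channel multi-unit spiking, sorted units, LFP, and the
online decoder output) is recorded.

## The core models and statistics

**Clock reports.**  A report is a clock position; the occurrence of
that position nearest the objective event gives a signed offset in
(-cycle/2, +cycle/2].  Per-condition timing is the in-sample *circular
median* (the sample point minimizing summed geodesic distance on the
cycle); condition contrasts are two-sided Wilcoxon rank-sum tests on
the unwrapped offsets; relative action-to-effect timing is the median
over all cross pairs of estimate differences.

**Single-trial change points.**  Firing rates approaching the reported
intention time are fit per trial and unit with the logistic

    f(t) = f_I / (1 + exp(-(t - t0)/alpha)) + f_b

where `f_b` is the baseline rate, `f_I` the step amplitude, `t0` the
change-point time relative to the reported intention, and `alpha` the
steepness scale (small alpha = step-like, large = ramp-like).  Fits use
a (t0, alpha) grid with the linear pair solved in closed form, then
bounded refinement; trials are retained when r² > 0.5.

**Movement decoding.**  Mean wavelet power (MWP): 11-level Daubechies
DWT per channel, detail levels 3-6 (235 Hz-3.75 kHz at 30 kHz) averaged
in 100 ms bins and z-scored — feeding a sparsity-pruned RBF SVM whose
score in [-1, 1] triggers movement at zero crossing.  Derived measures:
objective intention time (first excursion 5 SD above rest noise),
per-trial decoder AUC (signed time-average over ±2 s around action),
surrogate-window crossing rates, and Bonferroni-corrected per-bin
t-tests for condition time-course divergence.

**Population dynamics.**  PCA on time-concatenated condition-average
channel rates with trial-resampling bootstrap distance curves in the
top-2 space, and Morlet-CWT LFP band power (delta/theta/alpha/beta)
classified baseline-vs-induced with a 10-fold cross-validated SVM.

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

Generate a full-size synthetic session (six conditions × 50 trials, 96
channels, 66 sorted units) and run the behavioral and decoder stages:

```python
from intentchain import pipeline
from intentchain.behavior_analysis import summarize_reports, summaries_to_frame
from intentchain.synthetic_data import GeneratorParams, generate_session

bundle = generate_session(GeneratorParams(seed=42), seed=42)
print(summaries_to_frame(summarize_reports(bundle)).to_string(index=False))
```

```
condition     query  n  median_offset_ms    sem_ms
      IAE INTENTION 20       -762.528019 55.333486
      IAE    ACTION 15       -415.816551 48.635521
      IAE    EFFECT 15       -483.006642 31.942352
       AE    ACTION 25       -464.422582 27.743188
       AE    EFFECT 25       -500.080775 20.756620
       IE INTENTION 25       -620.241120 53.007053
       IE    EFFECT 25       -501.541269 26.659789
       IA INTENTION 25       -715.307651 74.006496
       IA    ACTION 25       -448.365824 33.222312
   A_ONLY    ACTION 50       -428.307688 19.300026
   E_ONLY    EFFECT 50       -520.904986 18.673410
```

Each row is one condition × judgment type: `median_offset_ms` is the
circular median of report offsets from the objective event (negative =
reported earlier than it happened — the generator injects the
experiment's anticipatory biases of roughly -600/-455/-512 ms for
intention/action/effect), and `sem_ms` its standard error.  Intention
reports are visibly earlier and noisier than action and effect reports.

```python
table = pipeline.decoder_trial_table(bundle)
intended = table[table.condition.isin(["IAE", "IA", "IE"])]
lead = (intended.crossing_ms - intended.objective_intent_ms).dropna()
print(f"objective intention precedes threshold by {lead.mean():.0f} ms on average")
print(pipeline.mua_summary(bundle).to_string(index=False))
```

```
objective intention precedes threshold by 610 ms on average
             group  n_trials  onset_ms  peak_time_ms  peak_rate_hz
    intention_only        50   -1220.0        1629.0     17.248964
movement_no_intent       100     -90.0         374.0     29.614571
        full_chain        50   -1144.0         373.0     35.219625
```

On movement trials the evoked multi-unit response peaks ~373 ms after
action (the generator's NMES-transient latency); on intention-bearing
trials evoked activity rises long before movement, and the decoder
detects intention (5 SD rule) well before the movement threshold is
crossed.

A thin CLI wraps the same functions:

```bash
intentchain simulate --seed 1 --out session/     # write a bundle to disk
intentchain validate session/                    # schema + invariant check
intentchain behavior session/ --out report.csv   # tidy report statistics
```

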