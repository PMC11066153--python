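# Methods

## The experiment being emulated

A rat stands on a motorized platform that executes one of four tilt types
(fast/slow × clockwise/counter-clockwise) in randomized, balanced order
with ~100 trials per type and per session. Multi-unit activity is recorded
bilaterally from hindlimb sensorimotor cortex; one hemisphere (*direct*)
feeds a tilt-type classifier that rights the platform when it decodes the
tilt correctly, the other (*indirect*) is recorded only. A day-0 baseline
session (400 trials, no closed loop) precedes daily training sessions.
Animals that string together five consecutive training days above their
day-1 performance are *learners*; yoked *controls* receive matched tilts
and rewards without neural control.

## Synthetic spike trains

Each neuron is an inhomogeneous Poisson process on the ±200 ms peri-tilt
window with rate

    λ(t) = r_bg + A_s · exp(−(t − (ℓ_s + δ))² / 2w²)

where `r_bg` is the background rate, `A_s` and `ℓ_s` the amplitude and
latency for the trial's tilt type `s`, `w` the response width, and
`δ ~ N(0, σ_jitter)` a per-trial shift of the bump center (jitter is per
trial, not per spike, so shrinking it increases spike-*timing* information
without changing counts). Sampling is by thinning: candidates are drawn at
the per-trial rate ceiling `r_bg + A_s` and accepted with probability
`λ(t)/(r_bg + A_s)`. A single seeded generator threads through every
stochastic call, so sessions, cohorts and all downstream analyses are
reproducible bit-for-bit.

Baseline rosters draw per-neuron parameters from ranges typical of
sensorimotor cortex unit recordings: background 3–12 spikes/s, evoked
amplitudes ~15–40 spikes/s with a ±50% per-tilt modulation, latencies
30–110 ms, jitter 5–15 ms, response width 10–25 ms.

### Day-by-day trajectories

Training dynamics are imposed by per-day adjustments to the baseline
specs; day 0 is always the identity.

| group      | tilt-type separation (direct)          | other dynamics |
|------------|----------------------------------------|----------------|
| learner    | ×1 → ×2.5, saturating, τ = 5 days      | direct jitter ×1 → ×0.6; indirect latency +20 ms early, relaxing late |
| nonlearner | ×1 → ×0.8 (−2%/day, disengagement)     | — |
| control    | flat                                   | — |

"Separation" scales each neuron's amplitude spread about its mean, so a
learner's PSTHs for different tilts move apart without changing its mean
drive. All groups share a slow +2%/day background-rate rise (electrode and
engagement drift). The learner time constant gives the fast-early /
slow-late two-phase learning curve; the nonlearner decline encodes
task disengagement and makes the generating groups statistically
identifiable from finite data — a fully flat nonlearner would be labeled
a "learner" by the five-consecutive-days rule in ~26% of runs at ten
training days from symmetric noise alone, with no analysis able to do
better.

### What the generator does not emulate

Tilt kinematics (the four types are abstract categories), inter-trial
intervals, non-Poisson spiking (refractoriness, bursting), correlated
noise between neurons, electrode drift that changes unit identity, and
within-session learning. Passing tests therefore validate the analysis
chain's correctness and calibration on Poisson-like data with known
structure; they do not certify behavior on real recordings with
correlated or non-stationary noise.

## Analysis conventions

- **Binning.** Half-open bins `[left, right)`; a spike at exactly +200 ms
  is excluded. Decoder templates: 20 ms bins on ±200 ms (20 bins).
  Information: 0–200 ms post-tilt, 20 ms bins (timing) or one 200 ms bin
  (count). Responsiveness: 2 ms bins, background from [−200, 0) ms.
- **Classifier.** Raw binned counts vs trial-mean templates, no
  normalization. Distance ties break to the lowest tilt index, making
  decoding fully deterministic. Online decoding of day *d* uses day
  *d − 1* templates (day 1 uses the baseline) with the roster restricted
  to neurons that fired on both days; a neuron first seen today is held
  out until tomorrow.
- **Bias correction.** The label vector is permuted without replacement,
  responses untouched, and the leave-one-out classification re-run per
  shuffle; 50 shuffles by default. Probabilities are plug-in counts with
  0·log 0 = 0 — no smoothing, since the shuffle subtraction handles the
  sampling bias. The >0 inclusion filter is strict.
- **Responsiveness threshold.** Background mean + 2 SD of the 2 ms
  background-bin values (configurable), then a one-sided paired t-test at
  p < 0.001 of window rate vs background rate across trials. When the
  per-trial differences have zero spread the t-test is replaced by the
  sign of the mean difference.
- **Normalized variance.** `NV = var(c)/(mean(c) + ε)` with ε = 0.01 on
  single-bin 200 ms pre-tilt counts — the Fano-factor form, which is 1 for
  Poisson counts and 0 for constant counts. A `use_rate` switch instead
  scales counts to spikes/s by the 200 ms bin constant first (multiplying
  the ratio by 5); the count form is the default because its calibration
  against the Poisson ground truth is parameter-free. Per-tilt values are
  z-scored to the day-0 baseline distribution across neurons and averaged
  over the four tilts into one value per hemisphere-day.
- **Learning rules.** Learner = some run of ≥ 5 consecutive training days
  with accuracy strictly greater than day 1, evaluated on the offline
  (leave-one-out) series; early/late = first/last 5 training days; expert
  day = the training day of maximum offline accuracy, ties to the latest.
  The cumulative-sum r² is defined as 0 for a zero-variance response
  (all-incorrect sessions). Only the first 300 trials of a session enter
  any analysis.
- **Naive-vs-expert distances.** Per neuron,
  `d_n = sqrt(Σ_b (T1_b − T2_b)²)` on 20 ms ±200 ms PSTHs, averaged over
  neurons. Tilts are pooled into the side contrast (right fast+slow vs
  left fast+slow) and the speed contrast (fast both sides vs slow both
  sides). Both days are truncated to a common trial count before the
  PSTHs are built: the squared distance between noisy PSTHs carries a
  positive noise floor proportional to 1/n_trials, and matching counts
  keeps the naive and expert floors comparable.

## Problem sizes

The shipped drivers and self-characterization experiments run a reduced
cohort — 10 training days of 120 trials with 6 neurons per hemisphere and
the full 400-trial baseline — which preserves the experiment's structure
(4 tilt types, balanced order, two hemispheres, learner/nonlearner/control
groups) at a scale where a full simulate-decode-analyze cycle takes
seconds. Calibration experiments (chance level, bias nulls, Fano
calibration) use 400–4000 trials as stated in their docstrings.

## Known limitations

- Ensemble information saturates at 2 bits, so redundancy estimates
  compress for very informative ensembles.
- The shuffle-corrected estimator remains noisy for near-silent neurons
  (sparse single-bin responses make the confusion matrix lumpy); such
  units are usually excluded by the > 0 filter, but their single-run
  estimates have high variance.
- Leave-one-out nearest-template decoding is slightly pessimistic at
  chance (the held-out trial's own class template is pushed away), though
  the effect is below binomial noise at the trial counts used here.
- The learner rule is a run statistic on a noisy series; near-threshold
  animals can flip labels between seeds. The end-to-end recovery check is
  therefore framed over a cohort of seeds rather than per animal.
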