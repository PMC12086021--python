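# Methods

This note documents the models, conventions and numerical choices behind the
`oddball` package: what the analysis computes, what the synthetic-data
generator emulates (and what it does not), and where the design was
genuinely open.

## The analysis

The pipeline quantifies how a systemic pharmacological manipulation (the
serotonin-2A agonist DOI) changes sound responses of auditory-cortex
neurons recorded across three within-session periods — pre-injection,
saline and DOI — with identical stimulus ensembles in each period.

**Windows.** For every stimulus presentation, baseline activity is counted
in [−200 ms, 0 ms) and evoked activity in [onset + 15 ms, offset + 15 ms),
the 15 ms compensating ear-to-cortex transmission delay. Windows are
half-open so a spike on a boundary is counted exactly once; rates are
counts divided by window length. The 15 ms shift is applied to both edges
of the evoked window and not to the baseline window.

**Inclusion filters.** A neuron enters the population analyses when (1) its
mean spontaneous and mean evoked firing each change by at most 30 % between
the pre-injection and saline periods (both pooled over trials by default; a
per-stimulus variant of the evoked screen is exposed as an option, and a
change of exactly 30 % passes), (2) it is responsive in every period — for some
stimulus, the paired Wilcoxon signed-rank test of evoked vs baseline rate
across trials rejects after Bonferroni correction by the number of stimuli
tested — and (3) its best stimulus drives it strictly above 5 spk/s in
every period. Deviance-detection analyses additionally require the
neuron×stimulus oddball enhancement index to vary by strictly less than
30 % between pre-injection and saline. Relative changes use the
pre-injection value as denominator; a zero denominator passes only if the
compared value is also zero.

**Frequency tuning.** Mean evoked rate per tone frequency is fit with a
Gaussian on log2 frequency, r(x) = b + A·exp(−(x−μ)²/2σ²), by bounded
least squares (μ within the fitted frequency span, σ ∈ [0.05, 5] octaves,
A, b ≥ 0). Initialization is a deterministic grid — μ over the 16
log-frequencies, σ over {0.25, 0.5, 1, 2} octaves — with the six
lowest-initial-SSE starts refined and the best final SSE winning, ties
broken by grid order. Best frequency is 2^μ, tuning width the full width at
half maximum 2.355σ, and Max Δ firing the Gaussian peak (b + A) minus the
measured spontaneous rate. Octaves (log base 2) are used throughout; any
other base rescales σ.

**R² gate.** Neurons with A > 0 and R² > 0.05 enter the tuning-change
analyses. When trial-level responses are available, R² is computed against
the single-trial rates (residual variance of trials around the fitted
curve, relative to their total variance). This is deliberate: a
four-parameter Gaussian fit to 16 noisy per-frequency *means* captures a
substantial share of their between-frequency noise variance — flat neurons
frequently score mean-based R² well above 0.05 — whereas against
trial-level variance an untuned neuron scores near zero and genuinely
tuned neurons score far above the gate. The mean-based R² is still
reported (`r_squared_means`) for comparison with conventions that fit only
summary tuning curves.

**Deviance detection.** For each neuron, stimulus and period, O is the mean
evoked rate over the stimulus's oddball presentations and S the mean over
its standard presentations in the role-swapped companion block, both raw
by default (a baseline-subtracted variant is exposed as an option);
OEI = (O−S)/(O+S). Drug effects per role use
MI = (DOI−Sal)/(DOI+Sal). Both indices lie in [−1, 1] for nonnegative
responses and are undefined when the denominator is zero; undefined values
are excluded pairwise, never imputed. All standard presentations count
toward S (an option excludes the first standard after each oddball, off by
default). Population comparisons are two-sided Wilcoxon signed-rank tests
across neurons, per stimulus, α = 0.05 (exact distribution for small
samples without ties, normal approximation with continuity correction
otherwise; zero differences dropped; fewer than 6 valid pairs → p
undefined).

**Controls.** The adaptation control compares response changes across the
two period transitions on all neurons responsive to the stimulus,
regardless of OEI stability: signed-rank tests of the oddball response
pre-vs-saline and saline-vs-DOI, and a paired comparison of the per-neuron
MI(Pre→Sal) vs MI(Sal→DOI). The matched-resampling control re-tests the
drug effect on subsets of late-session neurons whose mean saline OEI
matches the early-session mean within 0.01 OEI units; subsets are found by
a random start followed by greedy element swaps toward the target
(deterministic under the seed, at most 10,000 iterations), after a
feasibility check against the sorted-extreme subset means. The default
subset size is the largest feasible size up to min(n_early, n_late); 100
resamples are drawn and the fraction with median saline OEI above median
DOI OEI reported. The early/late split is sessions 1–2 vs 3–5 per animal,
and the early-vs-late comparison of per-neuron effects uses the
Mann–Whitney U test.

**Variability.** The Fano factor per neuron and tone is the
variance-to-mean ratio of evoked responses across that tone's trials
(unbiased n−1 variance; undefined for fewer than 2 trials or zero mean),
computed on evoked-window spike counts — the classical count convention;
on rates it would differ by exactly the factor 1/window length, and the
convention is stated in outputs. A neuron's FF is the mean over included
tones; saline-vs-DOI comparisons are paired across neurons with the median
per condition and the percentage of neurons increasing. In
running/stationary splits a tone is included only with at least four
trials in each locomotion state; unsplit analyses require two.

**Locomotion.** The motion-energy trace is smoothed with a 10-frame square
window and the smoothed value at the frame nearest each onset is
thresholded. The default threshold is data-derived: the histogram split
maximizing between-class variance (Otsu), returned as the midpoint of the
two class means so it sits between the stationary and running modes.

## The generator

Neurons are log-frequency Gaussian-tuned rate units. The expected
evoked-window rate on a trial is baseline + A·exp(−(x−bf)²/2σ²) ×
g_oddball(role) × g_running(state), where x is the stimulus's effective
log2 frequency (tone or chord-center frequency; geometric mean of the
range for FM sweeps). Deviance detection is modeled as a multiplicative
gain g_oddball applied to the tuned component on oddball trials only, so
with no baseline the population OEI converges to (g−1)/(g+1).

Evoked-window counts follow a count process with controllable Fano factor
φ (variance = φ·mean): Poisson at φ = 1, gamma-mixed Poisson (negative
binomial, shape mean/(φ−1)) for φ > 1, and binomial thinning with
randomized rounding of n = mean/(1−φ) for φ < 1 — the last because
empirical cortical Fano factors often sit below 1. Spike times are placed
uniformly within windows (temporal response shape is irrelevant to every
implemented statistic); background spiking is homogeneous Poisson at the
per-period baseline rate, thinned out of evoked windows. Baseline-window
counts are therefore Poisson regardless of φ.

Session layout is fixed as pre → saline → DOI with identical paradigm
structure per period: a 16-frequency tuning block (2–40 kHz, ≥ 20
repetitions, ISIs uniform 1–1.4 s), a chord oddball paradigm (8 / 13 kHz
centers, 12 components in [f/1.2, 1.2f], 50 ms sounds at 550 ms onset
asynchrony) and an FM oddball paradigm (8–13 kHz up/down sweeps, 100 ms
sounds at 600 ms asynchrony), each oddball sequence with 9–11 standards
per oddball (uniform), at least 50 oddballs, and a role-swapped companion
block. Locomotion probabilities default to 0.44 / 0.20 / 0.72 per period
(pre / saline / DOI), with a default running gain of 1.2 on the evoked
component.

Population priors: baseline rates and tuning amplitudes lognormal (medians
3 and 20 spk/s, log-SDs 0.6 and 0.5), best frequencies uniform on the
log2 tuning range, tuning widths uniform in [0.3, 1] octaves. The default
drug condition reduces baseline and evoked rates by 20 %, drops the
oddball gain from 1.5 to 1.1 and raises dispersion from 1.0 to 1.3 under
DOI, with pre-injection and saline statistically identical. Per-neuron
heterogeneity enters twice: lognormal spread of the saline oddball gain
(log-SD 0.08) and lognormal spread of the *effect ratios* (DOI/saline gain
ratio and rate scale, log-SD 0.08). Setting the effect spread to zero
makes each neuron's DOI parameters equal its saline parameters exactly —
the definition of "no drug effect" used by the null studies. These
population distributions are chosen to be qualitatively realistic and
configurable; they are not fitted to any dataset, and reported effect
sizes depend on them.

All randomness flows from one seeded generator hierarchy with per-neuron
substreams, so neuron i is byte-identical regardless of population size.

**What the generator does not emulate.** Rate stationarity within periods
(no drug-onset time course, no adaptation drift), no temporal response
structure or latency jitter, no correlated variability between neurons
beyond the shared locomotion state, no multi-peaked tuning, and locomotion
as a binary state. Passing tests therefore demonstrate correctness of the
analysis chain under the assumed effect structure, not that real cortical
data satisfy those assumptions.

## Calibration findings worth knowing

Two properties of this analysis design surfaced in null
simulations (no drug effect) and are reproducible with the replicate
studies in `oddball.studies`:

* **The OEI-stability screen is anti-conservative.** Selecting
  neuron×stimulus cells with |OEI_sal − OEI_pre|/|OEI_pre| < 0.3
  conditions on the saline OEI; because the acceptance window scales with
  |OEI_pre|, selection favors larger |saline| OEI, and the screened
  saline-vs-DOI test rejects at roughly 0.15 instead of 0.05 under a true
  null at the default noise level. The unscreened test on responsive
  neurons is calibrated. Both tracks are reported.
* **Shared locomotion is a common shock.** When ~100 simultaneously
  simulated neurons share one session, the realized running fraction of a
  period's ~50 oddball trials fluctuates, and the running gain converts
  that into a rate shock common to all neurons — correlating them and
  inflating across-neuron paired tests (~0.07 instead of 0.05). Pooling
  neurons across many recording sessions, as a multi-session experiment
  naturally does, dilutes this; the
  type-I calibration study therefore uses stationary sessions, and
  locomotion effects are assessed by the running/stationary splits.
* The MI-difference comparison of the adaptation control
  (MI(Pre→Sal) vs MI(Sal→DOI)) is slightly anti-conservative even with
  exchangeable periods, because the two indices share the saline term and
  their difference is skewed; the two underlying response comparisons are
  calibrated, and under the null the two MI medians agree closely.

## Problem sizes

Default study sizes are chosen for desk-scale runs: 100-neuron
populations, 100 replicates for power studies, 500 for null calibration,
10,000 trials for count-process calibration, 100 simulated neurons for
tuning recovery, 100 matched resamples. The end-to-end session example
uses 60 neurons at the full paradigm (≈ 8,000 trials per neuron across the
three periods).
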