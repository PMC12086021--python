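# oddball

Analysis of auditory-cortex **oddball (deviance-detection) electrophysiology**
under pharmacological manipulation, plus a synthetic spike-train generator
that makes the whole chain testable end to end.

The package is written for systems neuroscientists analyzing trial-based
extracellular recordings from awake rodents: sessions in which the same
stimulus ensembles — a pure-tone frequency-tuning block and oddball sequences
of chords or FM sweeps — are presented before injection, after a saline
control injection, and after a drug (here the serotonin-2A agonist psychedelic
DOI), and the question is how the drug changes responsiveness, frequency
tuning, trial-to-trial variability and deviance detection.

## What it computes

For spike trains aligned to a trial table (baseline window −200–0 ms, evoked
window 15 ms after onset to 15 ms after offset):

* **Inclusion filters** — firing-rate stability between pre-injection and
  saline (≤ 30 % change in spontaneous and evoked rate), responsiveness
  (Wilcoxon signed-rank of evoked vs baseline, Bonferroni-corrected over
  stimuli, in every period), and an evoked floor (> 5 spk/s).
* **Frequency tuning** — Gaussian fits on log2 frequency,
  r(x) = b + A·exp(−(x−μ)²/2σ²), giving best frequency BF = 2^μ, tuning
  width 2.355σ (FWHM, octaves) and Max Δ firing, gated by R² > 0.05.
* **Deviance detection** — per neuron and stimulus, the oddball enhancement
  index **OEI = (O − S)/(O + S)** from the mean response to a sound as a rare
  oddball (O) vs the same sound as the repeated standard (S) in the
  role-swapped companion block; drug effects per role via the modulation
  index **MI = (DOI − Sal)/(DOI + Sal)**; paired signed-rank population tests;
  an adaptation control (pre→saline vs saline→DOI changes) and an
  OEI-matched resampling control for repeated-administration analyses.
* **Variability** — Fano factor FF = σ²/μ of evoked spike counts per tone,
  averaged per neuron, compared between saline and DOI, optionally split by
  locomotion state (≥ 4 trials per running condition per stimulus).
* **Locomotion** — running/stationary classification from a motion-energy
  trace (10-frame boxcar smoothing, thresholded at stimulus onset).

The generator (`oddball.simulate`) emulates the full experimental design —
16 log-spaced tone frequencies from 2–40 kHz, 12-component chords at 8 and
13 kHz, 8–13 kHz FM sweeps, 9–11 standards per oddball with ≥ 50 oddballs and
role-swapped blocks, three periods with configurable drug effects on rate,
oddball gain and count dispersion — from a single seed, reproducibly.
See `docs/methods.md` for the model and its assumptions.

## Worked example

Simulate a 12-neuron session and run the full analysis:

```sh
oddball simulate --seed 42 --out-dir demo/session --n-neurons 12
# -> wrote session with 12 neurons, 7571 trials to demo/session
oddball report --session demo/session --out-dir demo/results
# -> report written to demo/results
```

`demo/results/summary.json` then contains (excerpt):

```json
{
  "n_neurons": 12,
  "n_included": 10,
  "oei": [
    {"stimulus_id": "chord_13kHz",
     "median_oei_saline": 0.2027, "median_oei_doi": 0.1060, "n": 3},
    {"stimulus_id": "chord_8kHz",
     "median_oei_saline": 0.1414, "median_oei_doi": -0.0152, "n": 2}
  ],
  "mi": [
    {"stimulus_id": "chord_13kHz",
     "median_mi_oddball": -0.2164, "median_mi_standard": -0.0970, "n": 10}
  ],
  "fano": {"all": {"median_a": 1.033, "median_b": 1.270,
                    "p": 0.00195, "pct_increased": 100.0, "n": 10}}
}
```

Reading: 10 of 12 simulated neurons pass the inclusion filters. The median
OEI drops from saline to DOI for both chords (deviance detection is reduced),
but with only 2–3 OEI-stable neurons per stimulus the paired test reports no
p-value (n < 6). The modulation index is negative for both roles and more
negative for oddballs — responses to rare sounds are suppressed more than
responses to common ones. The neuron-level Fano factor rises from 1.03 to
1.27 (the configured DOI dispersion increase), with 10/10 neurons increasing,
p ≈ 0.002. At realistic population sizes (the generator default is 100
neurons) the OEI tests are well powered; see `oddball.studies`.

Per-stage artifacts (`inclusion.csv`, `tuning.csv`, `oddball.csv`,
`fano.csv`, scatter figures) land next to `summary.json`; the `filter`,
`tuning`, `oddball` and `fano` subcommands run the stages individually.

### Session file formats (schema v1)

* `spikes.csv` — `neuron_id, spike_time_s` (one row per spike).
* `trials.csv` — `onset_s, stimulus_id, role, period, block_id, running,
  duration_s`, with `role ∈ {standard, oddball, tuning}`,
  `period ∈ {pre, saline, doi}` and `running ∈ {true, false, unknown}`;
  onsets strictly increasing.
* `motion.csv` — `motion_energy` (one row per video frame) — optional; used
  to classify locomotion when `running` is unknown.

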