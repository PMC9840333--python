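# neurochirp

Chirp-evoked EEG time–frequency analysis and TMS–EMG corticospinal
metrics, with a synthetic-session generator that makes every stage of
the pipeline testable offline.

The EEG arm reproduces a standard auditory-chirp steady-state paradigm:
a 1000 Hz tone amplitude-modulated by a linear 0→120 Hz sweep over 2 s,
presented 160 times with 1500–2500 ms jittered ISIs. Epochs are cleaned
(0.5–150 Hz bandpass + 60 Hz notch, SD-based channel rejection, ±200 µV
epoch rejection), averaged into four scalp ROIs, decomposed with complex
Morlet wavelets, and summarized as ERSP (dB) and inter-trial coherence
(ITC) maps. Onset (0–500 ms) and entrainment (750–2250 ms) masks are
thresholded (ITC ≥ 0.13) on the pooled frontal ITC map and used to
extract per-subject band summaries (theta/alpha/beta on onset,
low/high gamma on entrainment), which feed a one-way ANOVA with
Shapiro–Wilk/Levene assumption checks and variance-aware post-hoc
routing (Tukey HSD or Games-Howell).

The TMS arm computes peak-to-peak MEPs, SICI/ICF/SICF ratios over
baseline, per-trial LICI ratios, cortical silent period durations, and
input/output curves from EMG trial traces.

Because no recordings ship with the package, `neurochirp.synth`
generates sessions with controllable structure: 1/f background noise, a
phase-locked onset theta burst, an entrained component tracking the
stimulus AM frequency (von Mises trial-phase model, κ = 0 uniform …
κ → ∞ perfect locking), blink-like artifacts, bad channels, and EMG
blocks with programmed ratios / silent periods. Every generator is a
pure function of (params, seed).

## Layout

| module                  | role |
|-------------------------|------|
| `neurochirp.synth`      | chirp stimulus, trial schedules, EEG sessions, EMG trials |
| `neurochirp.preprocess` | filtering, channel/epoch rejection, epoching, ROI averaging |
| `neurochirp.tfr`        | Morlet decomposition, ERSP, ITC |
| `neurochirp.masks`      | onset/entrainment masks, band summaries, extraction table |
| `neurochirp.stats`      | assumption checks, one-way ANOVA, post-hoc routing |
| `neurochirp.tms`        | MEP, paired-pulse/LICI ratios, CSP, I/O curves |
| `neurochirp.io`         | flat-binary + JSON container, WAV/CSV export |
| `neurochirp.pipeline`   | end-to-end drivers (subject maps, replicate group studies) |

## CLI

```bash
# synthesize a session, preprocess it, map it
neurochirp simulate eeg --group carrier --seed 1 --kappa 8 --out session/
neurochirp preprocess --in session/session --schedule session/schedule.csv \
    --roi Fz --out work/epochs
neurochirp tfr --epochs work/epochs --out work/maps/s01_Fz

# band extraction and group stats
neurochirp extract --maps work/maps --out summaries.csv
neurochirp stats --summaries summaries.csv --out stats.csv

# TMS arm
neurochirp simulate emg --protocol LICI100 --ratio 0.4 --out emg/
neurochirp simulate emg --protocol baseline --out emg/
neurochirp tms --trials emg/ --out tms.csv
```

## Notable conventions

- Channel-SD rejection bounds (2–120) are interpreted in µV.
- Morlet cycles rule `max(3, f/2)`; baseline −800…−200 ms, divisive on
  trial-averaged power; dB = 10·log10(power ratio). Cells within half a
  wavelet of an epoch edge are flagged invalid and excluded everywhere.
- Mask threshold is inclusive (ITC ≥ 0.13); band edges are half-open.
- MEP search window 15–60 ms post-pulse; CSP uses a 5 ms moving-average
  rectified envelope with a 50 % of-baseline, ≥ 10 ms-sustained return
  criterion.
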