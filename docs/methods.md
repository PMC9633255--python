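# Methods

`dsirlab` simulates the measurement of a *dichotic spectral integration
range* (DSIR): the frequency range, from a lower-bound cutoff up to
8,000 Hz, that one ear needs for consonant recognition when the opposite
ear simultaneously receives only low-frequency information from the same
consonant.  The pipeline has five stages — stimulus synthesis, AI-Gram
spectro-temporal processing, dichotic filtering, a simulated listener, and
adaptive tracking — plus summary metrics.  This note documents the model
at each stage, the parameters that matter, and the design choices made
where the design was genuinely open.

## Synthetic stimuli

Real measurements of this kind use recorded consonant–vowel (CV) syllables
from a single talker.  The package instead synthesises the 14 CV tokens
parametrically so that every downstream stage is testable without
recordings:

- **Sampling rate** 44,100 Hz, fixed throughout.
- **Durations** per consonant from the bundled registry
  (`data/consonant_regions.csv`): 240–550 ms, mean 406.57 ms.
- **Vowel segment**: harmonics of F0 = 228 Hz (a female mean F0) under an
  /ɑ/-like formant envelope (F1/F2/F3 = 700/1200/2600 Hz, bandwidths
  110/120/160 Hz) with a −6 dB/oct source tilt and seeded random harmonic
  phases.  It occupies the token from the end of the consonant-cue window
  to the token offset.
- **Consonant cue**: band-limited noise (4th-order zero-phase Butterworth
  band-pass) restricted to the consonant's *target frequency band* and
  placed in its *target time window*, at 5× the vowel RMS.  This locks the
  cue's energy to the tabulated target region: across all 14 consonants,
  ≥ 93 % of the cue-window energy falls inside the target region (the test
  suite requires ≥ 50 %).
- **No silent edges**: a low-level noise floor (−40 dB re vowel) runs
  throughout, emulating recordings whose silent onsets/offsets were
  trimmed, without needing a trimming algorithm.
- **Conditioning**: 8-kHz band-limiting (2nd-order Butterworth low-pass,
  zero-phase) followed by normalisation to a long-term RMS of 0.05 full
  scale.  Absolute SPL and headphone equalisation are not modelled.

What the generator does *not* emulate: talker variability, coarticulation,
formant transitions, voicing onset asymmetries between consonant classes.
Tests that pass on these tokens therefore validate the *measurement
machinery* (processing, filtering, tracking, metrics), not claims about
human perception of natural speech.

## AI-Gram processing

Three conditions are applied to a token's STFT:

- `unprocessed` — identity (bitwise).
- `target` — +6 dB on the target frequency × time region.
- `target_conflicting` — target processing, then removal (zeroing) of the
  conflicting frequency band, under the **overlap rule**: any part of the
  conflicting band inside the target band is left intact.  With the
  tabulated bands this means nothing is removed for /pa/ and /ba/
  (conflicting ⊂ target) and only 3.5–3.6 kHz is removed for /za/.

STFT parameters: 20-ms Hann window, 50 % hop, 1024-point FFT.  This
overlap-add configuration reconstructs exactly (round-trip residual
≈ −310 dB; the suite requires ≤ −60 dB).  Numerical choices:

- Band/time membership is by bin-centre and frame-centre within closed
  intervals; band values are interpreted as inclusive intervals in kHz.
- **Gain masks**: the full linear gain covers the region *extended by one
  bin/one frame*, with a raised-cosine ramp outside that plateau.
  Extending outward (rather than ramping inside the region) keeps the
  measured in-region boost at 6.0 ± 0.1 dB despite the window smearing of
  re-analysis; the leak into the complement changes its RMS by < 0.1 dB.
- **Removal masks** zero the in-band bins (ramp outside) and are applied
  in *two* analysis–synthesis passes.  A single pass leaves ≈ −27 dB
  in-band residual due to the spectral shoulders at the band edges (window
  main-lobe width ≈ 200 Hz); the second pass attenuates the shoulders
  again, reaching ≈ −33 dB for broadband input (suite requires ≤ −30 dB).
  Removal bands derived from the overlap rule additionally carry a
  *protected band*: mask values inside the target band are forced back to
  unity so the removal ramp can never touch the target band (asserted as
  a mask invariant).
- The conflicting band has no tabulated time window, so removal spans the
  full token duration — the most conservative reading.
- An empty removal band is a no-op; removal means zeroing, not finite
  attenuation.

## Dichotic filtering

The LF (left) ear receives the processed token low-pass filtered at one of
the four fixed cutoffs 250/500/750/1,000 Hz; the HF (right) ear receives
it high-pass filtered at the adaptive cutoff (7,000 Hz start, 100-Hz
grid).  Both filters are 5th-order Butterworth designs (30 dB/oct nominal
roll-off), applied forward–backward (`sosfiltfilt`, reflected edge
padding), so the net group delay is zero and symmetric inputs stay
symmetric to machine precision.

Two deliberate readings of the filter specification:

- **"30 dB/oct" is the single-pass design slope.**  Zero-phase
  application squares the magnitude response, doubling the effective
  attenuation; the roll-off figure names the design, and zero-phase
  application is specified separately, so the probe `measure_rolloff`
  reports the single-pass slope.
- **The roll-off probe evaluates the continuous-time prototype.**  The
  digital realisation (pre-warped bilinear transform; −3 dB exactly at the
  cutoff) is steeper than 6 × order dB/oct near Nyquist because of
  frequency warping — e.g. a 2nd-order 8-kHz low-pass has no usable
  digital stopband octave below Nyquist at all.  The asymptotic slope is a
  property of the Butterworth family, so the probe evaluates the analog
  prototype magnitude at two stopband frequencies one octave apart,
  recovering 6 × order dB/oct to within 0.3 dB for orders 1–6.

## Simulated listener

Human subjects are replaced by a psychometric observer over 15 response
options (14 consonants + "none of these"):

    P(correct) = γ + (1 − γ) · logistic(k · (c − θ))

where *c* is the **coverage**: the fraction of the consonant's target
frequency band inside the delivered union [0, LPF] ∪ [HPF, 8000] Hz.
Coverage uses the frequency dimension only — the dichotic manipulation is
purely spectral, and the full time course is always delivered.

Parameters and defaults:

- γ = 1/15 (chance on the nominal 15-alternative paradigm), configurable.
- k = 10 by default (a moderately sloped observer); k = ∞ gives a step
  observer, k = 50 a sharp one (used for parameter-recovery tests).
- θ = 0.5 for every consonant by default: recognition requires half the
  target band.  Per-consonant thresholds and per-condition offsets (e.g.
  a lower θ under target processing, emulating an AI-Gram benefit) are
  supported but off by default, so the default experiment shows no
  processing effect — DSIR differences between consonants then emerge
  purely from where their target bands sit relative to the delivered
  bands.
- Foils on incorrect draws: uniform over the 14 remaining options, or
  weighted by target-band overlap (a crude confusability proxy).

Backends: the default `cutoff` backend computes coverage by interval
arithmetic (exact for ideal filters, fast enough for full experiments);
the `waveform` backend estimates the same quantity as a Welch band-power
ratio of the delivered channels to the processed token, exercising the
full DSP path.  The waveform estimate reads systematically lower near the
transition (zero-phase filtering doubles the skirt attenuation), so tracks
run through it converge a step or two below the interval-arithmetic
prediction; it is an end-to-end verification path, not the default.

## Adaptive tracking

One track per cell (consonant × condition × LPF cutoff): the HPF cutoff
starts at 7,000 Hz; an incorrect response resets the consecutive-correct
counter and lowers the cutoff by 100 Hz; the track converges at three
consecutive correct responses, returning that cutoff as the DSIR lower
bound.  Properties:

- A deterministic step observer with threshold C* on the grid is recovered
  exactly for every C* ∈ [100, 7000] (exhaustively tested).
- Track length is structurally bounded by 3 + 3 · (7000 − floor)/100
  trials (at most two corrects precede each decrement).
- Tracks that reach the floor cutoff (default 100 Hz, the grid's last
  positive value) without converging are flagged `floored` and excluded
  from summary means (with a surfaced count) rather than imputed.
- The consecutive-correct counter resets to zero on *any* error — the
  strict "three in a row" reading.

The full experiment replays 14 simulated subjects × 3 conditions × 4 LPF
cutoffs × 14 consonants = 2,352 tracks.  Consonant order is randomised
within each block; each track draws from an RNG substream keyed by
(master seed, subject, condition, LPF, consonant, repetition), so any cell
is independently reproducible.  With the default cutoff-backend listener
the complete design runs in well under a minute on one CPU.

A repeated presentation schedule can be read two ways: as one continuous
track per cell (default, `n_repetitions = 1`) or as several independent
tracks per cell (`n_repetitions > 1`).  The continuous reading is the
default because the stopping rule is defined on a single response stream.

## Metrics

A DSIR lower bound *x* maps to a percentage of the 0–8,000 Hz band as
(8000 − *x*)/8000 × 100 (e.g. 3,198 Hz → a 4,802-Hz range → 60 %), with
`invert_pct` as its exact inverse.  Summaries are mean ± SE (sample SD /
√n) per cell; per-consonant percentages are averaged across subjects
first, then correlated between LPF cutoffs (Pearson, 250-Hz reference,
Bonferroni-corrected α = 0.05/3 for the three tests sharing the
reference).  Cell means are converted to percentages after averaging
(convert-the-mean); converting per track first and averaging is available
by summarising the `pct_of_band` column directly.

## Known limitations

- The synthetic tokens are spectro-temporal stand-ins; no claim is made
  that the simulated DSIRs match human data numerically.  The headline
  *qualitative* property — DSIRs narrow (lower bounds rise) with more
  low-frequency information in the LF ear — is reproduced as a simulation
  property of the coverage listener.
- Repeated-measures ANOVA and pairwise hypothesis testing of the design
  factors are out of scope; only the correlation analysis is provided.
- The registry's tabulated duration column has mean 406.57 ms; its often
  quoted ±102.61 ms spread is not reproducible from the tabulated values
  (sample SD ≈ 109.6 ms) and is not asserted anywhere.
- WAV output is PCM-16 or float32; 24-bit files are read but not written.
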