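# Methods

## The detection problem

A single stored-product insect (a beetle larva or adult moving through
grain) produces trains of short elastic-wave impulses — 3 to 30 ms
each, broadband, with most energy between roughly 1.5 and 6 kHz.
Piezoelectric contact sensors inside a sound-insulated sampling
container pick these up, but ambient noise at an inspection facility
(machinery, speech, vehicles) penetrates the enclosure and produces
impulses of similar shape on the same sensors. This package implements
the full signal chain that separates the two: a normalized pulse
statistic, an optimized analysis band, and a reference-microphone
noise-removal step, followed by a two-criterion decision.

## The NSPA chain

Each channel is processed as:

1. **Band-pass filter.** A Butterworth band-pass with magnitude
   `M(f) = [1 + ((fc² − f²)/(f·fΔ))^{2n}]^{-1/2}`, `fc = √(f1·f2)`,
   `fΔ = f2 − f1`. The gain is exactly `1/√2` at both edges for every
   order — an algebraic identity (`fc² − f1² = f1·fΔ`) the tests
   exploit. The filter is applied forward-backward (zero phase), so the
   effective magnitude is `M(f)²` and impulse timing is preserved for
   the 10 ms peak-matching step; the digital design pre-warps the edge
   frequencies so the half-power points land exactly on f1 and f2.
   Default order n = 4: steeper roll-off buys little once the response
   is squared, while higher orders ring longer on millisecond impulses.
2. **Envelope.** `S_E = |S + i·H{S}|` via the FFT analytic-signal
   method on the full record (padded to an FFT-friendly length).
3. **Normalization.** `V = S_E / RMS(N_E)`, where `N_E` is the same
   filtered envelope computed on a self-noise reference recorded with
   no insect present. V is dimensionless: V ≈ 1 is the sensor's own
   noise floor. The RMS is taken over the whole reference record.
4. **NSPA.** `NSPA = 20·log10(RMS(V))` over the analysis region
   `0.5·Vmax ≤ V ≤ 0.9·Vmax` (bounds inclusive) — the amplitude band
   where insect pulses concentrate, deliberately excluding both the
   noise floor and the single largest excursion.

Degenerate inputs: the region is empty only for a near-constant
envelope (every sample above `0.9·Vmax`); the implementation then falls
back to `V ≥ 0.5·Vmax` and flags the result. An all-zero envelope has
no defined NSPA and raises. Vmax is searched excluding the first and
last 5 ms of the record, and peak detection ignores the same margins:
the finite filter and Hilbert transform both produce edge transients
there. The same 5 ms guard is the only place the implementation
deviates from the idealized infinite-support definitions.

Two invariances follow from the construction and are property-tested:
`NSPA(aV) = NSPA(V) + 20·log10(a)`, and invariance under joint scaling
of the raw signal and its reference (sensor sensitivity cancels, which
is why uncalibrated sensors are usable at all).

## Analysis band

Ambient noise concentrates its power below ~1600 Hz while insect
impulses keep theirs above; the default band is therefore
**1565–6000 Hz**. The original 500–6000 Hz band remains selectable
(`LEGACY_BAND`). `optimize_lower_frequency` reproduces the band choice
empirically: it sweeps f1, recomputing the baseline and every NSPA per
candidate band, and maximizes (mean insect NSPA − max noise NSPA) —
the worst-case noise is what sets the false-alarm threshold. A
coarse-to-fine search (default 250 Hz grid, 50 Hz refinement around
the coarse argmax) resolves the optimum without evaluating the fine
grid everywhere.

## Noise removal

The penetration coefficient K is the amplitude ratio between a
noise-generated pulse on an internal sensor and the same event on the
external microphone (≈ 0.03, i.e. −31 dB, for this enclosure class).
Given the NSPA threshold T, the linear amplitude threshold is
`A_T = 10^{T/20}`. The removal pass:

1. Gate: if `NSPA(K·Vmic) ≤ T`, ambient noise cannot produce a false
   positive and nothing is touched.
2. Find microphone-envelope peaks above `A_T/(2K)` — external events
   loud enough to reach half the detection amplitude on the sensors.
3. For each, zero the 10 ms sensor-envelope window centered on it *if*
   a sensor local maximum above `A_T/2` lies inside (the mic-side
   factor-2 margin mirrored on the sensor side; configurable via
   `piezo_peak_factor`). Windows are half-open `[t−w/2, t+w/2)` and
   merged when they overlap, so no sample or peak is counted twice.
4. NSPA and the impulse count are recomputed on the cleaned envelope.

Zeroing operates on the normalized envelope — the domain NSPA and the
peak counter consume — not the raw waveform. Peaks thinned closer than
10 ms (the removal-window width) count once, higher amplitude winning
and the earlier peak breaking exact ties. Simultaneous insect + noise
events inside one window are removed and counted as removed: the
algorithm zeroes, it does not separate.

K is estimated from a noise-only calibration recording: every mic peak
above a minimum amplitude is paired with the sensor-envelope maximum
within ±5 ms (half the removal window); the per-channel estimate is
the **median** of pair ratios (robust to the odd mismatched pair), the
overall K the **mean across channels**. At least five pairs are
required. The default pairing level is a quarter of the strongest mic
event (floored at 10× the mic noise floor): weak mic fluctuations pair
with the sensor noise floor and would bias K upward. K is defined on
normalized envelopes because the removal test `V > A_T/2K` operates in
that domain.

## Decision

Per piezo channel and per segment (default 60 s, the duration over
which the statistic was characterized): detected iff `NSPA ≥ T` **and**
`N ≥ Nmin` after noise removal, ties counting as detections. A
recording is positive if any channel in any segment is. Segments are
independent; a recording shorter than one segment is processed whole,
and a tail shorter than 10 s is discarded (NSPA on a few seconds is
dominated by a single impulse). Defaults: T = 22 dB — the maximum
noise NSPA at an 80 dBA ambient level in the optimized band, with
31 dB as the 90 dBA operating point — and Nmin = 5, matching the
convention that a credible infestation shows a train of at least five
impulses.

The calibrate-once-decide-many workflow is exposed as the
`InsectDetector` estimator (`fit` on a self-noise reference and
optionally an ambient recording for K; `decide`/`predict` on
recordings; `get_params`/`set_params` for composition with sklearn
tooling), with `detect_recording`/`evaluate_batch` as functional
wrappers.

## Synthetic scenes

The generator produces the statistical structure the detector relies
on, with ground truth attached; all randomness flows through one
seeded generator and a fixed seed reproduces a scene bit-exactly.

* **Insect tracks**: Gaussian-windowed tone bursts (σ = duration/6,
  support ± duration/2), durations 3–30 ms, carriers uniform in
  1.5–6 kHz by default, at uniform times with enforced minimum
  separation (rejection sampling; infeasible packings are refused).
  More than 90% of track energy lies above 1565 Hz.
* **Noise tracks**: a base with power below the 1600 Hz corner — a
  blend of a constant-envelope random-FM hum (600–1400 Hz) and
  low-passed Gaussian noise — plus, for impulsive classes,
  superimposed short (3–10 ms) tone bursts. The FM/Gaussian blend and
  the impulse scale are calibrated by bisection until the crest factor
  of the band-passed (500–6000 Hz) envelope hits the class target:
  continuous ≈ 2 dB, factory 8 dB, speech/chainsaw 13 dB. Unattainable
  targets raise. Noise impulses are kept ≤ 10 ms so one 10 ms removal
  window covers an impulse's support; a longer noise impulse would
  leave shoulders no 10 ms-zeroing algorithm can remove. Class carrier
  ranges: factory 0.5–1.5 kHz, speech 0.5–2.5 kHz, chainsaw
  0.5–5.5 kHz.
* **Scenes**: the external mic carries the noise track; each piezo
  channel carries the insect track (optionally a subset of channels),
  the noise track scaled by `K_true`, and independent white self-noise
  (RMS 10⁻³ sensor units). A no-collision flag keeps insect and noise
  events ≥ 20 ms apart so preservation/removal accounting is
  unambiguous. Nominal dBA labels map to RMS by
  `RMS = 0.5 · 10^{(dBA−100)/20}` — a declared convention anchoring
  100 dBA to RMS 0.5 sensor units, not an SPL calibration.

**What the generator does not emulate:** real impulse waveforms
(stick-slip transients rather than windowed tones), substrate
propagation and reverberation, inter-channel correlation of self-noise,
nonstationary noise spectra, or insect bursts with internal temporal
structure. Passing tests therefore demonstrate the correctness and
self-consistency of the algorithmic chain under its stated assumptions
— spectral separation, impulsive structure, linear coupling — not
field performance on recorded data, which requires the public corpus
(see `scripts/validate_dataset.py`).

### Scene designs used by the acceptance battery

* **Removal fidelity** (50 scenes): 5–10 insect impulses (3–15 ms,
  carriers 1.8–5.5 kHz — short enough that each physical event yields
  exactly one countable envelope peak at the 10 ms thinning distance)
  against 10–70 coupled noise impulses at chainsaw 95 dBA / speech
  90 dBA. Levels are chosen so the *continuous* base stays below the
  mic trigger `A_T/(2K)` while impulses stand far above it; with the
  base itself over the trigger, removal windows open on base
  fluctuations that correspond to no event, and exact per-event
  accounting is no longer defined for any algorithm of this form.
* **K recovery**: noise-only chainsaw scenes at 100 dBA,
  K ∈ {0.01, 0.03, 0.1}, ten seeds each, ±10% relative.
* **Band sweep corpus**: each insect recording concentrates its
  impulses around a recording-specific carrier (centers 1.7–4.2 kHz,
  ±50 Hz) — impulses have a spectral peak, not a flat band occupancy —
  and the noise is factory-class with long (8–20 ms) low-carrier
  (0.4–1.3 kHz) impulses. With a flat carrier occupancy the difference
  curve never turns over: narrowing the band shrinks the normalization
  baseline as fast as the insects lose energy. The sweep argmax falls
  at 1650–1800 Hz across seeds and the curve collapses beyond the
  insect band.
* **Detection battery** (200 scenes, 4 s, two piezo channels): 100
  insect + 100 control, half of each group under 90 dBA speech or
  100 dBA chainsaw noise; scored through the same `evaluate` path the
  CLI uses. Expected outcome: accuracy 1.0, zero false positives.

Problem sizes (4–5 s scenes, 1–4 piezo channels) are scaled for a
desk-class reproduction of corpus-scale results; every quantity the
tests assert is recomputed at run time from generated scenes.

## Known limitations

* The removal step zeroes envelope segments; it does not interpolate
  or spectrally subtract, so heavy zeroing deflates the impulse count
  on genuinely infested recordings under extreme noise.
* Continuous noise whose in-band coupled level approaches `A_T/2`
  defeats per-event removal by construction (no event structure to
  match); the gate then correctly reports that the threshold criterion
  is unreliable, but the package does not raise T automatically.
* Multi-segment session verdicts use any-segment OR; no majority or
  persistence logic.
* WAV I/O covers PCM 16/24/32 and float32 reading and PCM16/PCM32/
  float32 writing; 24-bit writing is rejected.
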