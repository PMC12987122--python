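# aspids

Acoustic detection of stored-product insects in the presence of strong
ambient noise.

Insect larvae and adults moving through grain produce trains of short
(3–30 ms) broadband impulses that piezoelectric contact sensors inside
a sound-insulated sampling container can pick up — but machinery,
speech and vehicle noise at an inspection station penetrates the
enclosure and produces impulses of the same shape. This package
implements the signal-processing chain that tells them apart, for
anyone building or evaluating acoustic pest-monitoring pipelines:
entomologists working with multichannel WAV recordings, and engineers
reproducing the algorithm on synthetic data.

## The algorithm

The detection statistic is the **Normalized Signal Pulse Amplitude**:

    NSPA = 20·log10( RMS(V) ),   over  0.5·Vmax ≤ V ≤ 0.9·Vmax

where `V = S_E / RMS(N_E)` is the Hilbert envelope of the
band-pass-filtered channel (Butterworth, default band **1565–6000 Hz**,
order 4, zero-phase) normalized by the same envelope of a self-noise
reference recorded with no insect present. The analysis region between
50% and 90% of the envelope maximum captures the amplitudes where
insect pulses concentrate.

Ambient noise reaches the internal sensors attenuated by the
**penetration coefficient** `K ≈ 0.03` (−31 dB) relative to an external
reference microphone. When the estimated coupled noise exceeds the
threshold (`NSPA(K·Vmic) > T`), microphone-envelope peaks above
`A_T/(2K)` — with `A_T = 10^(T/20)` — locate the contaminated
stretches, and 10 ms sensor-envelope windows around them are zeroed if
a sensor peak above `A_T/2` lies inside. A channel then reports an
insect iff **NSPA ≥ T and N ≥ Nmin** (impulse count after removal,
default T = 22 dB, Nmin = 5), and a recording is positive if any piezo
channel is, in any one-minute segment.

Because the recorded corpus is an external download, the package ships
a seeded scene generator (`aspids.synth`) reproducing the structure
the detector exploits: sparse 1.5–6 kHz insect impulses, ambient noise
with power below ~1600 Hz and calibrated crest factor (continuous
≈2 dB, factory 8 dB, speech/chainsaw 13 dB), coupling by `K_true`, and
sensor self-noise — with ground-truth event times attached.

## Worked example

```python
import numpy as np
from aspids import (InsectDetector, SceneConfig, NoiseConfig,
                    synth_scene, synth_self_noise)

# calibration inputs: a quiet self-noise reference and an ambient-noise
# recording with no insect present
rng = np.random.default_rng(0)
reference = synth_self_noise(5.0, 44100.0, rng, rms_scale=1e-3, n_channels=5)
noise_rec, _ = synth_scene(SceneConfig(seed=1, insect=None, k_true=0.03,
    noise=NoiseConfig(noise_class="chainsaw", level_dba=100.0)))

det = InsectDetector(t_db=22.0, n_min=5, k="calibrate")
det.fit(reference, noise_rec)
print(f"calibrated K = {det.k_:.4f}")

# a scene with one insect and 90 dBA speech-like noise
scene, truth = synth_scene(SceneConfig(seed=3,
    noise=NoiseConfig(noise_class="speech", level_dba=90.0)))
decision = det.decide(scene)
ch0 = decision.segments[0].channels[0]
print(f"insect present: {decision.overall}")
print(f"channel 0: NSPA = {ch0.nspa:.1f} dB, impulses N = {ch0.n_peaks}, "
      f"noise peaks removed = {ch0.removal_report.piezo_peaks_removed}")
```

Output:

```
calibrated K = 0.0301
insect present: True
channel 0: NSPA = 40.8 dB, impulses N = 8, noise peaks removed = 7
```

The detector recovers the designed coupling (K_true = 0.03), removes
the seven noise-generated impulses that exceeded the amplitude
threshold on the sensor, and the insect's eight impulses at 40.8 dB
clear both criteria.

The same workflow is available from the shell:

```bash
aspids simulate --seed 3 --out scene.wav --truth truth.json
aspids calibrate selfnoise.wav --noise ambient.wav --out cal.json
aspids detect scene.wav --baseline cal.json --t-db 22 --nmin 5
aspids evaluate manifest.json --baseline cal.json --out metrics.json
aspids optimize-band --insect i0.wav ... --noise n0.wav ... \
    --self-noise base.wav --out sweep.csv
```

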