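"""Seeded generator of labeled synthetic acoustic scenes.

Every pipeline stage is testable without recorded data because the
generator reproduces the statistical structure the detector exploits:

* **Insect activity** — sparse trains of short (3-30 ms) band-limited
  impulses (Gaussian-windowed tone bursts, carriers 1.5-6 kHz), so more
  than 90% of their energy sits above the optimized lower band edge.
* **Ambient noise** — a colored base with power concentrated below
  ~1600 Hz plus, for impulsive classes, superimposed insect-like
  impulses.  The base blends a constant-envelope random-FM hum with
  low-passed Gaussian noise; the blend and the impulse scale are
  calibrated by bisection so the crest factor of the band-passed
  envelope hits a per-class target (continuous ~2 dB, factory 8 dB,
  speech/chainsaw 13 dB).
* **Coupling** — each piezo channel receives the noise track scaled by
  the penetration coefficient K (the same construction used to emulate a
  sensor channel from an external clip), plus independent stationary
  self-noise.
* **Levels** — nominal dBA labels map to RMS scale factors relative to a
  declared reference (100 dBA <-> RMS 0.5 sensor units); no physical SPL
  calibration is implied.

All randomness flows through one seeded generator; a fixed seed yields a
bit-identical scene.  Ground-truth event times are attached for
parameter-recovery and removal-accounting tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dsp import BandSpec, bandpass_filter, crest_factor, envelope
from .io import Recording

__all__ = [
    "InsectConfig",
    "NoiseConfig",
    "SceneConfig",
    "SceneTruth",
    "NOISE_CLASSES",
    "dba_to_rms",
    "synth_insect_track",
    "synth_noise_track",
    "synth_self_noise",
    "synth_scene",
]

#: Reference point of the nominal-level convention: 100 dBA <-> RMS 0.5.
DBA_REF_LEVEL = 100.0
DBA_REF_RMS = 0.5

#: Band used when measuring a noise track's crest factor — wide enough to
#: see both the low-frequency base and the impulses.
CREST_BAND = BandSpec(500.0, 6000.0)

#: Per-class noise structure: default crest-factor target (dB) and, for
#: impulsive classes, the carrier range of the superimposed impulses.
NOISE_CLASSES: dict[str, dict] = {
    "continuous": {"impulsive": False, "crest_db": 2.0},
    "factory": {"impulsive": True, "crest_db": 8.0, "carrier": (500.0, 1500.0)},
    "speech": {"impulsive": True, "crest_db": 13.0, "carrier": (500.0, 2500.0)},
    "chainsaw": {"impulsive": True, "crest_db": 13.0, "carrier": (500.0, 5500.0)},
}


def dba_to_rms(dba: float) -> float:
    """Map a nominal dBA label to an RMS amplitude in sensor units."""
    return DBA_REF_RMS * 10.0 ** ((dba - DBA_REF_LEVEL) / 20.0)


@dataclass(frozen=True)
class InsectConfig:
    """Insect-impulse train parameters."""

    n_impulses: int = 8
    duration_range: tuple[float, float] = (0.003, 0.030)
    carrier_range: tuple[float, float] = (1500.0, 6000.0)
    amplitude_range: tuple[float, float] = (0.02, 0.10)
    min_separation: float = 0.05

    def __post_init__(self) -> None:
        if self.n_impulses < 0:
            raise ValueError("impulse count must be >= 0")
        for lo, hi in (self.duration_range, self.carrier_range, self.amplitude_range):
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range ({lo}, {hi})")


@dataclass(frozen=True)
class NoiseConfig:
    """Ambient-noise parameters."""

    noise_class: str = "speech"
    crest_db: float | None = None  # None -> the class default
    level_dba: float = 90.0
    n_impulses: int = 20
    corner_hz: float = 1600.0
    impulse_duration_range: tuple[float, float] = (0.003, 0.010)
    impulse_carrier_range: tuple[float, float] | None = None  # None -> class default
    min_separation: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_class not in NOISE_CLASSES:
            raise ValueError(
                f"unknown noise class {self.noise_class!r}; "
                f"expected one of {sorted(NOISE_CLASSES)}"
            )
        if self.n_impulses < 0:
            raise ValueError("impulse count must be >= 0")

    @property
    def target_crest_db(self) -> float:
        if self.crest_db is not None:
            return self.crest_db
        return NOISE_CLASSES[self.noise_class]["crest_db"]


@dataclass(frozen=True)
class SceneConfig:
    """A full labeled acoustic scene.

    ``insect=None`` gives a control scene; ``noise=None`` a quiet one.
    ``insect_channels`` restricts the insect track to a subset of piezo
    channels (emulating an insect near one sensor group); by default all
    piezo channels carry it.
    """

    duration: float = 5.0
    rate: float = 44100.0
    n_piezo: int = 4
    insect: InsectConfig | None = field(default_factory=InsectConfig)
    noise: NoiseConfig | None = field(default_factory=NoiseConfig)
    insect_channels: tuple[int, ...] | None = None
    k_true: float = 0.03
    self_noise_rms: float = 1e-3
    no_collision: bool = True
    collision_margin: float = 0.02
    seed: int = 0
    species: str | None = None
    material: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        if self.rate <= 2 * CREST_BAND.f2:
            raise ValueError(
                f"rate must exceed {2 * CREST_BAND.f2} Hz for the analysis bands"
            )
        if not (0 <= self.k_true <= 1):
            raise ValueError(f"K_true must be in [0, 1], got {self.k_true}")
        if self.self_noise_rms <= 0:
            raise ValueError(
                "self_noise_rms must be > 0 (a zero floor would make the "
                "normalization baseline degenerate)"
            )
        if self.n_piezo < 1:
            raise ValueError("need at least one piezo channel")


@dataclass
class SceneTruth:
    """Ground truth attached to a generated scene."""

    insect_times: np.ndarray
    noise_times: np.ndarray
    k_true: float
    roles: tuple[str, ...]
    insect_channels: tuple[int, ...]
    components: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "insect_times": self.insect_times.tolist(),
            "noise_times": self.noise_times.tolist(),
            "K_true": self.k_true,
            "labels": list(self.roles),
            "insect_channels": list(self.insect_channels),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# -- event scheduling ----------------------------------------------------

_EDGE_MARGIN = 0.05  # keep events clear of record edges / filter edges


def _draw_times(
    rng: np.random.Generator,
    duration: float,
    n: int,
    min_separation: float,
    existing: Sequence[float] = (),
    existing_margin: float = 0.0,
) -> np.ndarray:
    """Uniform event times with enforced minimum separation (rejection)."""
    if n == 0:
        return np.empty(0)
    usable = duration - 2 * _EDGE_MARGIN
    if usable <= 0 or n * min_separation > 0.8 * usable:
        raise ValueError(
            f"cannot pack {n} events with {min_separation * 1e3:.0f} ms "
            f"separation into {duration} s"
        )
    existing = np.asarray(existing, dtype=float)
    times: list[float] = []
    attempts = 0
    while len(times) < n:
        attempts += 1
        if attempts > 500 * n:
            raise ValueError(
                f"event packing failed: {n} events at {min_separation * 1e3:.0f} ms "
                f"separation do not fit in {duration} s with the existing schedule"
            )
        t = rng.uniform(_EDGE_MARGIN, duration - _EDGE_MARGIN)
        if times and np.min(np.abs(np.asarray(times) - t)) < min_separation:
            continue
        if existing.size and np.min(np.abs(existing - t)) < existing_margin:
            continue
        times.append(t)
    return np.sort(np.asarray(times))


def _add_impulse(
    x: np.ndarray,
    rate: float,
    t0: float,
    dur: float,
    carrier: float,
    amplitude: float,
    phase: float,
) -> None:
    """Add one Gaussian-windowed tone burst in place (support +/- dur/2)."""
    sigma = dur / 6.0
    half = int(round(dur / 2 * rate))
    i0 = int(round(t0 * rate))
    s, e = max(i0 - half, 0), min(i0 + half + 1, x.size)
    t = (np.arange(s, e) / rate) - t0
    x[s:e] += (
        amplitude * np.exp(-(t**2) / (2 * sigma**2)) * np.sin(2 * np.pi * carrier * t + phase)
    )


def synth_insect_track(
    duration: float,
    rate: float,
    cfg: InsectConfig,
    rng: np.random.Generator,
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Insect impulse train: waveform and exact peak times.

    Impulses are Gaussian-windowed tone bursts with carrier frequencies
    drawn in the configured band and durations 3-30 ms — the envelope
    signature of locomotion and feeding impulses.
    """
    n = int(round(duration * rate))
    x = np.zeros(n)
    if times is None:
        times = _draw_times(rng, duration, cfg.n_impulses, cfg.min_separation)
    else:
        times = np.sort(np.asarray(times, dtype=float))
    for t0 in times:
        dur = rng.uniform(*cfg.duration_range)
        carrier = rng.uniform(*cfg.carrier_range)
        amp = rng.uniform(*cfg.amplitude_range)
        _add_impulse(x, rate, t0, dur, carrier, amp, rng.uniform(0, 2 * np.pi))
    return x, times


def _fm_base(duration: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Constant-envelope random-FM hum wandering over 600-1400 Hz."""
    n = int(round(duration * rate))
    # Slow frequency path: smoothed white noise, ~10 Hz wander rate.
    n_ctl = max(int(duration * 20), 4)
    ctl = rng.standard_normal(n_ctl)
    path = np.interp(np.linspace(0, n_ctl - 1, n), np.arange(n_ctl), ctl)
    path = np.tanh(path)  # bound the excursion
    freq = 1000.0 + 400.0 * path
    phase = 2 * np.pi * np.cumsum(freq) / rate + rng.uniform(0, 2 * np.pi)
    return np.cos(phase)


def _gauss_base(
    duration: float, rate: float, corner_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise low-passed (order 6) at the spectral-tilt corner."""
    n = int(round(duration * rate))
    white = rng.standard_normal(n)
    from scipy import signal as sps

    sos = sps.butter(6, corner_hz, btype="lowpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, white)


def _measured_crest(x: np.ndarray, rate: float) -> float:
    # Trim 50 ms at each end: filter and Hilbert edge transients would
    # otherwise dominate the peak of a low-crest signal.
    env = envelope(bandpass_filter(x, rate, CREST_BAND))
    trim = int(0.05 * rate)
    if env.size > 4 * trim:
        env = env[trim:-trim]
    return crest_factor(env)


def _unit_rms(x: np.ndarray) -> np.ndarray:
    return x / np.sqrt(np.mean(x**2))


_CREST_TOL = 0.2
_BISECT_ITERS = 40


def _blend_base(
    duration: float,
    rate: float,
    corner_hz: float,
    target_db: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blend FM hum and Gaussian noise to a target envelope crest factor."""
    fm = _unit_rms(_fm_base(duration, rate, rng))
    ga = _unit_rms(_gauss_base(duration, rate, corner_hz, rng))

    def mix(alpha: float) -> np.ndarray:
        return (1 - alpha) * fm + alpha * ga

    lo_cf = _measured_crest(mix(0.0), rate)
    hi_cf = _measured_crest(mix(1.0), rate)
    if target_db < lo_cf - _CREST_TOL or target_db > hi_cf + _CREST_TOL:
        raise ValueError(
            f"crest-factor target {target_db:.1f} dB unattainable for the "
            f"continuous base (reachable {lo_cf:.1f}-{hi_cf:.1f} dB)"
        )
    lo, hi = 0.0, 1.0
    for _ in range(_BISECT_ITERS):
        mid = (lo + hi) / 2
        cf = _measured_crest(mix(mid), rate)
        if abs(cf - target_db) < _CREST_TOL:
            return mix(mid)
        if cf < target_db:
            lo = mid
        else:
            hi = mid
    return mix((lo + hi) / 2)


def synth_noise_track(
    duration: float,
    rate: float,
    cfg: NoiseConfig,
    rng: np.random.Generator,
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ambient-noise track: waveform (at the configured RMS) and impulse
    truth times (empty for the continuous class).

    The crest factor of the band-passed envelope is calibrated to the
    class target within ~1 dB: the base blend handles continuous classes
    directly, and for impulsive classes the superimposed-impulse scale is
    bisected on top of a low-crest base.
    """
    spec = NOISE_CLASSES[cfg.noise_class]
    target = cfg.target_crest_db
    n = int(round(duration * rate))

    if not spec["impulsive"]:
        base = _blend_base(duration, rate, cfg.corner_hz, target, rng)
        track = base * (dba_to_rms(cfg.level_dba) / np.sqrt(np.mean(base**2)))
        return track, np.empty(0)

    base_target = min(3.0, target - 3.0)
    if base_target < 0.0:
        raise ValueError(
            f"crest-factor target {target:.1f} dB too low for impulsive class "
            f"{cfg.noise_class!r}"
        )
    base = _blend_base(duration, rate, cfg.corner_hz, base_target, rng)

    if times is None:
        times = _draw_times(rng, duration, cfg.n_impulses, cfg.min_separation)
    else:
        times = np.sort(np.asarray(times, dtype=float))
    impulses = np.zeros(n)
    lo_c, hi_c = (
        cfg.impulse_carrier_range
        if cfg.impulse_carrier_range is not None
        else spec["carrier"]
    )
    for t0 in times:
        dur = rng.uniform(*cfg.impulse_duration_range)
        carrier = rng.uniform(lo_c, hi_c)
        rel = rng.uniform(0.6, 1.0)
        _add_impulse(impulses, rate, t0, dur, carrier, rel, rng.uniform(0, 2 * np.pi))

    if times.size == 0:
        track = base
    else:
        def mix(scale: float) -> np.ndarray:
            return base + scale * impulses

        # Bracket the impulse scale, then bisect on the measured crest.
        hi = 1.0
        for _ in range(_BISECT_ITERS):
            if _measured_crest(mix(hi), rate) > target:
                break
            hi *= 2.0
        else:
            raise ValueError(
                f"crest-factor target {target:.1f} dB unattainable with "
                f"{times.size} impulses in {duration} s"
            )
        lo = 0.0
        track = mix(hi)
        for _ in range(_BISECT_ITERS):
            mid = (lo + hi) / 2
            cf = _measured_crest(mix(mid), rate)
            if abs(cf - target) < _CREST_TOL:
                track = mix(mid)
                break
            if cf < target:
                lo = mid
            else:
                hi = mid
            track = mix((lo + hi) / 2)

    track = track * (dba_to_rms(cfg.level_dba) / np.sqrt(np.mean(track**2)))
    return track, times


def synth_self_noise(
    duration: float,
    rate: float,
    rng: np.random.Generator,
    rms_scale: float = 1e-3,
    n_channels: int = 1,
    roles: tuple[str, ...] | None = None,
) -> Recording:
    """Stationary white sensor self-noise, the normalization reference."""
    if rms_scale <= 0:
        raise ValueError("self-noise RMS scale must be positive")
    n = int(round(duration * rate))
    samples = rng.standard_normal((n_channels, n)) * rms_scale
    if roles is None:
        roles = tuple(
            ["piezo"] * (n_channels - 1) + ["external_mic"]
            if n_channels > 1
            else ["piezo"]
        )
    return Recording(samples=samples, rate=rate, roles=roles, label={"control": True})


def band_sweep_corpus(
    seed: int = 0,
    duration: float = 4.0,
    rate: float = 44100.0,
    carrier_centers: Sequence[float] = (1700.0, 1900.0, 2200.0, 2700.0, 3300.0, 4200.0),
    carrier_halfwidth: float = 50.0,
    n_noise: int = 4,
    noise_class: str = "factory",
    level_dba: float = 90.0,
    self_noise_rms: float = 1e-3,
) -> tuple[list[Recording], list[Recording], Recording]:
    """Corpus for the lower-band-edge sweep: insect recordings, noise-only
    recordings, and a self-noise reference.

    Each insect recording concentrates its impulse energy around a
    recording-specific carrier (real impulses have a spectral peak, not a
    flat occupancy of 1.5-6 kHz), so the corpus-mean NSPA genuinely
    decreases once the lower band edge cuts into the insect band — the
    behavior the sweep is meant to expose.  Noise recordings keep their
    power below ~1600 Hz.
    """
    insect_recs = []
    for i, fc in enumerate(carrier_centers):
        cfg = SceneConfig(
            seed=seed * 10007 + i,
            duration=duration,
            rate=rate,
            n_piezo=1,
            insect=InsectConfig(carrier_range=(fc - carrier_halfwidth, fc + carrier_halfwidth)),
            noise=None,
            self_noise_rms=self_noise_rms,
        )
        insect_recs.append(synth_scene(cfg)[0])
    noise_recs = []
    for i in range(n_noise):
        cfg = SceneConfig(
            seed=seed * 10007 + 1000 + i,
            duration=duration,
            rate=rate,
            n_piezo=1,
            insect=None,
            # Factory machinery: long, narrowband, low-carrier impulses —
            # keeps the corpus's noise power firmly below ~1600 Hz.
            noise=NoiseConfig(
                noise_class=noise_class,
                level_dba=level_dba,
                impulse_duration_range=(0.008, 0.020),
                impulse_carrier_range=(400.0, 1300.0),
            ),
            self_noise_rms=self_noise_rms,
        )
        noise_recs.append(synth_scene(cfg)[0])
    baseline_rec = synth_self_noise(
        duration, rate, np.random.default_rng(seed * 10007 + 5000),
        rms_scale=self_noise_rms, n_channels=2,
    )
    return insect_recs, noise_recs, baseline_rec


def synth_scene(cfg: SceneConfig) -> tuple[Recording, SceneTruth]:
    """Assemble a full multichannel scene with ground truth.

    Channel layout: ``n_piezo`` piezo channels followed by one external
    microphone.  The mic carries the noise track; each piezo channel
    carries the insect track (on the configured channels), the noise
    track suppressed by K_true, and independent self-noise.  With
    ``no_collision`` set, insect and noise events are kept at least
    ``collision_margin`` apart so preservation/removal accounting is
    unambiguous.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.rate))

    insect_times = np.empty(0)
    insect_track = np.zeros(n)
    if cfg.insect is not None and cfg.insect.n_impulses > 0:
        insect_times = _draw_times(
            rng, cfg.duration, cfg.insect.n_impulses, cfg.insect.min_separation
        )
        insect_track, _ = synth_insect_track(
            cfg.duration, cfg.rate, cfg.insect, rng, times=insect_times
        )

    noise_times = np.empty(0)
    noise_track = np.zeros(n)
    if cfg.noise is not None:
        spec = NOISE_CLASSES[cfg.noise.noise_class]
        if spec["impulsive"] and cfg.noise.n_impulses > 0:
            margin = cfg.collision_margin if cfg.no_collision else 0.0
            noise_times = _draw_times(
                rng,
                cfg.duration,
                cfg.noise.n_impulses,
                cfg.noise.min_separation,
                existing=insect_times,
                existing_margin=margin,
            )
        noise_track, noise_times = synth_noise_track(
            cfg.duration, cfg.rate, cfg.noise, rng, times=noise_times
        )

    roles = tuple(["piezo"] * cfg.n_piezo + ["external_mic"])
    insect_channels = (
        tuple(range(cfg.n_piezo))
        if cfg.insect_channels is None
        else tuple(cfg.insect_channels)
    )
    if any(c >= cfg.n_piezo for c in insect_channels):
        raise ValueError("insect_channels must index piezo channels")

    self_noise = rng.standard_normal((cfg.n_piezo + 1, n)) * cfg.self_noise_rms
    samples = np.empty((cfg.n_piezo + 1, n))
    for c in range(cfg.n_piezo):
        samples[c] = cfg.k_true * noise_track + self_noise[c]
        if c in insect_channels and cfg.insect is not None:
            samples[c] += insect_track
    samples[cfg.n_piezo] = noise_track + self_noise[cfg.n_piezo]

    label = {
        "species": cfg.species,
        "material": cfg.material,
        "noise_dBA": cfg.noise.level_dba if cfg.noise is not None else None,
        "is_control": cfg.insect is None or cfg.insect.n_impulses == 0,
    }
    rec = Recording(samples=samples, rate=cfg.rate, roles=roles, label=label)
    truth = SceneTruth(
        insect_times=insect_times,
        noise_times=noise_times,
        k_true=cfg.k_true,
        roles=roles,
        insect_channels=insect_channels,
        components={
            "insect": insect_track,
            "noise": noise_track,
            "self_noise": self_noise,
        },
    )
    return rec, truth
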