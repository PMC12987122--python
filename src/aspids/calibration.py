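"""Site calibration: penetration coefficient K and band optimization.

Before inspection begins the system records several minutes of ambient
noise with no insect present.  Two quantities come out of it:

* the self-noise normalization baseline (see :mod:`aspids.dsp`), and
* the penetration coefficient K — the amplitude ratio between
  noise-generated pulses on the internal piezoelectric sensors and the
  same events on the external microphone (~0.03, i.e. -31 dB, for the
  enclosure this models).

The analysis band itself can be optimized by sweeping the lower cutoff
f1 and maximizing the NSPA difference between representative insect
recordings and the ambient noise; with noise power concentrated below
~1600 Hz and insect energy at 1.5-6 kHz the optimum lands near 1565 Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .dsp import (
    BandSpec,
    NormalizedEnvelope,
    SelfNoiseBaseline,
    normalized_envelope,
    nspa,
    self_noise_baseline,
)
from .io import Recording
from .noise_control import detect_peaks

__all__ = [
    "PenetrationCoefficient",
    "BandSweepResult",
    "estimate_penetration_coefficient",
    "optimize_lower_frequency",
    "CalibrationResult",
    "calibrate",
    "save_calibration",
    "load_calibration",
]

#: Mic-peak to sensor-peak matching window, +/- seconds (half the 10 ms
#: removal window of the noise-control stage).
MATCH_WINDOW = 0.005

MIN_CALIBRATION_PAIRS = 5


@dataclass
class PenetrationCoefficient:
    """Estimated ambient-to-sensor coupling ratio."""

    k: float
    per_channel: dict[int, float]
    n_pairs: int

    def __post_init__(self) -> None:
        if not (0 < self.k):
            raise ValueError(f"K must be positive, got {self.k}")


def estimate_penetration_coefficient(
    piezo_envs: Sequence[NormalizedEnvelope],
    mic_env: NormalizedEnvelope,
    min_peak_amplitude: float,
    match_window: float = MATCH_WINDOW,
    min_peak_separation: float = 0.010,
) -> PenetrationCoefficient:
    """Estimate K from a noise-only calibration recording.

    For every external-mic envelope peak above ``min_peak_amplitude``,
    the sensor-envelope maximum within ``+/- match_window`` seconds is
    paired with it; the per-pair ratio sensor/mic estimates K.  The
    per-channel estimate is the median of pair ratios (robust to the odd
    missed or spurious pair); the overall K is the mean across channels.

    Raises an error when fewer than five mic peaks are available — too
    few pairs for a trustworthy ratio.
    """
    if not piezo_envs:
        raise ValueError("at least one sensor envelope is required")
    mic_peaks = detect_peaks(mic_env, min_peak_amplitude, min_peak_separation)
    if len(mic_peaks) < MIN_CALIBRATION_PAIRS:
        raise ValueError(
            f"insufficient calibration data: {len(mic_peaks)} mic peaks above "
            f"{min_peak_amplitude:g} (need >= {MIN_CALIBRATION_PAIRS})"
        )
    per_channel: dict[int, float] = {}
    for env in piezo_envs:
        ratios = []
        for t, mic_amp in zip(mic_peaks.times, mic_peaks.amplitudes):
            s = max(int(np.floor((t - match_window) * env.rate)), 0)
            e = min(int(np.ceil((t + match_window) * env.rate)) + 1, env.n_samples)
            if s >= e:
                continue
            ratios.append(float(np.max(env.values[s:e])) / mic_amp)
        if len(ratios) < MIN_CALIBRATION_PAIRS:
            raise ValueError(
                f"insufficient matched pairs on channel {env.channel}: "
                f"{len(ratios)} (need >= {MIN_CALIBRATION_PAIRS})"
            )
        channel_id = env.channel if env.channel is not None else len(per_channel)
        per_channel[channel_id] = float(np.median(ratios))
    k = float(np.mean(list(per_channel.values())))
    return PenetrationCoefficient(
        k=k, per_channel=per_channel, n_pairs=len(mic_peaks)
    )


@dataclass
class BandSweepResult:
    """NSPA separation between insect and noise corpora versus f1."""

    f1_grid: np.ndarray
    diff_db: np.ndarray
    f1_opt: float

    def to_rows(self) -> list[tuple[float, float]]:
        return list(zip(self.f1_grid.tolist(), self.diff_db.tolist()))


def _corpus_nspa(
    recs: Sequence[Recording], band: BandSpec, baseline: SelfNoiseBaseline
) -> np.ndarray:
    """Per-recording NSPA: the strongest piezo channel drives detection."""
    out = []
    for rec in recs:
        chans = rec.piezo_channels
        if not chans:
            raise ValueError("recording has no piezo channel")
        vals = []
        for c in chans:
            v = normalized_envelope(rec.samples[c], rec.rate, band, baseline, c)
            vals.append(nspa(v).nspa)
        out.append(max(vals))
    return np.asarray(out)


def optimize_lower_frequency(
    insect_recs: Sequence[Recording],
    noise_recs: Sequence[Recording],
    baseline_rec: Recording,
    f1_grid: Sequence[float],
    f2: float = 6000.0,
    order: int = 4,
    refine_step: float | None = None,
) -> BandSweepResult:
    """Sweep the lower band edge f1 to maximize insect/noise separation.

    For each candidate f1 the self-noise baseline and every NSPA are
    recomputed under the band (f1, f2); the objective is the mean insect
    NSPA minus the maximum noise NSPA (the worst-case noise is what sets
    the false-alarm threshold).  With ``refine_step`` set, a second pass
    evaluates a fine grid spanning the coarse neighbors of the coarse
    argmax — a coarse-to-fine search that resolves the optimum to a few
    Hz without evaluating the fine grid everywhere.
    """
    f1_grid = np.asarray(sorted(set(float(f) for f in f1_grid)))
    if f1_grid.size == 0:
        raise ValueError("f1 grid is empty")
    if np.any(f1_grid >= f2) or np.any(f1_grid <= 0):
        raise ValueError(f"every f1 candidate must lie in (0, {f2})")
    if not insect_recs or not noise_recs:
        raise ValueError("insect and noise corpora must both be nonempty")

    def objective(f1: float) -> float:
        band = BandSpec(f1, f2, order)
        baseline = self_noise_baseline(baseline_rec, band)
        insect = _corpus_nspa(insect_recs, band, baseline)
        noise = _corpus_nspa(noise_recs, band, baseline)
        return float(np.mean(insect) - np.max(noise))

    diff = np.asarray([objective(f1) for f1 in f1_grid])

    if refine_step is not None and f1_grid.size > 1:
        i = int(np.argmax(diff))
        lo = f1_grid[max(i - 1, 0)]
        hi = f1_grid[min(i + 1, f1_grid.size - 1)]
        fine = np.arange(lo, hi + refine_step / 2, refine_step)
        fine = fine[~np.isin(fine, f1_grid)]
        if fine.size:
            fine_diff = np.asarray([objective(f1) for f1 in fine])
            f1_grid = np.concatenate([f1_grid, fine])
            diff = np.concatenate([diff, fine_diff])
            order_idx = np.argsort(f1_grid)
            f1_grid, diff = f1_grid[order_idx], diff[order_idx]

    if not np.all(np.isfinite(diff)):
        raise ValueError("NSPA difference is non-finite on part of the grid")
    f1_opt = float(f1_grid[int(np.argmax(diff))])
    return BandSweepResult(f1_grid=f1_grid, diff_db=diff, f1_opt=f1_opt)


@dataclass
class CalibrationResult:
    """Everything the detector needs from a calibration session."""

    baseline: SelfNoiseBaseline
    penetration: PenetrationCoefficient | None = None

    def to_dict(self) -> dict:
        d: dict = {"baseline": self.baseline.to_dict()}
        if self.penetration is not None:
            d["k"] = self.penetration.k
            d["per_channel_k"] = {
                str(c): v for c, v in self.penetration.per_channel.items()
            }
            d["n_pairs"] = self.penetration.n_pairs
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        baseline = SelfNoiseBaseline.from_dict(d["baseline"])
        pen = None
        if "k" in d and d["k"] is not None:
            pen = PenetrationCoefficient(
                k=float(d["k"]),
                per_channel={int(c): float(v) for c, v in d.get("per_channel_k", {}).items()},
                n_pairs=int(d.get("n_pairs", 0)),
            )
        return cls(baseline=baseline, penetration=pen)


def calibrate(
    self_noise_rec: Recording,
    noise_rec: Recording | None,
    band: BandSpec,
    min_peak_amplitude: float | None = None,
) -> CalibrationResult:
    """Run the calibration session: baseline always, K when possible.

    ``self_noise_rec`` is the quiet reference used for normalization;
    ``noise_rec`` (optional) is an ambient-noise recording with no insect,
    from which K is estimated.  ``min_peak_amplitude`` is the mic-envelope
    level defining usable calibration peaks; by default only strong
    external events are paired — peaks above a quarter of the loudest one
    (floored at 10x the mic's own normalized noise level), since weak mic
    fluctuations pair with the sensor noise floor and bias K upward.
    """
    baseline = self_noise_baseline(self_noise_rec, band)
    pen = None
    if noise_rec is not None:
        mic = noise_rec.external_mic_channel
        mic_env = normalized_envelope(
            noise_rec.samples[mic], noise_rec.rate, band, baseline, mic
        )
        if min_peak_amplitude is None:
            min_peak_amplitude = max(10.0, 0.25 * float(np.max(mic_env.values)))
        piezo_envs = [
            normalized_envelope(noise_rec.samples[c], noise_rec.rate, band, baseline, c)
            for c in noise_rec.piezo_channels
        ]
        pen = estimate_penetration_coefficient(
            piezo_envs, mic_env, min_peak_amplitude
        )
    return CalibrationResult(baseline=baseline, penetration=pen)


def save_calibration(result: CalibrationResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def load_calibration(path: str | Path) -> CalibrationResult:
    with open(path) as fh:
        return CalibrationResult.from_dict(json.load(fh))
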