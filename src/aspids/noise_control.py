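"""External-microphone noise removal.

Strong ambient noise penetrates the enclosure attenuated by the
penetration coefficient K (~0.03, i.e. -31 dB), producing insect-like
pulses on the internal piezoelectric sensors.  Because the same event is
seen, much louder, by the external microphone, mic peaks can be used to
locate and zero out the contaminated stretches of the sensor envelopes:

1. Convert the NSPA detection threshold T (dB) to a linear envelope
   amplitude A_T = 10^(T/20).
2. If NSPA(K * Vmic) <= T, ambient noise cannot produce a false positive
   and nothing is removed.
3. Otherwise find mic-envelope peaks above A_T / (2K) — external events
   loud enough to reach half the detection amplitude on the sensors.
4. Around each mic peak, zero a 10 ms window of the sensor envelope if a
   local sensor maximum above A_T / 2 falls inside it.

Zeroing operates on the normalized envelope (the domain NSPA consumes);
NSPA and its analysis region are recomputed on the cleaned envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .dsp import DEFAULT_BAND, BandSpec, NormalizedEnvelope, nspa

__all__ = [
    "DetectionParams",
    "PeakList",
    "NoiseRemovalReport",
    "amplitude_threshold",
    "detect_peaks",
    "remove_noise_windows",
    "apply_noise_control",
]


@dataclass(frozen=True)
class DetectionParams:
    """Operating parameters of the detection and noise-removal stages.

    Parameters
    ----------
    t_db : float
        NSPA detection threshold T in dB.  22 dB corresponds to the
        maximum NSPA produced by 80 dBA ambient noise in the optimized
        band; 31 dB is the 90 dBA operating point.
    n_min : int
        Minimum number of envelope peaks above A_T required for a
        detection (a genuine infestation produces a train of impulses,
        not a lone spike).
    band : BandSpec
        Analysis band for filtering and normalization.
    k : float
        Penetration coefficient: amplitude ratio of external noise as
        seen by the internal sensors versus the external microphone.
    removal_window : float
        Width in seconds of the zeroed window centered on each mic peak.
    min_peak_separation : float
        Minimum spacing between counted peaks; a single physical impulse
        (3-30 ms) should count once.
    piezo_peak_factor : float
        A sensor local maximum above ``piezo_peak_factor * A_T`` inside a
        removal window triggers zeroing; mirrors the factor-2 margin of
        the mic-side level A_T/(2K).
    """

    t_db: float = 22.0
    n_min: int = 5
    band: BandSpec = field(default_factory=lambda: DEFAULT_BAND)
    k: float = 0.03
    removal_window: float = 0.010
    min_peak_separation: float = 0.010
    piezo_peak_factor: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_db):
            raise ValueError("threshold T must be finite")
        if self.n_min < 1:
            raise ValueError(f"Nmin must be >= 1, got {self.n_min}")
        if not (0 < self.k <= 1):
            raise ValueError(f"penetration coefficient K must be in (0, 1], got {self.k}")
        if self.removal_window <= 0 or self.min_peak_separation <= 0:
            raise ValueError("window durations must be positive")
        if not (0 < self.piezo_peak_factor <= 1):
            raise ValueError("piezo_peak_factor must be in (0, 1]")

    @property
    def a_t(self) -> float:
        """Linear amplitude threshold A_T = 10^(T/20)."""
        return amplitude_threshold(self.t_db)

    @property
    def mic_peak_level(self) -> float:
        """Mic-envelope detection level A_T / (2K)."""
        return self.a_t / (2.0 * self.k)

    def to_dict(self) -> dict:
        return {
            "t_db": self.t_db,
            "n_min": self.n_min,
            "band": self.band.to_dict(),
            "k": self.k,
            "removal_window": self.removal_window,
            "min_peak_separation": self.min_peak_separation,
            "piezo_peak_factor": self.piezo_peak_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        d = dict(d)
        if "band" in d:
            d["band"] = BandSpec.from_dict(d["band"])
        return cls(**d)


def amplitude_threshold(t_db: float) -> float:
    """Convert the NSPA threshold T (dB) to a linear envelope amplitude."""
    if not np.isfinite(t_db):
        raise ValueError("threshold T must be finite")
    return float(10.0 ** (t_db / 20.0))


@dataclass
class PeakList:
    """Times (s) and amplitudes of detected envelope peaks, time-ordered."""

    times: np.ndarray
    amplitudes: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if not (self.times.size == self.amplitudes.size == self.indices.size):
            raise ValueError("times, amplitudes and indices must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def empty(cls) -> "PeakList":
        return cls(times=np.empty(0), amplitudes=np.empty(0), indices=np.empty(0, int))

    def to_dict(self) -> list[dict]:
        return [
            {"t": float(t), "amp": float(a)}
            for t, a in zip(self.times, self.amplitudes)
        ]


def detect_peaks(
    v: NormalizedEnvelope,
    level: float,
    min_separation: float = 0.010,
    edge_exclude: float = 0.005,
) -> PeakList:
    """Local envelope maxima strictly above ``level``, greedily thinned.

    Thinning retains the higher peak whenever two candidates fall within
    ``min_separation`` seconds of each other (the earlier one wins an
    exact amplitude tie), so one physical impulse counts once.  The first
    and last ``edge_exclude`` seconds are ignored — the finite filter and
    Hilbert transform produce spurious transients there (the same guard
    the Vmax search applies).
    """
    if level <= 0:
        raise ValueError("peak detection level must be positive")
    values, rate = v.values, v.rate
    idx, _ = sps.find_peaks(values)
    idx = idx[values[idx] > level]
    margin = int(round(edge_exclude * rate))
    if margin and 2 * margin < values.size:
        idx = idx[(idx >= margin) & (idx < values.size - margin)]
    if idx.size == 0:
        return PeakList.empty()
    min_gap = min_separation * rate
    # Greedy by descending amplitude, earlier index breaking ties.
    order = np.lexsort((idx, -values[idx]))
    kept: list[int] = []
    for j in order:
        i = idx[j]
        if all(abs(i - k) >= min_gap for k in kept):
            kept.append(i)
    kept_arr = np.sort(np.asarray(kept, dtype=np.int64))
    return PeakList(
        times=kept_arr / rate, amplitudes=values[kept_arr], indices=kept_arr
    )


@dataclass
class NoiseRemovalReport:
    """Outcome of one noise-removal pass on a sensor envelope."""

    mic_peaks: PeakList
    zeroed_windows: list[tuple[float, float]]
    piezo_peaks_removed: int
    piezo_peaks_preserved: int
    cleaned: NormalizedEnvelope
    nspa_before: float | None = None
    nspa_after: float | None = None
    gate_triggered: bool = True

    def to_dict(self) -> dict:
        return {
            "mic_peaks": self.mic_peaks.to_dict(),
            "windows": [[s, e] for s, e in self.zeroed_windows],
            "removed": self.piezo_peaks_removed,
            "preserved": self.piezo_peaks_preserved,
            "nspa_before": self.nspa_before,
            "nspa_after": self.nspa_after,
            "gate_triggered": self.gate_triggered,
        }


def _merge_intervals(
    intervals: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    if not intervals:
        return []
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def remove_noise_windows(
    v_piezo: NormalizedEnvelope,
    mic_peaks: PeakList,
    window: float = 0.010,
    zero_level: float = 1.0,
    count_level: float | None = None,
    min_peak_separation: float = 0.010,
) -> NoiseRemovalReport:
    """Zero sensor-envelope windows around external-microphone peaks.

    For each mic peak at time t, the half-open interval
    [t - window/2, t + window/2) of the sensor envelope is zeroed if a
    local sensor maximum above ``zero_level`` lies inside it.  Overlapping
    windows are merged.  Sensor peaks above ``count_level`` (default
    ``2 * zero_level``, i.e. A_T) are tallied as removed or preserved
    depending on whether they fall inside a zeroed window; samples outside
    zeroed windows are untouched.
    """
    if window <= 0:
        raise ValueError("removal window must be positive")
    if count_level is None:
        count_level = 2.0 * zero_level
    values, rate = v_piezo.values, v_piezo.rate
    n = values.size
    half = window / 2.0

    pre_peaks = detect_peaks(v_piezo, count_level, min_peak_separation)
    # Candidate sensor maxima that justify zeroing a window.
    cand_idx, _ = sps.find_peaks(values)
    cand_idx = cand_idx[values[cand_idx] > zero_level]

    intervals: list[tuple[int, int]] = []
    for t in mic_peaks.times:
        s = int(np.ceil((t - half) * rate))
        e = s + int(round(window * rate))
        s, e = max(s, 0), min(e, n)
        if s >= e:
            continue
        in_window = cand_idx[(cand_idx >= s) & (cand_idx < e)]
        if in_window.size:
            intervals.append((s, e))
    merged = _merge_intervals(intervals)

    cleaned_values = values.copy()
    removed = 0
    for s, e in merged:
        cleaned_values[s:e] = 0.0
        removed += int(np.sum((pre_peaks.indices >= s) & (pre_peaks.indices < e)))
    preserved = len(pre_peaks) - removed

    cleaned = NormalizedEnvelope(
        values=cleaned_values,
        rate=rate,
        band=v_piezo.band,
        channel=v_piezo.channel,
    )
    return NoiseRemovalReport(
        mic_peaks=mic_peaks,
        zeroed_windows=[(s / rate, e / rate) for s, e in merged],
        piezo_peaks_removed=removed,
        piezo_peaks_preserved=preserved,
        cleaned=cleaned,
    )


def apply_noise_control(
    v_piezo: NormalizedEnvelope,
    v_mic: NormalizedEnvelope,
    params: DetectionParams,
) -> NoiseRemovalReport:
    """Run the full noise-removal decision on one sensor channel.

    The estimated noise contribution on the sensor is K * Vmic.  If its
    NSPA does not exceed the threshold T, ambient noise cannot trigger a
    false positive and the envelope passes through unchanged; otherwise
    mic peaks above A_T/(2K) are located and the corresponding sensor
    windows zeroed.
    """
    a_t = params.a_t
    before = nspa(v_piezo)

    gate = False
    if np.any(v_mic.values > 0):
        estimated = nspa(v_mic.scaled(params.k))
        gate = estimated.nspa > params.t_db

    if not gate:
        pre = detect_peaks(v_piezo, a_t, params.min_peak_separation)
        return NoiseRemovalReport(
            mic_peaks=PeakList.empty(),
            zeroed_windows=[],
            piezo_peaks_removed=0,
            piezo_peaks_preserved=len(pre),
            cleaned=v_piezo,
            nspa_before=before.nspa,
            nspa_after=before.nspa,
            gate_triggered=False,
        )

    mic_peaks = detect_peaks(
        v_mic, params.mic_peak_level, params.min_peak_separation
    )
    report = remove_noise_windows(
        v_piezo,
        mic_peaks,
        window=params.removal_window,
        zero_level=params.piezo_peak_factor * a_t,
        count_level=a_t,
        min_peak_separation=params.min_peak_separation,
    )
    report.nspa_before = before.nspa
    report.nspa_after = (
        nspa(report.cleaned).nspa if np.any(report.cleaned.values > 0) else None
    )
    report.gate_triggered = True
    return report
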