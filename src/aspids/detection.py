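"""Per-channel and per-recording detection decisions, batch metrics.

A piezo channel reports an insect when BOTH criteria hold after noise
removal: NSPA >= T and the count N of envelope peaks above the amplitude
threshold A_T is at least Nmin.  Ties count as detections.  A recording
is positive when any piezo channel is, in any one-minute segment.

The workflow is fit/predict shaped — calibrate once on a quiet reference
(and optionally an ambient-noise recording for K), then decide on any
number of recordings — so the module's main surface is the
:class:`InsectDetector` estimator; the module-level functions are thin
wrappers over it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .calibration import CalibrationResult, calibrate
from .dsp import (
    DEFAULT_BAND,
    BandSpec,
    NormalizedEnvelope,
    SelfNoiseBaseline,
    normalized_envelope,
    nspa,
)
from .io import Manifest, Recording, read_recording
from .noise_control import (
    DetectionParams,
    NoiseRemovalReport,
    apply_noise_control,
    detect_peaks,
)

__all__ = [
    "ChannelDecision",
    "SegmentDecision",
    "RecordingDecision",
    "BatchMetrics",
    "InsectDetector",
    "detect_channel",
    "detect_recording",
    "evaluate_batch",
]

#: Tail segments shorter than this are discarded: NSPA on a few seconds
#: of data is dominated by a single impulse and unstable.
MIN_SEGMENT = 10.0


@dataclass
class ChannelDecision:
    channel: int
    nspa: float
    n_peaks: int
    detected: bool
    removal_report: NoiseRemovalReport | None = None

    def to_dict(self) -> dict:
        d = {
            "channel": self.channel,
            "nspa": None if math.isinf(self.nspa) else self.nspa,
            "n_peaks": self.n_peaks,
            "detected": self.detected,
        }
        if self.removal_report is not None:
            d["removal"] = self.removal_report.to_dict()
        return d


@dataclass
class SegmentDecision:
    start: float
    end: float
    channels: list[ChannelDecision]
    detected: bool

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "detected": self.detected,
            "channels": [c.to_dict() for c in self.channels],
        }


@dataclass
class RecordingDecision:
    segments: list[SegmentDecision]
    overall: bool
    params: DetectionParams

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "params": self.params.to_dict(),
            "segments": [s.to_dict() for s in self.segments],
        }


def detect_channel(
    v_piezo: NormalizedEnvelope,
    v_mic: NormalizedEnvelope | None,
    params: DetectionParams,
    noise_control: bool = True,
) -> ChannelDecision:
    """Decide one channel: noise removal, then the two-criterion test."""
    report = None
    if noise_control and v_mic is not None:
        report = apply_noise_control(v_piezo, v_mic, params)
        cleaned = report.cleaned
    else:
        cleaned = v_piezo
    n_peaks = len(detect_peaks(cleaned, params.a_t, params.min_peak_separation))
    if np.any(cleaned.values > 0):
        nspa_db = nspa(cleaned).nspa
    else:
        nspa_db = -math.inf
    detected = (nspa_db >= params.t_db) and (n_peaks >= params.n_min)
    return ChannelDecision(
        channel=v_piezo.channel if v_piezo.channel is not None else -1,
        nspa=nspa_db,
        n_peaks=n_peaks,
        detected=detected,
        removal_report=report,
    )


def _segment_bounds(
    n_samples: int, rate: float, segment_length: float
) -> list[tuple[int, int]]:
    """Non-overlapping segment sample ranges; a short recording is one
    segment, a tail shorter than MIN_SEGMENT is discarded."""
    seg = int(round(segment_length * rate))
    if n_samples <= seg:
        return [(0, n_samples)]
    bounds = [(s, min(s + seg, n_samples)) for s in range(0, n_samples, seg)]
    min_n = int(MIN_SEGMENT * rate)
    return [(s, e) for s, e in bounds if e - s >= min_n]


def detect_recording(
    rec: Recording,
    baseline: SelfNoiseBaseline,
    params: DetectionParams,
    segment_length: float = 60.0,
    noise_control: bool = True,
) -> RecordingDecision:
    """Run the full decision procedure on one recording.

    The recording is processed in independent ``segment_length`` segments
    (default one minute, the duration over which NSPA was characterized);
    each piezo channel is filtered, enveloped, normalized, noise-cleaned
    and tested, and decisions are OR-combined across channels and
    segments.
    """
    piezo = rec.piezo_channels
    if not piezo:
        raise ValueError("recording has no piezo channel")
    mic: int | None = None
    if noise_control:
        try:
            mic = rec.external_mic_channel
        except ValueError as exc:
            raise ValueError(
                "noise control requires exactly one external_mic channel; "
                "pass noise_control=False to run without it"
            ) from exc

    segments = []
    for s, e in _segment_bounds(rec.n_samples, rec.rate, segment_length):
        v_mic = None
        if mic is not None:
            v_mic = normalized_envelope(
                rec.samples[mic, s:e], rec.rate, params.band, baseline, mic
            )
        decisions = []
        for c in piezo:
            v = normalized_envelope(
                rec.samples[c, s:e], rec.rate, params.band, baseline, c
            )
            decisions.append(detect_channel(v, v_mic, params, noise_control))
        segments.append(
            SegmentDecision(
                start=s / rec.rate,
                end=e / rec.rate,
                channels=decisions,
                detected=any(d.detected for d in decisions),
            )
        )
    return RecordingDecision(
        segments=segments,
        overall=any(seg.detected for seg in segments),
        params=params,
    )


@dataclass
class BatchMetrics:
    """Confusion counts and rates over a labeled manifest."""

    n_true_positive: int
    n_false_positive: int
    n_true_negative: int
    n_false_negative: int
    decisions: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_total(self) -> int:
        return (
            self.n_true_positive
            + self.n_false_positive
            + self.n_true_negative
            + self.n_false_negative
        )

    @property
    def accuracy(self) -> float:
        return (self.n_true_positive + self.n_true_negative) / self.n_total

    @property
    def false_positive_rate(self) -> float:
        n_neg = self.n_false_positive + self.n_true_negative
        return self.n_false_positive / n_neg if n_neg else 0.0

    @property
    def false_negative_rate(self) -> float:
        n_pos = self.n_true_positive + self.n_false_negative
        return self.n_false_negative / n_pos if n_pos else 0.0

    def to_dict(self) -> dict:
        return {
            "n_true_positive": self.n_true_positive,
            "n_false_positive": self.n_false_positive,
            "n_true_negative": self.n_true_negative,
            "n_false_negative": self.n_false_negative,
            "accuracy": self.accuracy,
            "false_positive_rate": self.false_positive_rate,
            "false_negative_rate": self.false_negative_rate,
        }


class InsectDetector(BaseEstimator):
    """Threshold detector for insect activity in multichannel recordings.

    Parameters
    ----------
    band : BandSpec
        Analysis band; default 1565-6000 Hz, the optimized band.
    t_db : float
        NSPA threshold T in dB (default 22, the 80 dBA operating point).
    n_min : int
        Minimum impulse count (default 5; a genuine infestation shows a
        train of impulses).
    k : float or "calibrate"
        Penetration coefficient, or ``"calibrate"`` to estimate it from
        the noise recording passed to :meth:`fit`.
    noise_control : bool
        Whether to run external-microphone noise removal.
    segment_length : float
        Segment duration in seconds (default 60).

    Attributes
    ----------
    baseline_ : SelfNoiseBaseline
        Per-channel normalization denominators, set by :meth:`fit`.
    k_ : float
        The penetration coefficient in effect after :meth:`fit`.
    params_ : DetectionParams
        The assembled operating parameters.
    """

    def __init__(
        self,
        band: BandSpec = DEFAULT_BAND,
        t_db: float = 22.0,
        n_min: int = 5,
        k: float | str = 0.03,
        removal_window: float = 0.010,
        min_peak_separation: float = 0.010,
        noise_control: bool = True,
        segment_length: float = 60.0,
    ):
        self.band = band
        self.t_db = t_db
        self.n_min = n_min
        self.k = k
        self.removal_window = removal_window
        self.min_peak_separation = min_peak_separation
        self.noise_control = noise_control
        self.segment_length = segment_length

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        reference: Recording,
        noise_recording: Recording | None = None,
    ) -> "InsectDetector":
        """Calibrate on a quiet self-noise reference.

        ``noise_recording`` (ambient noise, no insect) is required when
        ``k="calibrate"``; otherwise it is optional and, when given, the
        estimated K is stored in ``calibration_`` for inspection but the
        configured ``k`` is used.
        """
        want_estimate = self.k == "calibrate"
        if want_estimate and noise_recording is None:
            raise ValueError('k="calibrate" requires a noise_recording')
        cal = calibrate(reference, noise_recording, self.band)
        self.calibration_ = cal
        self.baseline_ = cal.baseline
        if want_estimate:
            self.k_ = cal.penetration.k
        else:
            self.k_ = float(self.k)
        self.params_ = DetectionParams(
            t_db=self.t_db,
            n_min=self.n_min,
            band=self.band,
            k=self.k_,
            removal_window=self.removal_window,
            min_peak_separation=self.min_peak_separation,
        )
        return self

    @classmethod
    def from_calibration(cls, cal: CalibrationResult, **kwargs) -> "InsectDetector":
        """Build a fitted detector from a saved calibration file."""
        if cal.penetration is not None and "k" not in kwargs:
            kwargs["k"] = cal.penetration.k
        det = cls(band=cal.baseline.band, **kwargs)
        det.calibration_ = cal
        det.baseline_ = cal.baseline
        det.k_ = float(det.k) if det.k != "calibrate" else cal.penetration.k
        det.params_ = DetectionParams(
            t_db=det.t_db,
            n_min=det.n_min,
            band=det.band,
            k=det.k_,
            removal_window=det.removal_window,
            min_peak_separation=det.min_peak_separation,
        )
        return det

    def _check_fitted(self) -> None:
        if not hasattr(self, "baseline_"):
            raise RuntimeError("detector is not fitted; call fit() first")

    # -- prediction ------------------------------------------------------

    def decide(self, rec: Recording) -> RecordingDecision:
        """Full decision report for one recording."""
        self._check_fitted()
        return detect_recording(
            rec,
            self.baseline_,
            self.params_,
            segment_length=self.segment_length,
            noise_control=self.noise_control,
        )

    def predict(self, recordings) -> np.ndarray:
        """Boolean insect-present verdict for each recording."""
        if isinstance(recordings, Recording):
            recordings = [recordings]
        return np.asarray([self.decide(r).overall for r in recordings], dtype=bool)

    def score(self, recordings, y) -> float:
        """Detection accuracy against boolean labels ``y``."""
        y = np.asarray(y, dtype=bool)
        return float(np.mean(self.predict(recordings) == y))

    # -- batch evaluation ------------------------------------------------

    def evaluate(self, manifest: Manifest, base_dir=None) -> BatchMetrics:
        """Confusion metrics over a labeled manifest of WAV files.

        Control entries are negatives, insect-labeled entries positives;
        an entry that is neither flagged as control nor species-labeled
        is rejected (its ground truth would be ambiguous).
        """
        self._check_fitted()
        if len(manifest) == 0:
            raise ValueError("manifest is empty")
        rows = []
        tp = fp = tn = fn = 0
        for entry in manifest.entries:
            if not entry.is_control and not entry.species:
                raise ValueError(
                    f"entry {entry.path!r} is neither a control nor labeled with a "
                    "species; cannot score it"
                )
            path = entry.path
            if base_dir is not None:
                from pathlib import Path

                path = str(Path(base_dir) / path)
            rec = read_recording(path, role_map=entry.role_map)
            decision = self.decide(rec)
            truth = not entry.is_control
            pred = decision.overall
            if truth and pred:
                tp += 1
            elif truth:
                fn += 1
            elif pred:
                fp += 1
            else:
                tn += 1
            rows.append(
                {
                    "path": entry.path,
                    "species": entry.species,
                    "material": entry.material,
                    "noise_dBA": entry.noise_dBA,
                    "truth": truth,
                    "detected": pred,
                    "max_nspa": max(
                        (c.nspa for s in decision.segments for c in s.channels),
                        default=-math.inf,
                    ),
                }
            )
        return BatchMetrics(
            n_true_positive=tp,
            n_false_positive=fp,
            n_true_negative=tn,
            n_false_negative=fn,
            decisions=pd.DataFrame(rows),
        )


def evaluate_batch(
    manifest: Manifest,
    baseline: SelfNoiseBaseline,
    params: DetectionParams,
    segment_length: float = 60.0,
    noise_control: bool = True,
    base_dir=None,
) -> BatchMetrics:
    """Functional wrapper over :meth:`InsectDetector.evaluate`."""
    det = InsectDetector(
        band=params.band,
        t_db=params.t_db,
        n_min=params.n_min,
        k=params.k,
        removal_window=params.removal_window,
        min_peak_separation=params.min_peak_separation,
        noise_control=noise_control,
        segment_length=segment_length,
    )
    det.baseline_ = baseline
    det.k_ = params.k
    det.params_ = params
    return det.evaluate(manifest, base_dir=base_dir)
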