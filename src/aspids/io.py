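"""Multichannel WAV I/O and dataset manifests.

The detection platform records eight channels: four piezoelectric contact
sensors inside the sampling container (channels 0-3), two internal air
microphones (4-5), one foam-mounted microphone (6) and one external
microphone mounted outside the enclosure (7).  The external microphone is
the noise reference used by the noise-removal stage.  Sensor amplitudes are
uncalibrated and dimensionless; all downstream processing is
normalization-based, so no physical-unit conversion is attempted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.io import wavfile

__all__ = [
    "ROLES",
    "DEFAULT_ROLE_MAP",
    "Recording",
    "Manifest",
    "ManifestEntry",
    "read_recording",
    "write_recording",
    "load_manifest",
    "save_manifest",
]

#: Recognized channel roles.
ROLES = ("piezo", "internal_mic", "foam_mic", "external_mic")

#: Channel layout of the 8-channel acquisition platform.
DEFAULT_ROLE_MAP: dict[int, str] = {
    0: "piezo",
    1: "piezo",
    2: "piezo",
    3: "piezo",
    4: "internal_mic",
    5: "internal_mic",
    6: "foam_mic",
    7: "external_mic",
}


@dataclass
class Recording:
    """A multichannel sampled waveform with per-channel sensor roles.

    Parameters
    ----------
    samples : ndarray of shape (n_channels, n_samples)
        Floating-point amplitudes in dimensionless sensor units (integer
        PCM input is scaled to [-1, 1] on read).
    rate : float
        Sampling rate in Hz.
    roles : sequence of str
        One role per channel, each from :data:`ROLES`.
    label : dict, optional
        Free-form metadata (species, material, nominal noise level dBA...).
    """

    samples: np.ndarray
    rate: float
    roles: tuple[str, ...]
    label: dict | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        self.roles = tuple(self.roles)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) matrix")
        if self.samples.shape[1] == 0:
            raise ValueError("recording has no samples")
        if len(self.roles) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.roles)} roles for {self.samples.shape[0]} channels"
            )
        bad = [r for r in self.roles if r not in ROLES]
        if bad:
            raise ValueError(f"unknown channel roles {bad}; expected one of {ROLES}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.rate

    def channels_with_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]

    @property
    def piezo_channels(self) -> list[int]:
        return self.channels_with_role("piezo")

    @property
    def external_mic_channel(self) -> int:
        """Index of the single external-microphone channel.

        Raises
        ------
        ValueError
            If zero or more than one channel carries the external_mic role.
        """
        ext = self.channels_with_role("external_mic")
        if len(ext) != 1:
            raise ValueError(
                f"expected exactly one external_mic channel, found {len(ext)}"
            )
        return ext[0]


def _normalize_role_map(
    role_map: Mapping[int, str] | Sequence[str] | None, n_channels: int
) -> tuple[str, ...]:
    if role_map is None:
        if n_channels == len(DEFAULT_ROLE_MAP):
            role_map = DEFAULT_ROLE_MAP
        else:
            raise ValueError(
                f"no role_map given and the file has {n_channels} channels; "
                f"the default layout covers {len(DEFAULT_ROLE_MAP)} channels"
            )
    if isinstance(role_map, Mapping):
        missing = sorted(set(range(n_channels)) - set(role_map))
        extra = sorted(set(role_map) - set(range(n_channels)))
        if missing or extra:
            raise ValueError(
                f"role_map must cover channels 0..{n_channels - 1} exactly "
                f"(missing {missing}, extraneous {extra})"
            )
        roles = tuple(role_map[i] for i in range(n_channels))
    else:
        roles = tuple(role_map)
        if len(roles) != n_channels:
            raise ValueError(
                f"role_map lists {len(roles)} roles for {n_channels} channels"
            )
    return roles


def read_recording(
    path: str | Path,
    role_map: Mapping[int, str] | Sequence[str] | None = None,
    label: dict | None = None,
) -> Recording:
    """Read a WAV file into a :class:`Recording`.

    Integer PCM samples (16/24/32-bit) are scaled to [-1, 1]; IEEE-float
    files are taken as-is.  The sampling rate always comes from the file
    header.  ``role_map`` maps channel index to role; when omitted, the
    default 8-channel platform layout is assumed (and the file must have
    8 channels).
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, EOFError) as exc:
        raise ValueError(f"unreadable WAV file {path}: {exc}") from exc
    if data.ndim == 1:
        data = data[:, None]
    if np.issubdtype(data.dtype, np.integer):
        # 24-bit PCM arrives left-justified in int32; full-scale division
        # covers 16/24/32-bit uniformly.
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    samples = samples.T  # (channel, time)
    roles = _normalize_role_map(role_map, samples.shape[0])
    return Recording(samples=samples, rate=float(rate), roles=roles, label=label)


def write_recording(
    rec: Recording, path: str | Path, subtype: str = "float32"
) -> None:
    """Write a :class:`Recording` as a WAV file.

    ``subtype`` is one of ``float32`` (default, lossless to ~1e-7),
    ``pcm16`` or ``pcm32`` (amplitudes clipped to [-1, 1] and quantized,
    max absolute error one LSB).
    """
    path = Path(path)
    data = rec.samples.T
    if subtype == "float32":
        out = data.astype(np.float32)
    elif subtype in ("pcm16", "pcm32"):
        dtype = np.int16 if subtype == "pcm16" else np.int32
        scale = float(np.iinfo(dtype).max) + 1.0
        clipped = np.clip(data, -1.0, 1.0 - 1.0 / scale)
        out = np.round(clipped * scale).astype(dtype)
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")
    try:
        wavfile.write(path, int(round(rec.rate)), np.ascontiguousarray(out))
    except OSError as exc:
        raise OSError(f"cannot write WAV file {path}: {exc}") from exc


@dataclass
class ManifestEntry:
    path: str
    role_map: dict[int, str] | None = None
    species: str | None = None
    material: str | None = None
    noise_dBA: float | None = None
    is_control: bool = False

    def to_dict(self) -> dict:
        d = {
            "path": self.path,
            "species": self.species,
            "material": self.material,
            "noise_dBA": self.noise_dBA,
            "is_control": self.is_control,
        }
        if self.role_map is not None:
            d["role_map"] = {str(k): v for k, v in self.role_map.items()}
        return d


@dataclass
class Manifest:
    """A labeled collection of recording paths, controls separable."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        problems = []
        for i, e in enumerate(self.entries):
            if not e.path:
                problems.append(f"entry {i}: missing path")
            elif e.path in seen:
                problems.append(
                    f"entry {i}: duplicate path {e.path!r} (first at entry {seen[e.path]})"
                )
            else:
                seen[e.path] = i
            if e.is_control and e.species:
                problems.append(
                    f"entry {i}: control recording {e.path!r} carries insect label "
                    f"{e.species!r}"
                )
        if problems:
            raise ValueError("invalid manifest:\n  " + "\n  ".join(problems))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def controls(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.is_control]

    @property
    def insect_entries(self) -> list[ManifestEntry]:
        return [e for e in self.entries if not e.is_control]


def _entry_from_dict(d: Mapping, where: str) -> ManifestEntry:
    if "path" not in d:
        raise ValueError(f"{where}: missing required field 'path'")
    role_map = d.get("role_map")
    if role_map is not None:
        role_map = {int(k): v for k, v in role_map.items()}
    noise = d.get("noise_dBA")
    noise = None if noise in (None, "") else float(noise)
    is_control = d.get("is_control", False)
    if isinstance(is_control, str):
        is_control = is_control.strip().lower() in ("1", "true", "yes")
    return ManifestEntry(
        path=str(d["path"]),
        role_map=role_map,
        species=d.get("species") or None,
        material=d.get("material") or None,
        noise_dBA=noise,
        is_control=bool(is_control),
    )


def load_manifest(path: str | Path) -> Manifest:
    """Load a manifest from JSON (preferred) or CSV.

    JSON: ``{"entries": [{path, role_map?, species?, material?, noise_dBA?,
    is_control?}, ...]}``.  CSV: columns ``path,species,material,noise_dBA,
    is_control``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        rows = raw["entries"] if isinstance(raw, dict) else raw
        entries = [_entry_from_dict(r, f"{path} entry {i}") for i, r in enumerate(rows)]
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            entries = [
                _entry_from_dict(row, f"{path} row {i + 2}")
                for i, row in enumerate(reader)
            ]
    return Manifest(entries=entries)


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest as JSON."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"entries": [e.to_dict() for e in manifest.entries]}, fh, indent=2)
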