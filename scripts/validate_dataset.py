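#!/usr/bin/env python
"""Optional validation against a downloaded recording corpus.

This script is NOT part of the synthetic acceptance battery: it runs
only when pointed at a directory of real multichannel recordings (for
example the public stored-product-insect corpus), with a manifest
labeling insect and control files, and reports the NSPA distribution in
the optimized band plus detection accuracy at the chosen threshold.

    python scripts/validate_dataset.py --data-dir /path/to/corpus \
        --manifest manifest.json --self-noise selfnoise.wav [--t-db 22]

The manifest format is the package's own (see aspids.io.load_manifest).
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from aspids.detection import evaluate_batch
from aspids.dsp import BandSpec, normalized_envelope, nspa, self_noise_baseline
from aspids.io import load_manifest, read_recording
from aspids.noise_control import DetectionParams


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--manifest", type=Path, required=True)
    parser.add_argument("--self-noise", type=Path, required=True,
                        help="A no-insect reference WAV for the baseline.")
    parser.add_argument("--t-db", type=float, default=22.0)
    parser.add_argument("--nmin", type=int, default=5)
    parser.add_argument("--k", type=float, default=0.03)
    parser.add_argument("--f1", type=float, default=1565.0)
    parser.add_argument("--f2", type=float, default=6000.0)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    band = BandSpec(args.f1, args.f2)
    ref = read_recording(args.self_noise)
    baseline = self_noise_baseline(ref, band)
    manifest = load_manifest(args.manifest)

    nspa_values = []
    for entry in manifest.entries:
        rec = read_recording(args.data_dir / entry.path, role_map=entry.role_map)
        for c in rec.piezo_channels:
            v = normalized_envelope(rec.samples[c], rec.rate, band, baseline, c)
            nspa_values.append(nspa(v).nspa)
    nspa_values = np.asarray(nspa_values)

    params = DetectionParams(t_db=args.t_db, n_min=args.nmin, band=band, k=args.k)
    metrics = evaluate_batch(manifest, baseline, params, base_dir=args.data_dir)

    report = {
        "nspa_min_db": float(nspa_values.min()),
        "nspa_max_db": float(nspa_values.max()),
        "nspa_median_db": float(np.median(nspa_values)),
        "n_channels_scored": int(nspa_values.size),
        **metrics.to_dict(),
    }
    text = json.dumps(report, indent=2)
    if args.out:
        args.out.write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
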