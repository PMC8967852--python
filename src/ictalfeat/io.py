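"""Dataset persistence: per-recording arrays + a JSON sidecar manifest.

Recordings are stored as one ``.npy`` array per recording next to a
``manifest.json`` describing subject, channels, sample rate and onset.
EDF input is supported through mne when available (reading only; no EDF
writer is bundled).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import DataError
from .synthetic import Recording

MANIFEST_NAME = "manifest.json"


def save_dataset(recordings: list[Recording], outdir) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, rec in enumerate(recordings):
        fname = f"rec_{i:04d}.npy"
        np.save(out / fname, rec.samples)
        manifest.append({
            "file": fname,
            "subject_id": rec.subject_id,
            "channel_ids": list(rec.channel_ids),
            "sample_rate": rec.sample_rate,
            "onset_sample": int(rec.onset_sample),
            "montage_tag": rec.montage_tag,
        })
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    return out


def load_dataset(indir) -> list[Recording]:
    src = Path(indir)
    manifest = json.loads((src / MANIFEST_NAME).read_text())
    recordings = []
    for entry in manifest:
        recordings.append(Recording(
            samples=np.load(src / entry["file"]),
            sample_rate=entry["sample_rate"],
            onset_sample=entry["onset_sample"],
            subject_id=entry["subject_id"],
            channel_ids=entry["channel_ids"],
            montage_tag=entry.get("montage_tag", "common-reference"),
        ))
    return recordings


def read_edf(path, onset_time: float, subject_id: str,
             montage_tag: str = "common-reference") -> Recording:
    """Read an EDF file into a Recording (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise DataError("reading EDF requires the mne package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    return Recording(
        samples=raw.get_data(),
        sample_rate=fs,
        onset_sample=int(round(onset_time * fs)),
        subject_id=subject_id,
        channel_ids=list(raw.ch_names),
        montage_tag=montage_tag,
    )
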