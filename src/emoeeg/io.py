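"""Recording and table I/O: EDF signals, JSON annotation sidecars, CSV
feature matrices.

Recordings are written as standard 16-bit EDF (one file per subject) so
any EEG toolbox can open them; trial annotations travel in a JSON sidecar
next to the EDF (``<name>.json``) because EDF proper has no structured
annotation channel.  Reading goes through mne's EDF reader, which also
serves as an independent check on the writer in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import ChannelLayout, standard_layout
from .recording import RawRecording, TrialAnnotation
from .simulate import GroundTruth


class FormatError(ValueError):
    pass


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(recording: RawRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with 1-second data records.

    The sampling rate must be an integer (one data record per second); the
    final record is zero-padded, and the true sample count is stored in the
    JSON sidecar written by :func:`write_recording`.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError(f"EDF writer needs an integer sampling rate, got {fs}")
    spr = int(round(fs))
    n_ch, n_samp = recording.data.shape
    n_records = int(np.ceil(n_samp / spr))

    # per-channel symmetric physical range, integer microvolts
    bounds = np.ceil(np.abs(recording.data).max(axis=1)) + 1.0
    dig_min, dig_max = -32768, 32767

    with path.open("wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(f"subject {recording.subject_id}", 80))
        fh.write(_pad("synthetic emotional EEG", 80))
        fh.write(_pad("01.01.20", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (n_ch + 1)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for name in recording.layout.names:
            fh.write(_pad(name, 16))
        for _ in range(n_ch):
            fh.write(_pad("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for b in bounds:
            fh.write(_pad(str(int(-b)), 8))
        for b in bounds:
            fh.write(_pad(str(int(b)), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dig_min), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dig_max), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))

        scale = (dig_max - dig_min) / (2.0 * bounds)  # digital units per uV
        padded = np.zeros((n_ch, n_records * spr))
        padded[:, :n_samp] = recording.data
        for r in range(n_records):
            seg = padded[:, r * spr : (r + 1) * spr]
            dig = np.rint(seg * scale[:, None]).astype("<i2")
            fh.write(dig.tobytes())
    return path


def _sidecar_path(edf_path: Path) -> Path:
    return edf_path.with_suffix(".json")


def write_recording(recording: RawRecording, path: str | Path) -> Path:
    """Write EDF plus a JSON sidecar with annotations and exact length."""
    path = Path(path)
    write_edf(recording, path)
    sidecar = {
        "subject_id": recording.subject_id,
        "fs": recording.fs,
        "n_samples": recording.n_samples,
        "channels": list(recording.layout.names),
        "trials": [asdict(a) for a in recording.annotations],
        "meta": {k: v for k, v in recording.meta.items() if _jsonable(v)},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _layout_for(channels: list[str]) -> ChannelLayout:
    full = standard_layout()
    try:
        return full.subset(channels)
    except KeyError as exc:
        raise FormatError(f"unknown channel in file: {exc}") from exc


def read_recording(path: str | Path) -> RawRecording:
    """Read an EDF + JSON sidecar pair back into a RawRecording.

    Signal values round-trip within the 16-bit quantization step;
    annotations round-trip exactly.
    """
    import mne  # deferred: slow import, only needed for file ingestion

    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"annotation sidecar {sidecar_file} is missing")
    sidecar = json.loads(sidecar_file.read_text())

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    if list(raw.ch_names) != list(sidecar["channels"]):
        raise FormatError(
            f"channel mismatch between EDF ({len(raw.ch_names)}) and "
            f"sidecar ({len(sidecar['channels'])})"
        )
    data = data[:, : int(sidecar["n_samples"])]
    annotations = [TrialAnnotation(**t) for t in sidecar["trials"]]
    return RawRecording(
        data=data,
        fs=float(sidecar["fs"]),
        layout=_layout_for(sidecar["channels"]),
        annotations=annotations,
        subject_id=sidecar["subject_id"],
        meta=sidecar.get("meta", {}),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(truth), indent=1))
    return path


def write_features(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
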