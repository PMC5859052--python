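"""Reading and writing standard EEG interchange formats.

Reading goes through MNE (EDF and BrainVision).  Writing uses compact
writers implemented here: 16-bit EDF and the BrainVision triplet
(.vhdr/.vmrk/.eeg) in its 32-bit IEEE-float multiplexed dialect.  Reference
and state metadata — which neither format carries natively — travel in a
small JSON sidecar next to the data file and are restored on read; without a
sidecar the reference defaults to the Cz common electrode.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .recording import EEGRecording, common_reference


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(path: Path, rec: EEGRecording) -> None:
    meta = {"reference": rec.reference, "state": rec.state}
    _sidecar_path(path).write_text(json.dumps(meta))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return {"reference": common_reference("Cz"), "state": "unknown"}


# -- EDF (16-bit) ------------------------------------------------------------


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} (max {width})")
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: EEGRecording) -> None:
    """Write a 16-bit EDF file with 1-second data records.

    The sampling rate must be a positive integer; a trailing partial second
    is zero-padded (EDF records are fixed-length).
    """
    path = Path(path)
    if abs(rec.sfreq - round(rec.sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    sfreq = int(round(rec.sfreq))
    nchan = rec.n_channels
    n_records = math.ceil(rec.n_samples / sfreq)
    data = rec.data
    pad = n_records * sfreq - rec.n_samples
    if pad:
        data = np.hstack([data, np.zeros((nchan, pad))])

    # physical scaling: symmetric range per channel onto +/-32767
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-9)
    scale = 32767.0 / phys_max
    digital = np.round(data * scale[:, None]).astype("<i2")

    hdr = bytearray()
    hdr += _edf_field("0", 8)  # version
    hdr += _edf_field("restcompare synthetic subject", 80)
    hdr += _edf_field("restcompare recording", 80)
    hdr += _edf_field("01.01.00", 8)
    hdr += _edf_field("00.00.00", 8)
    hdr += _edf_field(256 + 256 * nchan, 8)
    hdr += _edf_field("", 44)
    hdr += _edf_field(n_records, 8)
    hdr += _edf_field(1, 8)  # record duration, s
    hdr += _edf_field(nchan, 4)
    for label in rec.labels:
        hdr += _edf_field(label, 16)
    hdr += b"".join(_edf_field("", 80) for _ in range(nchan))  # transducer
    hdr += b"".join(_edf_field("uV", 8) for _ in range(nchan))
    for pm in phys_max:
        hdr += _edf_field(f"{-pm:.6g}"[:8], 8)
    for pm in phys_max:
        hdr += _edf_field(f"{pm:.6g}"[:8], 8)
    hdr += b"".join(_edf_field(-32767, 8) for _ in range(nchan))
    hdr += b"".join(_edf_field(32767, 8) for _ in range(nchan))
    hdr += b"".join(_edf_field("", 80) for _ in range(nchan))  # prefilter
    hdr += b"".join(_edf_field(sfreq, 8) for _ in range(nchan))
    hdr += b"".join(_edf_field("", 32) for _ in range(nchan))

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        for r in range(n_records):
            block = digital[:, r * sfreq : (r + 1) * sfreq]
            fh.write(block.tobytes())  # channel-blocked within each record
    _write_sidecar(path, rec)


# -- BrainVision (.vhdr / .vmrk / .eeg, float32 multiplexed) -----------------


def write_brainvision(path, rec: EEGRecording) -> None:
    """Write a BrainVision triplet; ``path`` is the .vhdr file."""
    vhdr = Path(path)
    if vhdr.suffix != ".vhdr":
        raise ValueError("BrainVision path must end in .vhdr")
    stem = vhdr.with_suffix("")
    eeg, vmrk = stem.with_suffix(".eeg"), stem.with_suffix(".vmrk")

    interval_us = 1e6 / rec.sfreq
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:.6f}".rstrip("0").rstrip("."),
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(rec.labels, 1):
        lines.append(f"Ch{i}={label},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    vmrk.write_text(
        "BrainVision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg.name}\n\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,00000000000000000000\n",
        encoding="utf-8",
    )
    rec.data.T.astype("<f4").tofile(eeg)  # multiplexed: sample-major
    _write_sidecar(vhdr, rec)


# -- readers -----------------------------------------------------------------


def read_recording(path, format: str | None = None) -> EEGRecording:
    """Read an EDF or BrainVision recording into an :class:`EEGRecording`.

    ``format`` is inferred from the extension (.edf / .vhdr) when omitted.
    Data are returned in microvolts; reference and state come from the JSON
    sidecar when present, else the Cz common-electrode default.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording: {path}")
    if format is None:
        format = {".edf": "edf", ".vhdr": "brainvision"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from {path.suffix!r}")
    if format == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif format == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'edf' or 'brainvision'")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    meta = _read_sidecar(path)
    return EEGRecording(
        data=data_uv,
        sfreq=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        reference=meta.get("reference", common_reference("Cz")),
        state=meta.get("state", "unknown"),
    )


def write_recording(path, rec: EEGRecording, format: str | None = None) -> None:
    """Write EDF or BrainVision, inferring the format from the extension."""
    path = Path(path)
    if format is None:
        format = {".edf": "edf", ".vhdr": "brainvision"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from {path.suffix!r}")
    if format == "edf":
        write_edf(path, rec)
    elif format == "brainvision":
        write_brainvision(path, rec)
    else:
        raise ValueError(f"unknown format {format!r}")
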