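"""EDF (European Data Format) and CSV-matrix I/O for EEG recordings.

A self-contained EDF implementation covering the subset this package
needs: uniform sampling across signals, 1-second data records, physical
units in microvolts, 16-bit samples. The EDF header is plain ASCII
(256 bytes global + 256 per signal) followed by little-endian int16
sample records, so a minimal reader/writer is small and dependency-free.
Round-trip error is bounded by one quantization step of the 16-bit
physical scaling.

A plain-text fallback (`write_eeg_csv` / `read_eeg_csv`) stores the
channels x samples matrix with a header line carrying the sampling rate
and labels, for dependency-free text fixtures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import SESSION_TAGS, TEN_TWENTY_19, EegRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ASCII bytes")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    """Shortest fixed-point representation fitting the 8-char header field."""
    for dec in range(6, -1, -1):
        s = f"{x:.{dec}f}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {x} in {width} chars")


def write_eeg_edf(recording: EegRecording, path: str | Path) -> None:
    """Write a recording as EDF with 1-s data records.

    The sample count must be a whole number of seconds; physical scaling is
    symmetric around zero per channel. The session tag travels in the
    recording-identification header field.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = recording.data.shape
    if n_samp % fs != 0:
        raise ValueError("EDF export requires a whole number of 1-s records")
    n_records = n_samp // fs

    phys_max = np.maximum(np.abs(recording.data).max(axis=1), 1.0)
    phys_max = np.ceil(phys_max * 100) / 100  # keep the header field short
    phys_min = -phys_max
    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((recording.data - phys_min[:, None]) / scale[:, None]
                       + _DIG_MIN).astype("<i2")

    header = b"".join([
        _ascii("0", 8),
        _ascii(recording.participant_id, 80),
        _ascii(f"session {recording.session_tag}", 80),
        _ascii("01.01.00", 8),           # fixed nominal start date/time:
        _ascii("00.00.00", 8),           # synthetic data carries no clock
        _ascii(256 * (1 + n_ch), 8),
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii(1, 8),                    # record duration, seconds
        _ascii(n_ch, 4),
    ])
    per_signal = b"".join([
        b"".join(_ascii(lab, 16) for lab in recording.channel_labels),
        b"".join(_ascii("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_ascii("uV", 8) for _ in range(n_ch)),
        b"".join(_ascii(_fmt_float(phys_min[i]), 8) for i in range(n_ch)),
        b"".join(_ascii(_fmt_float(phys_max[i]), 8) for i in range(n_ch)),
        b"".join(_ascii(_DIG_MIN, 8) for _ in range(n_ch)),
        b"".join(_ascii(_DIG_MAX, 8) for _ in range(n_ch)),
        b"".join(_ascii("", 80) for _ in range(n_ch)),
        b"".join(_ascii(fs, 8) for _ in range(n_ch)),
        b"".join(_ascii("", 32) for _ in range(n_ch)),
    ])
    records = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
    Path(path).write_bytes(header + per_signal + records.tobytes())


def _norm_label(raw: str) -> str:
    """Normalize an EDF signal label to a bare 10-20 electrode name."""
    s = raw.strip()
    if s.upper().startswith("EEG"):
        s = s[3:].strip()
    s = s.split("-")[0].strip()
    canonical = {name.lower(): name for name in TEN_TWENTY_19}
    return canonical.get(s.lower(), s)


def read_eeg_edf(path: str | Path, participant_id: str | None = None,
                 session_tag: str | None = None) -> EegRecording:
    """Read an EDF file into an :class:`EegRecording` (voltages in uV).

    Signal labels are normalized to bare 10-20 names; the session tag is
    recovered from the recording-identification field when present, else
    must be supplied. Requires uniform sampling across signals.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: not an EDF file (truncated header)")
    try:
        head = raw[:256].decode("ascii")
    except UnicodeDecodeError as exc:
        raise ValueError(f"{path}: non-ASCII EDF header") from exc
    pid = head[8:88].strip()
    rec_id = head[88:168].strip()
    n_records = int(head[236:244])
    record_dur = float(head[244:252])
    n_ch = int(head[252:256])

    off = 256
    def field_block(width: int) -> list[str]:
        nonlocal off
        vals = [raw[off + i * width: off + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)]
        off += width * n_ch
        return vals

    labels = field_block(16)
    field_block(80)                      # transducer
    dims = field_block(8)
    phys_min = np.array([float(v) for v in field_block(8)])
    phys_max = np.array([float(v) for v in field_block(8)])
    dig_min = np.array([float(v) for v in field_block(8)])
    dig_max = np.array([float(v) for v in field_block(8)])
    field_block(80)                      # prefilter
    spr = [int(v) for v in field_block(8)]
    off += 32 * n_ch                     # reserved

    if len(set(spr)) != 1:
        raise ValueError(f"{path}: non-uniform sampling across signals: {spr}")
    if np.any(phys_max <= phys_min) or np.any(dig_max <= dig_min):
        raise ValueError(
            f"{path}: ambiguous physical scaling\n"
            f"  labels={labels}\n  phys=[{phys_min}, {phys_max}]\n"
            f"  dig=[{dig_min}, {dig_max}]"
        )
    fs = spr[0] / record_dur

    expected = n_records * n_ch * spr[0] * 2
    payload = raw[off: off + expected]
    if len(payload) < expected:
        raise ValueError(f"{path}: truncated data section")
    digital = np.frombuffer(payload, dtype="<i2").reshape(n_records, n_ch, spr[0])
    digital = digital.transpose(1, 0, 2).reshape(n_ch, -1).astype(float)

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    for i, dim in enumerate(dims):
        d = dim.lower()
        if d in ("uv", "µv", ""):
            continue
        if d == "mv":
            data[i] *= 1e3
        elif d == "v":
            data[i] *= 1e6
        else:
            raise ValueError(f"{path}: unsupported physical dimension {dim!r}")

    if session_tag is None:
        for tag in SESSION_TAGS:
            if tag in rec_id:
                session_tag = tag
                break
        else:
            session_tag = "rest_eyes_closed"
    return EegRecording(
        participant_id=participant_id or pid or Path(path).stem,
        session_tag=session_tag, fs=fs,
        channel_labels=tuple(_norm_label(lab) for lab in labels),
        data=data,
    )


def write_eeg_csv(recording: EegRecording, path: str | Path) -> None:
    """Plain-text fallback: header line ``# fs=<Hz> session=<tag> id=<pid>``,
    then one ``label,v1,v2,...`` row per channel (full float precision)."""
    with open(path, "w") as fh:
        fh.write(f"# fs={recording.fs} session={recording.session_tag} "
                 f"id={recording.participant_id}\n")
        for lab, row in zip(recording.channel_labels, recording.data):
            fh.write(lab + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_eeg_csv(path: str | Path) -> EegRecording:
    """Read the :func:`write_eeg_csv` format."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing CSV matrix header line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        labels, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(",")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return EegRecording(
        participant_id=meta.get("id", Path(path).stem),
        session_tag=meta.get("session", "rest_eyes_closed"),
        fs=float(meta["fs"]),
        channel_labels=tuple(labels),
        data=np.asarray(rows),
    )
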