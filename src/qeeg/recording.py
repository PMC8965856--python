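"""Core containers for multichannel scalp EEG segments.

Voltages are stored in microvolts as a ``channels x samples`` array together
with 10-20 electrode labels and the sampling rate. Analysis in this package
is restricted to the midline electrodes Fz, Cz and Pz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Recording-session tags. Only ``rest_eyes_closed`` (session 1) and
#: ``cpt_task`` (session 3) are consumed by the analysis pipeline; the other
#: tags are accepted on input and ignored.
SESSION_TAGS = (
    "rest_eyes_closed",
    "rest_eyes_open",
    "cpt_task",
    "noise_rest_closed",
    "noise_rest_open",
    "noise_cpt",
)

#: Midline electrodes of interest.
MIDLINE_ELECTRODES = ("Fz", "Cz", "Pz")

#: The 19 scalp positions of the International 10-20 system used here.
TEN_TWENTY_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)


@dataclass
class EegRecording:
    """A multichannel EEG voltage series.

    Parameters
    ----------
    participant_id : str
        Identifier of the participant the recording belongs to.
    session_tag : str
        One of :data:`SESSION_TAGS`.
    fs : float
        Sampling rate in Hz (200 Hz for the supported acquisition protocol).
    channel_labels : tuple of str
        Unique 10-20 electrode names, one per data row.
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    t0 : float
        Offset of the first sample from the start of the session, in seconds.
    """

    participant_id: str
    session_tag: str
    fs: float
    channel_labels: tuple[str, ...]
    data: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.session_tag not in SESSION_TAGS:
            raise ValueError(f"unknown session tag {self.session_tag!r}")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"electrode {label!r} not present in recording "
                f"(has {', '.join(self.channel_labels)})"
            ) from None

    def pick(self, labels) -> "EegRecording":
        """Return a copy restricted to ``labels`` (order preserved)."""
        idx = [self.channel_index(lab) for lab in labels]
        return replace(self, channel_labels=tuple(labels), data=self.data[idx])

    def slice_seconds(self, start: float, duration: float) -> "EegRecording":
        """Return the contiguous segment ``[start, start + duration)``."""
        i0 = int(round(start * self.fs))
        n = int(round(duration * self.fs))
        if i0 < 0 or i0 + n > self.n_samples:
            raise ValueError("requested segment lies outside the recording")
        return replace(self, data=self.data[:, i0 : i0 + n], t0=self.t0 + start)


@dataclass
class CleanEpoch:
    """A contiguous artifact-screened analysis segment of fixed duration."""

    recording: EegRecording
    duration: float = 60.0
    artifact_fraction: float = 0.0

    def __post_init__(self) -> None:
        expected = int(round(self.duration * self.recording.fs))
        if self.recording.n_samples != expected:
            raise ValueError(
                f"epoch has {self.recording.n_samples} samples, expected {expected} "
                f"for {self.duration} s at {self.recording.fs} Hz"
            )

    @property
    def fs(self) -> float:
        return self.recording.fs

    @property
    def data(self) -> np.ndarray:
        return self.recording.data

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return self.recording.channel_labels
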