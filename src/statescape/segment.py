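"""Multichannel recording segments and plain-text IO.

A :class:`RecordingSegment` holds a channels x samples voltage matrix ``M``
together with its sampling rate and provenance labels (subject, condition).
Segments are written as delimited text: a single ``#``-prefixed JSON header
line carrying the metadata, followed by one comma-separated row per channel.
EDF files can be read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RecordingSegment", "read_segment", "write_segment", "read_edf"]


@dataclass
class RecordingSegment:
    """A channels x samples matrix with a sampling rate and labels.

    Parameters
    ----------
    data
        ``(C, T)`` array of voltage-like values; must be finite.
    fs
        Sampling rate in Hz, shared by all channels.
    channel_ids
        Per-channel labels; defaults to ``ch00 .. chNN``.
    subject, condition
        Free-form provenance labels carried through the pipeline.
    history
        Log of processing steps applied to this segment.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str] | None = None
    subject: str = "unknown"
    condition: str = "unknown"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        c, t = self.data.shape
        if c < 1 or t < 2:
            raise ValueError(f"need C >= 1 channels and T >= 2 samples, got shape {(c, t)}")
        if not np.all(np.isfinite(self.data)):
            bad = int(np.count_nonzero(~np.isfinite(self.data)))
            raise ValueError(f"segment contains {bad} non-finite entries")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.fs = float(self.fs)
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:02d}" for i in range(c)]
        if len(self.channel_ids) != c:
            raise ValueError("channel_ids length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, step: str) -> "RecordingSegment":
        """Copy of this segment with new data and an appended history entry."""
        return replace(self, data=np.asarray(data, dtype=float), history=self.history + [step])


def write_segment(seg: RecordingSegment, path: str | Path) -> None:
    """Write a segment as delimited text with a JSON metadata header."""
    path = Path(path)
    meta = {
        "fs": seg.fs,
        "subject": seg.subject,
        "condition": seg.condition,
        "channel_ids": seg.channel_ids,
    }
    with path.open("w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        np.savetxt(fh, seg.data, delimiter=",", fmt="%.10g")


def read_segment(path: str | Path, fs: float | None = None) -> RecordingSegment:
    """Read a delimited-text segment.

    Files written by :func:`write_segment` carry their metadata in the
    header; bare numeric matrices are accepted if ``fs`` is given.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    meta: dict = {}
    if first.startswith("#"):
        meta = json.loads(first.lstrip("# "))
    data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    if "fs" not in meta and fs is None:
        raise ValueError(f"{path} has no metadata header; pass fs explicitly")
    return RecordingSegment(
        data=data,
        fs=float(meta.get("fs", fs if fs is not None else 0.0)),
        channel_ids=meta.get("channel_ids"),
        subject=meta.get("subject", "unknown"),
        condition=meta.get("condition", "unknown"),
    )


def read_edf(path: str | Path, subject: str = "unknown", condition: str = "unknown") -> RecordingSegment:
    """Read an EDF recording into a segment (requires the ``edf`` extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF support requires mne; install statescape[edf]") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return RecordingSegment(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_ids=list(raw.ch_names),
        subject=subject,
        condition=condition,
    )
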