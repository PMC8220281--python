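"""Signal conditioning for recording segments.

The conditioning chain is: zero-phase FIR band limiting (high-pass,
low-pass), mains notch filters at the base frequency and its harmonics,
edge trimming to discard filter transients, and a single global z-score
over the whole channels x samples matrix. Filtering precedes trimming
precedes z-scoring.

All FIR filters are windowed-sinc (Hamming) designs applied forwards and
backwards (``filtfilt``), so the net phase response is zero. A true FIR
high-pass at cutoffs like 0.1 Hz would need more taps than a 10 s segment
supports; when the requested high-pass cannot be realised within the
segment length the chain falls back to mean (DC) removal and records which
path ran in the segment history.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .segment import RecordingSegment

__all__ = ["apply_filters", "trim_edges", "zscore_global", "preprocess_segment"]

#: transition bandwidth rule: max(0.25 * band edge, 2 Hz)
_MIN_TRANSITION_HZ = 2.0
#: half-width of each mains notch, Hz
_NOTCH_HALF_WIDTH_HZ = 2.0
#: notch transition bandwidth, Hz; wider than the band-limit rule so the
#: filter stays short and its edge transients stay inside the trim window
_NOTCH_TRANSITION_HZ = 4.0


def _n_taps(fs: float, transition_hz: float) -> int:
    """Hamming-window FIR length for a given transition bandwidth (odd)."""
    n = int(np.ceil(3.3 * fs / transition_hz))
    return n + 1 if n % 2 == 0 else n


def _filtfilt(b: np.ndarray, data: np.ndarray) -> np.ndarray:
    t = data.shape[-1]
    padlen = min(3 * len(b), t - 1)
    return signal.filtfilt(b, [1.0], data, axis=-1, padlen=padlen)


def apply_filters(
    seg: RecordingSegment,
    hp: float = 0.1,
    lp: float = 200.0,
    notch_base: float = 50.0,
    notch_max: float = 250.0,
) -> RecordingSegment:
    """Zero-phase FIR band limiting plus mains notches with harmonics.

    Parameters
    ----------
    seg
        Input segment.
    hp, lp
        High-/low-pass band edges in Hz; must satisfy ``0 <= hp < lp < fs/2``.
        ``hp = 0`` disables high-pass entirely.
    notch_base
        Mains frequency; notches are placed at ``notch_base, 2*notch_base,
        ...`` up to ``notch_max`` (and below Nyquist). ``notch_base = 0``
        disables notching.
    """
    fs = seg.fs
    nyq = fs / 2.0
    if not 0 <= hp < lp:
        raise ValueError(f"need 0 <= hp < lp, got hp={hp}, lp={lp}")
    if lp >= nyq:
        raise ValueError(f"low-pass edge {lp} Hz must be below Nyquist {nyq} Hz")
    if notch_base < 0:
        raise ValueError("notch_base must be >= 0")

    data = seg.data
    t = seg.n_samples
    steps: list[str] = []

    # high-pass: FIR when the segment can support it, else DC removal.
    # The transition band must stay below the cutoff itself (a 2 Hz
    # transition around a 0.1 Hz edge would not be a 0.1 Hz filter), which
    # is what makes short-segment sub-Hz FIR high-passes infeasible.
    if hp > 0:
        tb = 0.25 * hp
        ntaps = _n_taps(fs, tb)
        if ntaps < t // 3:
            b = signal.firwin(ntaps, hp, fs=fs, pass_zero=False, window="hamming")
            data = _filtfilt(b, data)
            steps.append(f"hp_fir({hp}Hz,{ntaps}taps)")
        else:
            data = data - data.mean(axis=-1, keepdims=True)
            steps.append(f"hp_dc_removal(requested {hp}Hz FIR needs {ntaps} taps > T/3)")

    # low-pass
    tb = max(0.25 * lp, _MIN_TRANSITION_HZ)
    ntaps = _n_taps(fs, tb)
    if ntaps >= t:
        raise ValueError(f"segment too short for low-pass FIR: needs {ntaps} taps, T={t}")
    b = signal.firwin(ntaps, lp, fs=fs, pass_zero=True, window="hamming")
    data = _filtfilt(b, data)
    steps.append(f"lp_fir({lp}Hz,{ntaps}taps)")

    # mains notches at base frequency and harmonics
    if notch_base > 0:
        ntaps = _n_taps(fs, _NOTCH_TRANSITION_HZ)
        if ntaps >= t:
            raise ValueError(f"segment too short for notch FIR: needs {ntaps} taps, T={t}")
        f = notch_base
        while f <= notch_max and f + _NOTCH_HALF_WIDTH_HZ < nyq:
            b = signal.firwin(
                ntaps,
                [f - _NOTCH_HALF_WIDTH_HZ, f + _NOTCH_HALF_WIDTH_HZ],
                fs=fs,
                pass_zero="bandstop",
                window="hamming",
            )
            data = _filtfilt(b, data)
            steps.append(f"notch_fir({f}Hz)")
            f += notch_base

    return seg.with_data(data, "apply_filters[" + ";".join(steps) + "]")


def trim_edges(seg: RecordingSegment, trim_ms: float = 50.0) -> RecordingSegment:
    """Drop ``trim_ms`` milliseconds from both ends (filter transients)."""
    if trim_ms < 0:
        raise ValueError("trim_ms must be >= 0")
    n = int(round(trim_ms * seg.fs / 1000.0))
    if n == 0:
        return seg.with_data(seg.data, "trim_edges(0)")
    if 2 * n >= seg.n_samples:
        raise ValueError(f"trimming 2x{n} samples would consume the whole segment (T={seg.n_samples})")
    return seg.with_data(seg.data[:, n:-n], f"trim_edges({trim_ms}ms={n}samples)")


def zscore_global(seg: RecordingSegment) -> RecordingSegment:
    """Z-score the whole C x T matrix with one pooled mean and SD.

    A single transform is used for all channels so relative amplitudes
    between channels are preserved (per-channel scaling would discard the
    spatial pattern of activity).
    """
    mu = seg.data.mean()
    sd = seg.data.std()
    if sd == 0:
        raise ValueError("segment is constant: pooled SD is zero, cannot z-score")
    return seg.with_data((seg.data - mu) / sd, f"zscore_global(mu={mu:.6g},sd={sd:.6g})")


def preprocess_segment(
    seg: RecordingSegment,
    hp: float = 0.1,
    lp: float = 200.0,
    notch_base: float = 50.0,
    notch_max: float = 250.0,
    trim_ms: float = 50.0,
    filter_enabled: bool = True,
) -> RecordingSegment:
    """Full conditioning chain: filters -> trim -> global z-score."""
    if filter_enabled:
        seg = apply_filters(seg, hp=hp, lp=lp, notch_base=notch_base, notch_max=notch_max)
        seg = trim_edges(seg, trim_ms)
    return zscore_global(seg)
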