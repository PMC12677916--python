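"""Resting-state EEG preprocessing chain.

Fixed stage order, applied by :func:`preprocess_session`:

1. drop the final minute of each recording (terminal-phase fatigue drift),
2. 0.5-60 Hz band-pass + 50-Hz notch (zero-phase forward-backward IIR, so
   downstream phase-based connectivity is undistorted),
3. common average reference over the analysis channels (references dropped),
4. amplitude-threshold artifact excision (default +/-100 uV, 1-s windows),
5. segmentation into contiguous, non-overlapping 2-min epochs.

Two 5-min recordings therefore yield exactly four 2-min epochs per session.
No stage alters the sampling rate or channel order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import Montage
from .recording import Recording

EPOCH_SECONDS = 120.0


@dataclass
class RejectionLog:
    """Record of excised artifact windows for one recording."""

    threshold_uv: float
    window_s: float
    n_windows_total: int = 0
    n_windows_rejected: int = 0
    rejected_starts_s: list[float] = field(default_factory=list)
    fully_rejected: bool = False

    def to_dict(self) -> dict:
        return {
            "threshold_uv": self.threshold_uv,
            "window_s": self.window_s,
            "n_windows_total": self.n_windows_total,
            "n_windows_rejected": self.n_windows_rejected,
            "rejected_starts_s": list(self.rejected_starts_s),
            "fully_rejected": self.fully_rejected,
        }


@dataclass
class CleanEpochs:
    """Artifact-cleaned 2-min segments for one session.

    ``epochs[k]`` is an (n_analysis_channels x n_samples) array; indices run
    1..4 across the session (recording 1 epochs first).  ``provenance``
    stores filter settings and per-recording rejection logs.
    """

    epochs: list[np.ndarray]
    sampling_rate: float
    montage: Montage
    provenance: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def epoch_indices(self) -> list[int]:
        return list(range(1, self.n_epochs + 1))


def drop_final_minute(recording: Recording) -> Recording:
    """Exclude the terminal 60 s of a recording (kept samples untouched)."""
    if recording.duration < 60.0:
        raise ValueError(
            f"recording of {recording.duration:.1f} s is shorter than the "
            "60-s exclusion window"
        )
    keep = recording.n_samples - int(round(60.0 * recording.sampling_rate))
    return recording.copy_with(samples=recording.samples[:, :keep].copy())


def bandpass_notch(
    recording: Recording,
    low: float = 0.5,
    high: float = 60.0,
    notch: float = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase Butterworth band-pass plus IIR notch.

    Forward-backward filtering (``sosfiltfilt``/``filtfilt``) doubles the
    effective order and cancels phase distortion.
    """
    nyq = recording.sampling_rate / 2.0
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    if recording.is_empty:
        return recording.copy_with()
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=recording.sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos, recording.samples, axis=1)
    if notch is not None and 0 < notch < nyq:
        b, a = signal.iirnotch(notch, notch_q, fs=recording.sampling_rate)
        out = signal.filtfilt(b, a, out, axis=1)
    return recording.copy_with(samples=np.ascontiguousarray(out))


def common_average_reference(recording: Recording) -> Recording:
    """Subtract the mean over analysis channels; drop reference channels.

    The returned recording's montage contains only analysis channels, so the
    operation is idempotent.
    """
    analysis = recording.montage.analysis_labels
    if len(analysis) < 2:
        raise ValueError("common average reference needs >= 2 analysis channels")
    idx = [recording.montage.index(ch) for ch in analysis]
    data = recording.samples[idx]
    data = data - data.mean(axis=0, keepdims=True)
    return Recording(
        samples=data,
        sampling_rate=recording.sampling_rate,
        montage=recording.montage.subset(analysis),
        session_tag=recording.session_tag,
        recording_index=recording.recording_index,
        ground_truth=recording.ground_truth,
    )


def reject_artifacts(
    recording: Recording,
    amplitude_threshold: float = 100.0,
    window: float = 1.0,
    mode: str = "excise",
) -> tuple[Recording, RejectionLog]:
    """Handle fixed-length windows where any analysis channel exceeds
    +/-``amplitude_threshold`` uV: ``excise`` drops them (shortening the
    recording), ``interpolate`` replaces them by a linear bridge between
    the neighbouring clean samples (preserving length).

    A fully rejected recording is returned empty and flagged in the log,
    never raised.
    """
    if amplitude_threshold <= 0:
        raise ValueError("amplitude_threshold must be positive")
    if mode not in ("excise", "interpolate"):
        raise ValueError("mode must be 'excise' or 'interpolate'")
    wlen = int(round(window * recording.sampling_rate))
    analysis_idx = [recording.montage.index(ch)
                    for ch in recording.montage.analysis_labels]
    n_win = recording.n_samples // wlen if wlen > 0 else 0
    log = RejectionLog(threshold_uv=amplitude_threshold, window_s=window,
                       n_windows_total=n_win)
    bad_windows = []
    for w in range(n_win):
        sl = slice(w * wlen, (w + 1) * wlen)
        if np.any(np.abs(recording.samples[analysis_idx, sl]) > amplitude_threshold):
            bad_windows.append(w)
            log.n_windows_rejected += 1
            log.rejected_starts_s.append(w * wlen / recording.sampling_rate)
    if mode == "interpolate":
        data = recording.samples.copy()
        for w in bad_windows:
            a, b = w * wlen, (w + 1) * wlen
            left = data[:, a - 1] if a > 0 else data[:, min(b, data.shape[1] - 1)]
            right = data[:, b] if b < data.shape[1] else left
            ramp = np.linspace(0.0, 1.0, b - a, endpoint=False)
            data[:, a:b] = left[:, None] + (right - left)[:, None] * ramp
        log.fully_rejected = len(bad_windows) == n_win and n_win > 0
        return recording.copy_with(samples=data), log
    bad = set(bad_windows)
    kept = [recording.samples[:, w * wlen:(w + 1) * wlen]
            for w in range(n_win) if w not in bad]
    tail = recording.samples[:, n_win * wlen:]
    if tail.shape[1]:
        kept.append(tail)
    if kept:
        data = np.concatenate(kept, axis=1)
    else:
        data = recording.samples[:, :0]
    log.fully_rejected = data.shape[1] == 0
    return recording.copy_with(samples=data.copy()), log


def epoch_session(recordings: list[Recording]) -> CleanEpochs:
    """Cut each cleaned recording into contiguous non-overlapping 2-min
    epochs and concatenate in session order (rec 1 epochs, then rec 2).

    Recordings shorter than 2 min contribute fewer epochs; the shortfall is
    noted in provenance.
    """
    if not recordings:
        raise ValueError("no recordings given")
    fs = recordings[0].sampling_rate
    montage = recordings[0].montage
    for rec in recordings[1:]:
        if rec.sampling_rate != fs:
            raise ValueError("recordings disagree on sampling rate")
        if rec.montage.channel_labels != montage.channel_labels:
            raise ValueError("recordings disagree on channel set")
    elen = int(round(EPOCH_SECONDS * fs))
    epochs: list[np.ndarray] = []
    per_recording = []
    for rec in sorted(recordings, key=lambda r: r.recording_index):
        n = rec.n_samples // elen
        for k in range(n):
            epochs.append(rec.samples[:, k * elen:(k + 1) * elen].copy())
        per_recording.append({"recording_index": rec.recording_index,
                              "n_epochs": n,
                              "duration_s": rec.duration})
    provenance = {"epoch_seconds": EPOCH_SECONDS, "recordings": per_recording}
    if len(recordings) == 2 and len(epochs) < 4:
        provenance["warning"] = (
            f"expected 4 epochs from a complete session, got {len(epochs)}")
    elif len(recordings) == 1:
        provenance["warning"] = "partial session: one recording only"
    return CleanEpochs(epochs=epochs, sampling_rate=fs, montage=montage,
                       provenance=provenance)


def preprocess_session(
    recordings: list[Recording],
    amplitude_threshold: float = 100.0,
    reject_window: float = 1.0,
    low: float = 0.5,
    high: float = 60.0,
    notch: float = 50.0,
) -> CleanEpochs:
    """Full chain: truncate -> filter -> re-reference -> reject -> epoch."""
    cleaned = []
    logs = []
    for rec in recordings:
        r = drop_final_minute(rec)
        r = bandpass_notch(r, low=low, high=high, notch=notch)
        r = common_average_reference(r)
        r, log = reject_artifacts(r, amplitude_threshold, reject_window)
        cleaned.append(r)
        logs.append(log.to_dict())
    out = epoch_session(cleaned)
    out.provenance["filter"] = {"low_hz": low, "high_hz": high, "notch_hz": notch,
                                "family": "butterworth-order-4-zero-phase"}
    out.provenance["rejection"] = logs
    out.provenance["order"] = ["truncate", "filter", "re-reference", "reject", "epoch"]
    return out
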