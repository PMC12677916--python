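"""Multichannel EEG recording container and text-based I/O.

A :class:`Recording` is a channels x samples matrix in microvolts with its
sampling rate and montage.  Recordings serialize to a plain-text CSV bundle
(one header row of channel labels, one row per sample) plus a JSON sidecar
holding sampling rate, montage and any simulation ground truth, so round
trips never require binary formats.  EDF files are read through ``mne``
when available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .montage import Montage

SESSION_TAGS = ("pre", "post", "none")


@dataclass
class Recording:
    """One resting-state EEG recording.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts; channel order follows ``montage.channel_labels``.
    sampling_rate : float
        Hz.
    montage : Montage
    session_tag : str
        ``pre`` / ``post`` / ``none``.
    recording_index : int
        1 or 2 within a session.
    ground_truth : dict or None
        Simulator-provided per-channel band powers, when synthetic.
    """

    samples: np.ndarray
    sampling_rate: float
    montage: Montage
    session_tag: str = "none"
    recording_index: int = 1
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.samples.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.session_tag not in SESSION_TAGS:
            raise ValueError(f"session_tag must be one of {SESSION_TAGS}")
        if self.recording_index not in (1, 2):
            raise ValueError("recording_index must be 1 or 2")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def is_empty(self) -> bool:
        return self.n_samples == 0

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.montage.index(label)]

    def copy_with(self, **changes: Any) -> "Recording":
        if "samples" not in changes:
            changes["samples"] = self.samples.copy()
        return replace(self, **changes)


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` as ``<path>.csv`` + ``<path>.json`` sidecar.

    Returns the CSV path.
    """
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    df = pd.DataFrame(rec.samples.T, columns=list(rec.montage.channel_labels))
    df.to_csv(csv_path, index=False, float_format="%.6f")
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "montage": rec.montage.to_dict(),
        "session_tag": rec.session_tag,
        "recording_index": rec.recording_index,
        "ground_truth": rec.ground_truth,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(
    path: str | Path,
    sampling_rate: float | None = None,
    montage: Montage | None = None,
) -> Recording:
    """Read a recording from a CSV bundle or an EDF file.

    CSV: expects the sidecar ``<stem>.json`` next to the file; explicit
    ``sampling_rate``/``montage`` arguments override it (and are required
    if no sidecar exists).  EDF: delegated to ``mne.io.read_raw_edf``;
    channels not in the montage argument (if given) are dropped.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, montage)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(".json")
    sidecar: dict = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    if sampling_rate is None:
        sampling_rate = sidecar.get("sampling_rate")
    if sampling_rate is None:
        raise ValueError("sampling_rate not given and no sidecar found")
    if montage is None:
        if "montage" in sidecar:
            montage = Montage.from_dict(sidecar["montage"])
        else:
            montage = Montage(
                channel_labels=tuple(df.columns),
                reference_labels=(),
                homologous_pairs=(),
            )
    return Recording(
        samples=df[list(montage.channel_labels)].to_numpy().T,
        sampling_rate=float(sampling_rate),
        montage=montage,
        session_tag=sidecar.get("session_tag", "none"),
        recording_index=sidecar.get("recording_index", 1),
        ground_truth=sidecar.get("ground_truth"),
    )


def _read_edf(path: Path, montage: Montage | None) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    if montage is None:
        montage = Montage(channel_labels=labels, reference_labels=(), homologous_pairs=())
    data = raw.get_data(picks=list(montage.channel_labels)) * 1e6  # V -> uV
    return Recording(samples=data, sampling_rate=float(raw.info["sfreq"]), montage=montage)
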