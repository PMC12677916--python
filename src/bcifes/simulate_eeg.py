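"""Synthetic resting-state EEG with known ground truth.

The generator superimposes, per channel: (a) band-limited oscillators —
narrowband-filtered Gaussian noise carriers by default, so phase consistency
between channels is tunable, or pure tones when ``bandwidth == 0`` for
closed-form spectral checks; (b) a 1/f background; (c) 50-Hz line noise; and
(d) low-frequency high-amplitude frontal transients standing in for ocular
artifacts.  Amplitudes are RMS in microvolts, so a lone oscillator of RMS
amplitude ``a`` contributes band power ``a**2`` uV^2 (equivalently, peak
amplitude ``a*sqrt(2)`` and the sinusoidal ``peak**2/2`` convention).

Identical (config, seed) pairs reproduce recordings bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import Montage, default_montage
from .recording import Recording


@dataclass(frozen=True)
class BandComponent:
    """One oscillatory component: ``channel`` label, center frequency and
    bandwidth in Hz, RMS amplitude in uV.  ``bandwidth == 0`` means a pure
    tone.  ``name`` tags the component (used by coupling specs and ground
    truth); defaults to the center frequency's canonical band."""

    channel: str
    center: float
    bandwidth: float
    amplitude: float
    name: str | None = None

    @property
    def band_name(self) -> str:
        if self.name is not None:
            return self.name
        for nm, lo, hi in (
            ("delta", 0.5, 4.0), ("theta", 4.0, 8.0), ("alpha", 8.0, 13.0),
            ("beta", 13.0, 30.0), ("gamma", 30.0, 60.0),
        ):
            if lo <= self.center < hi:
                return nm
        return f"{self.center:g}Hz"


@dataclass(frozen=True)
class CouplingSpec:
    """Phase coupling between two channels' oscillators of the same band.

    ``mix`` in [0, 1] is the fraction of channel A's carrier injected into
    channel B's oscillator: 1.0 makes the carriers identical (PPC -> 1),
    0.0 leaves them independent.
    """

    channel_a: str
    channel_b: str
    band: str
    mix: float


@dataclass(frozen=True)
class EEGSimConfig:
    """Configuration of the synthetic EEG generator.

    Defaults emulate eyes-closed resting EEG at the study's recording
    geometry: 250 Hz, 5-min recordings, the 24-channel 10-20 montage.
    """

    sampling_rate: float = 250.0
    duration: float = 300.0
    montage: Montage = field(default_factory=default_montage)
    band_components: tuple[BandComponent, ...] = ()
    background_exponent: float = 1.0
    background_rms: float = 4.0
    line_noise_amplitude: float = 0.0
    line_noise_freq: float = 50.0
    ocular_artifact_rate: float = 0.0
    ocular_artifact_amplitude: float = 300.0
    coupling_spec: tuple[CouplingSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        nyq = self.sampling_rate / 2.0
        for c in self.band_components:
            if c.amplitude < 0:
                raise ValueError(f"negative amplitude on {c.channel}")
            lo, hi = c.center - c.bandwidth / 2.0, c.center + c.bandwidth / 2.0
            if lo <= 0 or hi >= nyq:
                raise ValueError(
                    f"band edges ({lo:g}, {hi:g}) Hz outside (0, Nyquist={nyq:g})"
                )
            if c.channel not in self.montage.channel_labels:
                raise ValueError(f"component channel {c.channel!r} not in montage")
        for cp in self.coupling_spec:
            if not 0.0 <= cp.mix <= 1.0:
                raise ValueError("mixing ratio must lie in [0, 1]")
        if self.background_rms < 0 or self.line_noise_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.ocular_artifact_rate < 0:
            raise ValueError("ocular_artifact_rate must be non-negative")


def default_eeg_config(**overrides) -> EEGSimConfig:
    """A plausible eyes-closed resting configuration on the full montage:
    posterior alpha, frontal-midline theta, central beta over a 1/f floor."""
    components = []
    for ch in ("P3", "P4", "Pz", "Oz"):
        components.append(BandComponent(ch, 10.0, 2.0, 4.0))
    for ch in ("Fz", "FCz", "Cz"):
        components.append(BandComponent(ch, 6.0, 2.0, 3.0))
    for ch in ("C3", "C4"):
        components.append(BandComponent(ch, 20.0, 4.0, 2.0))
    cfg = EEGSimConfig(
        band_components=tuple(components),
        background_rms=4.0,
        line_noise_amplitude=1.0,
        ocular_artifact_rate=2.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _narrowband_carrier(
    rng: np.random.Generator, n: int, fs: float, center: float, bandwidth: float
) -> np.ndarray:
    """Unit-RMS carrier: filtered noise, or a random-phase tone if bw == 0."""
    t = np.arange(n) / fs
    if bandwidth == 0.0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        return np.sqrt(2.0) * np.sin(2.0 * np.pi * center * t + phase)
    white = rng.standard_normal(n)
    lo = center - bandwidth / 2.0
    hi = center + bandwidth / 2.0
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0.0:  # pragma: no cover - degenerate filter
        return x
    return x / rms


def _one_over_f(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^exponent background via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _ocular_bump(fs: float, width_s: float = 0.8) -> np.ndarray:
    """Raised-cosine transient, < 4 Hz energy, unit peak."""
    n = max(int(round(width_s * fs)), 3)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))


def generate_recording(
    config: EEGSimConfig,
    seed: int | None = None,
    session_tag: str = "none",
    recording_index: int = 1,
) -> Recording:
    """Synthesize one multichannel recording from ``config``.

    ``seed`` overrides ``config.seed`` when given.  The returned
    :class:`~bcifes.recording.Recording` carries ground truth: per channel,
    the configured oscillator power (RMS amplitude squared) by band name.
    """
    if config.montage.n_channels < 2:
        raise ValueError("montage must have at least 2 channels")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    labels = config.montage.channel_labels
    data = np.zeros((len(labels), n))

    # carriers are drawn channel-by-channel in montage order so coupling can
    # reference a previously generated carrier deterministically
    carriers: dict[tuple[str, str], np.ndarray] = {}
    comps_by_channel: dict[str, list[BandComponent]] = {}
    for comp in config.band_components:
        comps_by_channel.setdefault(comp.channel, []).append(comp)
    coupling = {(cp.channel_b, cp.band): cp for cp in config.coupling_spec}

    truth: dict[str, dict[str, float]] = {ch: {} for ch in labels}
    for ch in labels:
        for comp in comps_by_channel.get(ch, []):
            carrier = _narrowband_carrier(rng, n, fs, comp.center, comp.bandwidth)
            key = (ch, comp.band_name)
            cp = coupling.get(key)
            if cp is not None and (cp.channel_a, cp.band) in carriers:
                src = carriers[(cp.channel_a, cp.band)]
                mixed = cp.mix * src + (1.0 - cp.mix) * carrier
                rms = np.sqrt(np.mean(mixed**2))
                carrier = mixed / rms if rms > 0 else mixed
            carriers[key] = carrier
            data[config.montage.index(ch)] += comp.amplitude * carrier
            truth[ch][comp.band_name] = truth[ch].get(comp.band_name, 0.0) + comp.amplitude**2

    if config.background_rms > 0:
        for i in range(len(labels)):
            data[i] += config.background_rms * _one_over_f(
                rng, n, fs, config.background_exponent
            )

    if config.line_noise_amplitude > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0.0, 2.0 * np.pi)
        line = np.sqrt(2.0) * np.sin(2.0 * np.pi * config.line_noise_freq * t + phase)
        data += config.line_noise_amplitude * line  # common across channels

    n_events = 0
    if config.ocular_artifact_rate > 0:
        n_events = rng.poisson(config.ocular_artifact_rate * config.duration / 60.0)
        frontal = [i for i, ch in enumerate(labels) if ch.upper().startswith("F")]
        bump = _ocular_bump(fs)
        for _ in range(n_events):
            start = rng.integers(0, max(n - len(bump), 1))
            amp = config.ocular_artifact_amplitude * rng.uniform(0.8, 1.2)
            sign = rng.choice([-1.0, 1.0])
            for i in frontal:
                data[i, start : start + len(bump)] += sign * amp * bump[: n - start]

    return Recording(
        samples=data,
        sampling_rate=fs,
        montage=config.montage,
        session_tag=session_tag,
        recording_index=recording_index,
        ground_truth={"band_power": truth, "n_ocular_events": int(n_events)},
    )
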