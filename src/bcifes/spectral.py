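"""Quantitative EEG spectral biomarkers.

Welch power spectral density (rectangular 20-s windows, 5-s overlap),
absolute and relative band powers, the delta/alpha ratio (DAR), the
(delta+theta)/(alpha+beta) ratio (DTABR), and the pairwise-derived brain
symmetry index (pdBSI).

Conventions
-----------
* Band edges are half-open ``[low, high)``; defaults: delta 0.5-4, theta
  4-8, alpha 8-13, beta 13-30, gamma 30-60 Hz.
* Relative PSD is each band's share of total 1-60 Hz power (band masks are
  intersected with the evaluation range so the full partition sums to 1).
* pdBSI uses the normalized form ``|(R - L) / (R + L)|`` per homologous pair
  and frequency bin, averaged over bins (1-25 Hz by default) then pairs, so
  the index is amplitude-scale-free and bounded in [0, 1].
* Global DAR/DTABR are ratios of channel-averaged band powers, which stay
  finite when individual channels have near-zero alpha; per-channel ratios
  are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .montage import Montage
from .preprocess import CleanEpochs

DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 60.0),
)


@dataclass(frozen=True)
class BandScheme:
    """Named, ordered, non-overlapping frequency bands with [low, high) edges."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        prev_high = 0.0
        for name, low, high in self.bands:
            if not 0.0 < low < high <= 60.0:
                raise ValueError(f"band {name!r} edges ({low}, {high}) out of (0, 60]")
            if low < prev_high:
                raise ValueError(f"band {name!r} overlaps the previous band")
            prev_high = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def edges(self, name: str) -> tuple[float, float]:
        for nm, low, high in self.bands:
            if nm == name:
                return low, high
        raise KeyError(f"unknown band {name!r}")

    def __iter__(self):
        return iter(self.bands)


@dataclass
class PSDMatrix:
    """Per-channel Welch PSD in uV^2/Hz.

    ``power`` is channels x frequency bins; ``bin_frequencies`` in Hz with
    spacing ``1/window_length`` unless zero padding was requested.
    """

    power: np.ndarray
    bin_frequencies: np.ndarray
    channel_labels: tuple[str, ...]
    window_length: float
    overlap: float
    n_windows: int

    @property
    def df(self) -> float:
        """Bin spacing, Hz."""
        return float(self.bin_frequencies[1] - self.bin_frequencies[0])

    def channel(self, label: str) -> np.ndarray:
        return self.power[self.channel_labels.index(label)]


def welch_psd(
    data: np.ndarray,
    sampling_rate: float,
    channel_labels: tuple[str, ...] | None = None,
    window_length: float = 20.0,
    overlap: float = 5.0,
    nfft: int | None = None,
) -> PSDMatrix:
    """Welch PSD with a rectangular window.

    Windows advance by ``window_length - overlap`` (15 s by default); the
    per-channel estimate is the mean modified periodogram over windows.
    ``nfft`` enables zero padding to a finer nominal bin spacing; the native
    spacing is ``1 / window_length``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    nperseg = int(round(window_length * sampling_rate))
    noverlap = int(round(overlap * sampling_rate))
    if data.shape[1] < nperseg:
        raise ValueError(
            f"epoch of {data.shape[1]} samples shorter than one "
            f"{window_length:g}-s window"
        )
    freqs, psd = signal.welch(
        data, fs=sampling_rate, window="boxcar", nperseg=nperseg,
        noverlap=noverlap, nfft=nfft, detrend=False, scaling="density", axis=1,
    )
    step = nperseg - noverlap
    n_windows = (data.shape[1] - nperseg) // step + 1
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return PSDMatrix(
        power=psd, bin_frequencies=freqs, channel_labels=tuple(channel_labels),
        window_length=window_length, overlap=overlap, n_windows=n_windows,
    )


def band_power(psd: PSDMatrix, low: float, high: float) -> np.ndarray:
    """Rectangle-rule integral of the PSD over bins with ``low <= f < high``."""
    mask = (psd.bin_frequencies >= low) & (psd.bin_frequencies < high)
    if not np.any(mask):
        raise ValueError(f"no frequency bins in [{low}, {high}) Hz")
    return psd.power[:, mask].sum(axis=1) * psd.df


def band_power_table(psd: PSDMatrix, bands: BandScheme | None = None) -> pd.DataFrame:
    """Channels x bands table of absolute band powers (uV^2)."""
    bands = bands or BandScheme()
    cols = {name: band_power(psd, low, high) for name, low, high in bands}
    return pd.DataFrame(cols, index=list(psd.channel_labels))


def relative_psd(
    psd: PSDMatrix,
    bands: BandScheme | None = None,
    total_range: tuple[float, float] = (1.0, 60.0),
) -> pd.DataFrame:
    """Each band's share of total power in ``total_range`` per channel.

    Band masks are intersected with the evaluation range, so shares over a
    full band partition sum to 1.  Channels with zero total power get NaN
    shares (reported missing, not 0).
    """
    bands = bands or BandScheme()
    lo_t, hi_t = total_range
    total = band_power(psd, lo_t, hi_t)
    shares = {}
    for name, low, high in bands:
        lo, hi = max(low, lo_t), min(high, hi_t)
        if lo >= hi:
            shares[name] = np.zeros(psd.power.shape[0])
            continue
        shares[name] = band_power(psd, lo, hi)
    table = pd.DataFrame(shares, index=list(psd.channel_labels))
    with np.errstate(invalid="ignore", divide="ignore"):
        table = table.div(np.where(total > 0, total, np.nan), axis=0)
    return table


@dataclass
class RatioResult:
    """Per-channel ratio plus the global (channel-aggregated) value."""

    per_channel: pd.Series
    global_value: float
    flagged_channels: tuple[str, ...] = ()


def _safe_ratio(num: pd.Series, den: pd.Series) -> tuple[pd.Series, tuple[str, ...]]:
    flagged = tuple(den.index[den <= 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den.where(den > 0, np.nan)
    return ratio, flagged


def dar(powers: pd.DataFrame) -> RatioResult:
    """Delta/alpha power ratio; lower values indicate better cortical
    function after stroke.  Global value = mean delta power / mean alpha."""
    per_channel, flagged = _safe_ratio(powers["delta"], powers["alpha"])
    mean_alpha = powers["alpha"].mean()
    global_value = float(powers["delta"].mean() / mean_alpha) if mean_alpha > 0 else np.nan
    return RatioResult(per_channel, global_value, flagged)


def dtabr(powers: pd.DataFrame) -> RatioResult:
    """(delta + theta) / (alpha + beta) power ratio; a lower value reflects a
    shift toward faster oscillations.  Gamma does not enter the formula."""
    num = powers["delta"] + powers["theta"]
    den = powers["alpha"] + powers["beta"]
    per_channel, flagged = _safe_ratio(num, den)
    dmean = den.mean()
    global_value = float(num.mean() / dmean) if dmean > 0 else np.nan
    return RatioResult(per_channel, global_value, flagged)


@dataclass
class PdBSIResult:
    value: float
    per_pair: pd.Series
    n_bins_skipped: int = 0


def pdbsi(
    psd: PSDMatrix,
    montage: Montage,
    fmin: float = 1.0,
    fmax: float = 25.0,
    band: tuple[float, float] | None = None,
) -> PdBSIResult:
    """Pairwise-derived brain symmetry index.

    ``|(R - L)/(R + L)|`` on PSD values per homologous pair and bin in
    [``fmin``, ``fmax``) (optionally intersected with ``band``), averaged
    over bins then pairs.  0 = perfect interhemispheric symmetry; bins with
    zero total pair power are skipped and counted.
    """
    if not montage.homologous_pairs:
        raise ValueError("montage defines no homologous pairs")
    lo, hi = fmin, fmax
    if band is not None:
        lo, hi = max(lo, band[0]), min(hi, band[1])
    mask = (psd.bin_frequencies >= lo) & (psd.bin_frequencies < hi)
    if not np.any(mask):
        raise ValueError(f"no frequency bins in [{lo}, {hi}) Hz")
    per_pair = {}
    skipped = 0
    for left, right in montage.homologous_pairs:
        pl = psd.channel(left)[mask]
        pr = psd.channel(right)[mask]
        tot = pl + pr
        valid = tot > 0
        skipped += int(np.sum(~valid))
        if not np.any(valid):
            per_pair[f"{left}-{right}"] = np.nan
            continue
        per_pair[f"{left}-{right}"] = float(
            np.mean(np.abs((pr[valid] - pl[valid]) / tot[valid]))
        )
    series = pd.Series(per_pair)
    return PdBSIResult(value=float(series.mean()), per_pair=series,
                       n_bins_skipped=skipped)


def global_psd(psd: PSDMatrix, montage: Montage) -> np.ndarray:
    """Per-bin arithmetic mean of the PSD over the analysis channels."""
    if tuple(psd.channel_labels) != montage.analysis_labels:
        raise ValueError(
            "PSD channels do not match the montage analysis set "
            f"({len(psd.channel_labels)} vs {montage.n_analysis})"
        )
    return psd.power.mean(axis=0)


@dataclass
class BiomarkerSet:
    """All spectral biomarkers for one epoch."""

    epoch_index: int
    psd: PSDMatrix
    band_power: pd.DataFrame
    rpsd: pd.DataFrame
    dar: RatioResult
    dtabr: RatioResult
    pdbsi: PdBSIResult
    pdbsi_per_band: dict[str, PdBSIResult]


def compute_biomarkers(
    clean: CleanEpochs,
    bands: BandScheme | None = None,
    pdbsi_range: tuple[float, float] = (1.0, 25.0),
) -> list[BiomarkerSet]:
    """Spectral biomarkers per 2-min epoch of a cleaned session."""
    bands = bands or BandScheme()
    out = []
    for k, epoch in enumerate(clean.epochs, start=1):
        psd = welch_psd(epoch, clean.sampling_rate,
                        channel_labels=clean.montage.analysis_labels)
        powers = band_power_table(psd, bands)
        per_band = {
            name: pdbsi(psd, clean.montage, *pdbsi_range, band=(low, high))
            for name, low, high in bands
            if low < pdbsi_range[1] and high > pdbsi_range[0]
        }
        out.append(BiomarkerSet(
            epoch_index=k,
            psd=psd,
            band_power=powers,
            rpsd=relative_psd(psd, bands),
            dar=dar(powers),
            dtabr=dtabr(powers),
            pdbsi=pdbsi(psd, clean.montage, *pdbsi_range),
            pdbsi_per_band=per_band,
        ))
    return out


def biomarkers_table(sets: list[BiomarkerSet]) -> pd.DataFrame:
    """Tidy (epoch, channel, band, metric, value) table for CSV export."""
    rows = []
    for s in sets:
        for ch in s.band_power.index:
            for band in s.band_power.columns:
                rows.append((s.epoch_index, ch, band, "band_power",
                             s.band_power.loc[ch, band]))
                rows.append((s.epoch_index, ch, band, "rpsd",
                             s.rpsd.loc[ch, band]))
            rows.append((s.epoch_index, ch, "", "dar", s.dar.per_channel[ch]))
            rows.append((s.epoch_index, ch, "", "dtabr", s.dtabr.per_channel[ch]))
        rows.append((s.epoch_index, "GLOBAL", "", "dar", s.dar.global_value))
        rows.append((s.epoch_index, "GLOBAL", "", "dtabr", s.dtabr.global_value))
        rows.append((s.epoch_index, "GLOBAL", "", "pdbsi", s.pdbsi.value))
        for band, res in s.pdbsi_per_band.items():
            rows.append((s.epoch_index, "GLOBAL", band, "pdbsi", res.value))
    return pd.DataFrame(rows, columns=["epoch", "channel", "band", "metric", "value"])
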